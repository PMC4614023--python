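"""Synthetic replicate-level Cq generator with known ground truth.

Emulates a repeated-measures qPCR study design: 15 candidate reference
genes measured in triplicate over 75 blood samples drawn from 7 animals.
Cq for gene g, sample j, replicate i is

    Cq_gij = mean_g + s_j + u_animal(j) + lambda_g * F_b(g),j + e_gj + t_gij

with s a shared per-sample shift (RNA input/quality), u a per-animal
effect, F a standard-normal latent factor shared by a co-regulated gene
block, e gene-specific biological noise and t technical replicate noise —
all additive normal on the Cq (log2 expression) scale, i.e. log-normal
expression. The realized per-gene noise magnitudes are recorded so
stability rankings can be checked against the intended order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cq_data import CqRecord
from .efficiency import EfficiencyTable
from .errors import ValidationError

#: animal split of the default 75-sample, 7-animal repeated-measures design
PAPER_DESIGN_ANIMAL_SIZES = (13, 12, 10, 10, 10, 10, 10)


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the emulated study design."""

    n_genes: int = 15
    n_samples: int = 75
    n_animals: int = 7
    #: per-gene mean Cq (cycles); None -> evenly spread 21..32
    gene_means: np.ndarray | None = None
    #: SD of the shared per-sample shift (cycles)
    sample_effect_sd: float = 0.4
    #: SD of the per-animal shift (cycles)
    animal_effect_sd: float = 0.2
    #: per-gene independent biological noise SD (cycles); None -> 0.1..0.8
    gene_noise_sd: np.ndarray | None = None
    #: co-regulated blocks: (gene indices, loading in cycles per factor unit)
    coreg_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    #: per-gene percent amplification efficiency; None -> evenly spread 95..105
    efficiencies: np.ndarray | None = None
    #: technical replicate noise SD (cycles)
    replicate_sd: float = 0.1
    n_replicates: int = 3
    #: samples per animal; None -> near-even split of n_samples over n_animals
    animal_sizes: tuple[int, ...] | None = None
    seed: int = 0

    @classmethod
    def paper_design(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The emulated study design: 75 samples over 7 animals (13,12,10x5)."""
        return cls(animal_sizes=PAPER_DESIGN_ANIMAL_SIZES, seed=seed, **overrides)

    def resolved_gene_means(self) -> np.ndarray:
        if self.gene_means is not None:
            return np.asarray(self.gene_means, dtype=float)
        return np.linspace(21.0, 32.0, self.n_genes)

    def resolved_gene_noise_sd(self) -> np.ndarray:
        if self.gene_noise_sd is not None:
            return np.asarray(self.gene_noise_sd, dtype=float)
        return np.linspace(0.1, 0.8, self.n_genes)

    def resolved_efficiencies(self) -> np.ndarray:
        if self.efficiencies is not None:
            return np.asarray(self.efficiencies, dtype=float)
        return np.linspace(95.0, 105.0, self.n_genes)

    def resolved_animal_sizes(self) -> np.ndarray:
        if self.animal_sizes is not None:
            sizes = np.asarray(self.animal_sizes, dtype=int)
        else:
            base = self.n_samples // self.n_animals
            sizes = np.full(self.n_animals, base)
            sizes[: self.n_samples - base * self.n_animals] += 1
        return sizes

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{j + 1:0{width}d}" for j in range(self.n_samples)]

    def animal_ids(self) -> list[str]:
        return [f"A{a + 1}" for a in range(self.n_animals)]

    def validate(self) -> "SimConfig":
        if self.n_genes < 1 or self.n_samples < 1 or self.n_replicates < 1:
            raise ValidationError("n_genes, n_samples, n_replicates must be >= 1")
        means = self.resolved_gene_means()
        if means.shape != (self.n_genes,):
            raise ValidationError("gene_means must have one entry per gene")
        if not ((means > 10.0) & (means < 40.0)).all():
            raise ValidationError("gene mean Cq must lie in (10, 40) cycles")
        noise = self.resolved_gene_noise_sd()
        if noise.shape != (self.n_genes,) or (noise < 0).any():
            raise ValidationError("gene_noise_sd must be one non-negative SD per gene")
        for sd_name in ("sample_effect_sd", "animal_effect_sd", "replicate_sd"):
            if getattr(self, sd_name) < 0:
                raise ValidationError(f"{sd_name} must be >= 0")
        eff = self.resolved_efficiencies()
        if eff.shape != (self.n_genes,) or (eff <= 0).any():
            raise ValidationError("efficiencies must be one positive percent per gene")
        sizes = self.resolved_animal_sizes()
        if sizes.sum() != self.n_samples or (sizes < 1).any():
            raise ValidationError(
                f"animal_sizes {tuple(sizes)} must be positive and sum to n_samples={self.n_samples}"
            )
        seen: set[int] = set()
        for genes_in_block, loading in self.coreg_blocks:
            for g in genes_in_block:
                if not (0 <= g < self.n_genes):
                    raise ValidationError(f"co-regulation block gene index {g} out of range")
                if g in seen:
                    raise ValidationError(f"gene index {g} appears in more than one block")
                seen.add(g)
            if loading < 0:
                raise ValidationError("block loadings must be >= 0")
        return self

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "n_animals": self.n_animals,
            "gene_means": self.resolved_gene_means().tolist(),
            "sample_effect_sd": self.sample_effect_sd,
            "animal_effect_sd": self.animal_effect_sd,
            "gene_noise_sd": self.resolved_gene_noise_sd().tolist(),
            "coreg_blocks": [[list(g), lam] for g, lam in self.coreg_blocks],
            "efficiencies": self.resolved_efficiencies().tolist(),
            "replicate_sd": self.replicate_sd,
            "n_replicates": self.n_replicates,
            "animal_sizes": self.resolved_animal_sizes().tolist(),
            "seed": self.seed,
        }


@dataclass
class SimTruth:
    """Ground truth recorded during generation."""

    #: per gene: sqrt(e_sd^2 + lambda^2), the gene-specific noise magnitude
    total_noise_sd: pd.Series
    #: genes ascending by total noise (ties by gene ID) — intended stability order
    stability_order: list[str]
    #: latent factor draws, one row per block, one column per sample
    latent_factors: np.ndarray
    #: per-cell true Cq before technical replicate noise (genes x samples)
    true_cq: pd.DataFrame
    config: SimConfig


def expected_order(truth: SimTruth) -> list[str]:
    """Genes ascending by gene-specific noise SD (independent + block loading)."""
    s = truth.total_noise_sd
    return sorted(s.index, key=lambda g: (s[g], g))


def _draw(config: SimConfig) -> tuple[np.ndarray, SimTruth, np.ndarray]:
    """Draw the Cq array (genes x samples x replicates) and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, n, r = config.n_genes, config.n_samples, config.n_replicates
    means = config.resolved_gene_means()
    noise_sd = config.resolved_gene_noise_sd()
    sizes = config.resolved_animal_sizes()

    animal_of_sample = np.repeat(np.arange(config.n_animals), sizes)
    s_j = rng.normal(0.0, config.sample_effect_sd, size=n)
    u_a = rng.normal(0.0, config.animal_effect_sd, size=config.n_animals)

    loadings = np.zeros(g)
    factor_contrib = np.zeros((g, n))
    factors = np.zeros((len(config.coreg_blocks), n))
    for b, (genes_in_block, lam) in enumerate(config.coreg_blocks):
        factors[b] = rng.normal(0.0, 1.0, size=n)
        for gi in genes_in_block:
            loadings[gi] = lam
            factor_contrib[gi] = lam * factors[b]

    e_gj = rng.normal(0.0, 1.0, size=(g, n)) * noise_sd[:, None]
    true_cq = (
        means[:, None]
        + s_j[None, :]
        + u_a[animal_of_sample][None, :]
        + factor_contrib
        + e_gj
    )
    t_gij = rng.normal(0.0, config.replicate_sd, size=(g, n, r))
    cq = true_cq[:, :, None] + t_gij

    gene_ids = config.gene_ids()
    sample_ids = config.sample_ids()
    total = np.sqrt(noise_sd**2 + loadings**2)
    total_s = pd.Series(total, index=gene_ids)
    truth = SimTruth(
        total_noise_sd=total_s,
        stability_order=sorted(gene_ids, key=lambda x: (total_s[x], x)),
        latent_factors=factors,
        true_cq=pd.DataFrame(true_cq, index=gene_ids, columns=sample_ids),
        config=config,
    )
    return cq, truth, animal_of_sample


def simulate_cq(config: SimConfig) -> tuple[list[CqRecord], SimTruth]:
    """Draw a replicate-level Cq dataset from the seeded generator."""
    cq, truth, animal_of_sample = _draw(config)
    g, n, r = config.n_genes, config.n_samples, config.n_replicates
    gene_ids = config.gene_ids()
    sample_ids = config.sample_ids()
    animal_ids = config.animal_ids()
    records = [
        CqRecord(
            sample_id=sample_ids[j],
            gene_id=gene_ids[gi],
            replicate_index=i + 1,
            cq=float(cq[gi, j, i]),
            animal_id=animal_ids[animal_of_sample[j]],
        )
        for j in range(n)
        for gi in range(g)
        for i in range(r)
    ]
    return records, truth


def simulate_matrix(config: SimConfig) -> tuple["CqMatrix", SimTruth]:
    """Draw and collapse in one step (plain replicate mean, no SD rule).

    Bit-identical draws to :func:`simulate_cq` at the same seed; the
    replicate SD acceptance rule is bypassed, which only matters when
    ``replicate_sd`` is large relative to the 0.5-cycle threshold.
    """
    from .cq_data import CqMatrix

    cq, truth, animal_of_sample = _draw(config)
    collapsed = pd.DataFrame(
        cq.mean(axis=2), index=config.gene_ids(), columns=config.sample_ids()
    )
    animal_ids = config.animal_ids()
    ann = pd.DataFrame(
        {
            "animal": [animal_ids[a] for a in animal_of_sample],
            "condition": [None] * config.n_samples,
        },
        index=config.sample_ids(),
    )
    return CqMatrix(collapsed, ann), truth


def efficiency_table(config: SimConfig) -> EfficiencyTable:
    """The generator's per-gene efficiencies as a pipeline-ready table."""
    return EfficiencyTable.from_percent(
        pd.Series(config.resolved_efficiencies(), index=config.gene_ids())
    )


def write_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a long Cq CSV, an efficiency CSV and a truth.json sidecar."""
    from .cq_data import write_long_csv  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_cq(config)
    cq_path = outdir / "cq_long.csv"
    write_long_csv(records, cq_path)
    eff_path = outdir / "efficiency.csv"
    pd.DataFrame(
        {"gene": config.gene_ids(), "efficiency_percent": config.resolved_efficiencies()}
    ).to_csv(eff_path, index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "per_gene_total_noise_sd": truth.total_noise_sd.round(6).to_dict(),
                "stability_order": truth.stability_order,
                "seed": config.seed,
                "config": config.to_dict(),
            },
            indent=2,
        )
    )
    return {"cq": cq_path, "efficiency": eff_path, "truth": truth_path}
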