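"""Sample-size robustness: rerun the ranking on random sample subsets.

The study design question: does a smaller panel of samples identify the
same top reference genes as the full panel? For each requested subset size
the full pipeline is rerun on randomly drawn sample subsets (without
replacement; per-gene Cq minima recomputed within the subset) and the
resulting comprehensive rankings are compared with the full-data ranking
by Spearman correlation and top-3 set overlap.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .aggregation import ComprehensiveRanking, comprehensive_table
from .cq_data import CqMatrix
from .efficiency import EfficiencyTable
from .errors import ValidationError
from .stability import ALGORITHMS, Algorithm


def ranking_concordance(
    a: ComprehensiveRanking, b: ComprehensiveRanking
) -> tuple[float, int]:
    """Spearman rho of final ranks plus top-3 set overlap.

    Ties get the average-rank correction inside the correlation only. The
    top-3 sets are the genes with final rank <= 3 (possibly more than three
    under ties); the overlap is capped at 3.
    """
    genes_a = set(a.table.index)
    genes_b = set(b.table.index)
    if genes_a != genes_b:
        raise ValidationError(
            f"gene sets differ: {sorted(genes_a ^ genes_b)}"
        )
    order = sorted(genes_a)
    ra = a.final_rank.reindex(order).to_numpy()
    rb = b.final_rank.reindex(order).to_numpy()
    rho = float(spearmanr(ra, rb).statistic)
    overlap = min(3, len(a.top_genes(3) & b.top_genes(3)))
    return rho, overlap


def draw_subset(
    sample_ids: Sequence[str],
    size: int,
    seed: int,
    draw_index: int,
    animals: pd.Series | None = None,
) -> list[str]:
    """Uniform without-replacement subset, reproducible from (seed, size, draw).

    Each draw uses an independent generator keyed by the seed, the subset
    size and the draw counter, so draw d is identical no matter how many
    draws precede it. With ``animals`` given, sampling is stratified:
    the subset size is apportioned over animals proportionally to their
    sample counts (largest-remainder rounding).
    """
    rng = np.random.default_rng([seed, size, draw_index])
    ids = list(sample_ids)
    if animals is None:
        chosen = rng.choice(len(ids), size=size, replace=False)
        return [ids[i] for i in sorted(chosen)]
    groups = pd.Series(list(animals), index=ids).groupby(lambda s: animals[s]).groups
    counts = {a: len(v) for a, v in groups.items()}
    total = sum(counts.values())
    quota = {a: size * c / total for a, c in counts.items()}
    base = {a: int(np.floor(q)) for a, q in quota.items()}
    leftover = size - sum(base.values())
    order = sorted(quota, key=lambda a: (-(quota[a] - base[a]), str(a)))
    for a in order[:leftover]:
        base[a] += 1
    chosen: list[str] = []
    for a in sorted(base, key=str):
        members = sorted(groups[a])
        take = min(base[a], len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        chosen.extend(members[i] for i in idx)
    return sorted(chosen)


@dataclass
class SubsampleReport:
    """Concordance of subset rankings with the full-data ranking."""

    subset_size: int
    n_draws: int
    seed: int
    rankings: list[ComprehensiveRanking]
    rhos: list[float]
    top3_overlaps: list[int]
    #: per gene: distribution of final ranks over draws
    rank_distribution: pd.DataFrame

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.rhos))

    @property
    def top3_overlap_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.top3_overlaps, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def summary_table(self) -> pd.DataFrame:
        """Per gene: median final rank, IQR, fraction of draws in the top 3."""
        rd = self.rank_distribution
        out = pd.DataFrame(
            {
                "median_final_rank": rd.median(axis=1),
                "iqr": rd.quantile(0.75, axis=1) - rd.quantile(0.25, axis=1),
                "fraction_top3": (rd <= 3).mean(axis=1),
            }
        )
        out.index.name = "gene"
        return out.sort_values("median_final_rank")


def subsample_rankings(
    matrix: CqMatrix,
    eff: EfficiencyTable,
    sizes: Iterable[int],
    n_draws: int = 100,
    seed: int = 0,
    stratify_by_animal: bool = False,
    algorithms: Iterable[Algorithm] = ALGORITHMS,
    v_cutoff: float = 0.15,
    dispersion: str = "sd",
) -> dict[int, SubsampleReport]:
    """Rerun the comprehensive ranking on random sample subsets per size.

    Subsets are drawn uniformly without replacement (optionally stratified
    by animal). Each subset rerun recomputes the per-gene Cq minima and the
    whole pipeline from scratch. Returns one report per subset size keyed
    by size.
    """
    sizes = list(sizes)
    n = matrix.n_samples
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    for size in sizes:
        if not (3 <= size <= n):
            raise ValidationError(
                f"subset size {size} outside valid range [3, {n}]"
            )
    algorithms = tuple(algorithms)
    full = comprehensive_table(
        matrix, eff, algorithms=algorithms, v_cutoff=v_cutoff, dispersion=dispersion
    ).ranking

    animals = None
    if stratify_by_animal:
        if matrix.sample_annotations is None or "animal" not in matrix.sample_annotations:
            raise ValidationError("stratified subsampling requires animal annotations")
        animals = matrix.sample_annotations["animal"]

    reports: dict[int, SubsampleReport] = {}
    for size in sizes:
        rankings, rhos, overlaps = [], [], []
        rank_cols = {}
        for d in range(n_draws):
            subset = draw_subset(matrix.samples, size, seed, d, animals)
            sub = matrix.subset_samples(subset)
            ranking = comprehensive_table(
                sub, eff, algorithms=algorithms, v_cutoff=v_cutoff, dispersion=dispersion
            ).ranking
            rho, overlap = ranking_concordance(full, ranking)
            rankings.append(ranking)
            rhos.append(rho)
            overlaps.append(overlap)
            rank_cols[d] = ranking.final_rank
        rank_dist = pd.DataFrame(rank_cols).reindex(sorted(full.table.index))
        reports[size] = SubsampleReport(
            subset_size=size,
            n_draws=n_draws,
            seed=seed,
            rankings=rankings,
            rhos=rhos,
            top3_overlaps=overlaps,
            rank_distribution=rank_dist,
        )
    return reports
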