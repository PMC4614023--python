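"""The four reference-gene stability algorithms.

All four produce a per-gene score oriented "lower = more stable":

- geNorm M: mean SD (across samples) of a gene's pairwise log2 expression
  ratios with every other candidate, refined by iteratively excluding the
  least stable gene; also yields the pairwise variations V(n/n+1) used to
  choose how many reference genes suffice (default cutoff 0.15).
- NormFinder: model-based estimate of a gene's own variance after removing
  an additive per-sample effect from log-scale expression (single-group
  variant, bias-corrected closed form).
- BestKeeper: plain dispersion (SD, optionally MAD) of each gene's Cq
  across samples; SD < 1 cycle is the conventional "stably expressed" rule.
- Comparative delta-Ct: mean over partner genes of the SD of pairwise Cq
  differences.

geNorm and NormFinder operate on relative quantities (log2 scale); BestKeeper
and delta-Ct operate on (corrected) Cq directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import gmean, pearsonr

from .efficiency import CorrectedCqMatrix
from .errors import ValidationError

#: geNorm pairwise-variation cutoff below which adding a gene is unnecessary
DEFAULT_V_CUTOFF = 0.15
#: geNorm M above this indicates an unusable reference gene
GENORM_M_LIMIT = 1.5
#: BestKeeper SD (cycles) below this counts as stably expressed
BESTKEEPER_SD_LIMIT = 1.0

Algorithm = Literal["genorm", "normfinder", "bestkeeper", "delta_ct"]
ALGORITHMS: tuple[Algorithm, ...] = ("delta_ct", "bestkeeper", "normfinder", "genorm")


@dataclass
class StabilityScores:
    """Per-gene stability scores for one algorithm (lower = more stable)."""

    algorithm: Algorithm
    scores: pd.Series  # gene -> non-negative score
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError(
                f"{self.algorithm} produced non-finite or negative scores"
            )


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

@dataclass
class GenormResult:
    #: full-panel M per gene (before any exclusion)
    m_values: pd.Series
    #: genes from least to most stable, with the M each carried when excluded;
    #: the final pair appears last, both carrying their mutual pairwise SD
    exclusion_order: list[tuple[str, float]]
    #: the two genes remaining after iterative exclusion (shared rank 1)
    final_pair: tuple[str, str]
    #: stepwise M per gene (the reported geNorm score)
    stepwise_m: pd.Series
    #: (n, V(n/n+1)) for n = 2..K-1
    v_values: list[tuple[int, float]]
    #: smallest n with V(n/n+1) < cutoff, or None
    optimal_n: int | None
    v_cutoff: float = DEFAULT_V_CUTOFF
    warning: str | None = None

    @property
    def stability_order(self) -> list[str]:
        """Genes most to least stable (final pair first, reverse exclusion)."""
        return [g for g, _ in reversed(self.exclusion_order)]

    def scores(self) -> StabilityScores:
        return StabilityScores(
            "genorm",
            self.stepwise_m,
            {
                "m_full_panel": self.m_values,
                "v_values": self.v_values,
                "optimal_n": self.optimal_n,
                "final_pair": self.final_pair,
                "all_below_limit": bool((self.stepwise_m < GENORM_M_LIMIT).all()),
            },
        )


def _pairwise_log_ratio_sd(logq: np.ndarray) -> np.ndarray:
    """V[j, k] = SD over samples (ddof=1) of logq_j - logq_k."""
    diffs = logq[:, None, :] - logq[None, :, :]
    return diffs.std(axis=2, ddof=1)


def _m_values(logq: np.ndarray) -> np.ndarray:
    v = _pairwise_log_ratio_sd(logq)
    k = v.shape[0]
    return v.sum(axis=1) / (k - 1)


def genorm(q: pd.DataFrame, v_cutoff: float = DEFAULT_V_CUTOFF) -> GenormResult:
    """geNorm stability analysis on a relative-quantity matrix (genes x samples).

    Iteratively removes the gene with the largest M (ties broken by
    lexicographically smallest gene ID) until two genes remain; those two
    share rank 1 and both report their mutual pairwise SD as M. The
    pairwise variations V(n/n+1) between normalization factors built from
    the top n and top n+1 genes give the optimal reference-gene count:
    the smallest n whose V falls below ``v_cutoff``.
    """
    arr = q.to_numpy(dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValidationError("geNorm requires strictly positive finite quantities")
    if q.shape[1] < 2:
        raise ValidationError("geNorm needs at least 2 samples")
    genes = list(q.index)
    k = len(genes)
    logq = np.log2(arr)
    m_full = pd.Series(_m_values(logq), index=genes) if k >= 2 else None
    if k < 2:
        raise ValidationError("geNorm needs at least 2 genes")

    warning = None
    exclusion: list[tuple[str, float]] = []
    if k == 2:
        pair_sd = float(np.std(logq[0] - logq[1], ddof=1))
        stepwise = pd.Series([pair_sd, pair_sd], index=genes)
        return GenormResult(
            m_values=m_full,
            exclusion_order=[(genes[0], pair_sd), (genes[1], pair_sd)],
            final_pair=(genes[0], genes[1]),
            stepwise_m=stepwise,
            v_values=[],
            optimal_n=None,
            v_cutoff=v_cutoff,
            warning="only 2 genes: no exclusion possible, both rank 1",
        )

    remaining = list(range(k))
    while len(remaining) > 2:
        m = _m_values(logq[remaining])
        # largest M leaves; ties -> lexicographically smallest gene ID
        worst_m = m.max()
        tied = [i for i, mi in zip(remaining, m) if mi == worst_m]
        out = min(tied, key=lambda i: genes[i])
        exclusion.append((genes[out], float(worst_m)))
        remaining.remove(out)

    i, j = remaining
    pair_sd = float(np.std(logq[i] - logq[j], ddof=1))
    final_pair = tuple(sorted((genes[i], genes[j])))
    for g in final_pair:
        exclusion.append((g, pair_sd))

    stepwise = pd.Series({g: m for g, m in exclusion}).reindex(genes)

    # normalization factors over the top-n genes, most stable first
    order = [g for g, _ in reversed(exclusion)]
    order_idx = [genes.index(g) for g in order]
    v_values: list[tuple[int, float]] = []
    for n in range(2, k):
        nf_n = gmean(arr[order_idx[:n]], axis=0)
        nf_n1 = gmean(arr[order_idx[: n + 1]], axis=0)
        v = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
        v_values.append((n, v))
    optimal_n = next((n for n, v in v_values if v < v_cutoff), None)

    return GenormResult(
        m_values=m_full,
        exclusion_order=exclusion,
        final_pair=final_pair,  # type: ignore[arg-type]
        stepwise_m=stepwise,
        v_values=v_values,
        optimal_n=optimal_n,
        v_cutoff=v_cutoff,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

@dataclass
class NormFinderModel:
    """Fitted single-group NormFinder model.

    The additive model y_ij = alpha_i + beta_j + eps_ij is fit to log-scale
    expression by double-centering. With r the residual grid,
    a_i = sum_j r_ij^2 / (n-1), A = sum_i a_i, the bias-corrected per-gene
    variance is sigma2_i = (a_i - A/(k(k-1))) * k/(k-2) and the stability
    value is sqrt(max(sigma2_i, 0)).
    """

    gene_means: pd.Series
    sample_effects: pd.Series
    residuals: pd.DataFrame
    raw_mean_square: pd.Series  # a_i
    variance: pd.Series  # sigma2_i, may be negative before flooring
    stability: pd.Series  # sqrt(floored variance)
    floored_genes: list[str]

    def scores(self) -> StabilityScores:
        return StabilityScores(
            "normfinder",
            self.stability,
            {"variance": self.variance, "floored_genes": self.floored_genes},
        )


def normfinder(y: pd.DataFrame) -> NormFinderModel:
    """NormFinder stability on log-scale expression (genes x samples).

    Requires at least 3 genes (the variance estimator is undefined for
    k <= 2) and 3 samples. Negative variance estimates (possible in the
    bias-corrected form) are floored at 0 and the affected genes recorded.
    """
    k, n = y.shape
    if k < 3:
        raise ValidationError(f"NormFinder needs >= 3 genes, got {k}")
    if n < 3:
        raise ValidationError(f"NormFinder needs >= 3 samples, got {n}")
    arr = y.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("NormFinder input must be finite")
    gene_means = arr.mean(axis=1)
    sample_means = arr.mean(axis=0)
    grand = arr.mean()
    r = arr - gene_means[:, None] - sample_means[None, :] + grand
    a = (r**2).sum(axis=1) / (n - 1)
    total = a.sum()
    var = (a - total / (k * (k - 1))) * k / (k - 2)
    stab = np.sqrt(np.clip(var, 0.0, None))
    genes = y.index
    floored = [g for g, v in zip(genes, var) if v < 0]
    return NormFinderModel(
        gene_means=pd.Series(gene_means, index=genes),
        sample_effects=pd.Series(sample_means - grand, index=y.columns),
        residuals=pd.DataFrame(r, index=genes, columns=y.columns),
        raw_mean_square=pd.Series(a, index=genes),
        variance=pd.Series(var, index=genes),
        stability=pd.Series(stab, index=genes),
        floored_genes=floored,
    )


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

@dataclass
class BestKeeperResult:
    """Per-gene Cq dispersion statistics.

    ``per_gene`` columns: sd (n-1 sample SD, cycles), mad (mean absolute
    deviation from the mean, cycles), cv_percent, stable_flag (SD < 1).
    When computed with the index option, ``index`` holds the per-sample
    geometric mean Cq and ``index_correlation`` the per-gene Pearson r
    against it.
    """

    per_gene: pd.DataFrame
    dispersion: Literal["sd", "mad"]
    index: pd.Series | None = None
    index_correlation: pd.DataFrame | None = None

    def scores(self) -> StabilityScores:
        return StabilityScores(
            "bestkeeper",
            self.per_gene[self.dispersion],
            {
                "per_gene": self.per_gene,
                "all_stable": bool(self.per_gene["stable_flag"].all()),
            },
        )


def bestkeeper(
    cq: CorrectedCqMatrix,
    dispersion: Literal["sd", "mad"] = "sd",
    with_index: bool = False,
) -> BestKeeperResult:
    """BestKeeper dispersion of (corrected) Cq across samples.

    The ranking score is the chosen dispersion (sample SD by default, MAD
    optionally). ``with_index`` additionally computes the BestKeeper index
    (per-sample geometric mean Cq) and each gene's Pearson correlation with it.
    """
    v = cq.values
    if v.shape[1] < 2:
        raise ValidationError("BestKeeper needs >= 2 samples")
    if dispersion not in ("sd", "mad"):
        raise ValueError(f"dispersion must be 'sd' or 'mad', got {dispersion!r}")
    sd = v.std(axis=1, ddof=1)
    mad = (v.sub(v.mean(axis=1), axis=0)).abs().mean(axis=1)
    per_gene = pd.DataFrame(
        {
            "sd": sd,
            "mad": mad,
            "cv_percent": 100.0 * sd / v.mean(axis=1),
            "stable_flag": sd < BESTKEEPER_SD_LIMIT,
        }
    )
    index = corr = None
    if with_index:
        index = pd.Series(gmean(v.to_numpy(), axis=0), index=v.columns, name="bk_index")
        rows = {}
        for g in v.index:
            r, p = pearsonr(v.loc[g], index)
            rows[g] = {"pearson_r": r, "p_value": p}
        corr = pd.DataFrame.from_dict(rows, orient="index")
    return BestKeeperResult(per_gene, dispersion, index, corr)


# ---------------------------------------------------------------------------
# Comparative delta-Ct
# ---------------------------------------------------------------------------

def delta_ct(cq: CorrectedCqMatrix) -> StabilityScores:
    """Comparative delta-Ct stability on (corrected) Cq.

    For every gene pair (j, k) the per-sample difference Cq_j - Cq_k is
    formed; gene j's score is the mean over partners k != j of the SD
    (ddof=1) of that difference across samples. Per-sample offsets common
    to all genes cancel in the differences.
    """
    v = cq.values
    k, n = v.shape
    if k < 2:
        raise ValidationError("delta-Ct needs >= 2 genes")
    if n < 2:
        raise ValidationError("delta-Ct needs >= 2 samples")
    sds = _pairwise_log_ratio_sd(v.to_numpy(dtype=float))  # differences on Cq scale
    scores = pd.Series(sds.sum(axis=1) / (k - 1), index=v.index)
    return StabilityScores(
        "delta_ct", scores, {"pairwise_sd": pd.DataFrame(sds, index=v.index, columns=v.index)}
    )
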