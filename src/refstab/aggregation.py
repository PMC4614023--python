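"""Rank assignment and comprehensive (geometric-mean) rank aggregation.

Each algorithm's scores are converted to competition ("minimum") ranks —
tied scores share the smallest applicable rank and the next distinct score
skips (1, 1, 3, ...). The comprehensive ranking is the per-gene geometric
mean of the per-algorithm integer ranks, itself competition-ranked
ascending; lower geomean = more stable overall.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import gmean, rankdata

from .cq_data import CqMatrix
from .efficiency import EfficiencyTable, correct_cq, relative_quantity
from .errors import ValidationError
from .stability import (
    ALGORITHMS,
    Algorithm,
    GenormResult,
    StabilityScores,
    bestkeeper,
    delta_ct,
    genorm,
    normfinder,
)


@dataclass
class RankTable:
    """Competition ranks (1 = most stable) for one algorithm."""

    algorithm: str
    ranks: pd.Series  # gene -> int rank


def assign_ranks(scores: StabilityScores) -> RankTable:
    """Ascending competition ranking of stability scores (lower = better)."""
    if len(scores.scores) == 0:
        raise ValidationError("cannot rank an empty score set")
    ranks = rankdata(scores.scores.to_numpy(dtype=float), method="min").astype(int)
    return RankTable(scores.algorithm, pd.Series(ranks, index=scores.scores.index))


@dataclass
class ComprehensiveRanking:
    """Per-gene per-algorithm ranks, geomean of ranks, and final ordering.

    ``table`` is sorted by final rank and carries one ``<alg>_rank`` column
    per contributing algorithm plus ``geomean`` (rounded to 2 decimals for
    display), ``geomean_exact`` and ``final_rank``.
    """

    table: pd.DataFrame
    algorithms: tuple[str, ...]

    @property
    def final_rank(self) -> pd.Series:
        return self.table["final_rank"]

    def top_genes(self, max_rank: int = 3) -> set[str]:
        return set(self.table.index[self.table["final_rank"] <= max_rank])


def aggregate_geomean(rank_tables: Iterable[RankTable]) -> ComprehensiveRanking:
    """Geometric-mean aggregation of per-algorithm rank tables.

    All tables must cover the same gene set. The displayed geomean is the
    exact value rounded half-even to 2 decimals; the final competition
    ranking uses the unrounded values. Display order breaks geomean ties by
    mean rank, then gene ID (the shared final_rank is unaffected).
    """
    tables = list(rank_tables)
    if not tables:
        raise ValidationError("no rank tables to aggregate")
    genes = set(tables[0].ranks.index)
    for t in tables:
        missing = genes.symmetric_difference(t.ranks.index)
        if missing:
            raise ValidationError(
                f"gene set mismatch in algorithm {t.algorithm!r}: {sorted(missing)}"
            )
    rank_df = pd.DataFrame(
        {f"{t.algorithm}_rank": t.ranks for t in tables}
    ).loc[tables[0].ranks.index]
    geo = pd.Series(gmean(rank_df.to_numpy(dtype=float), axis=1), index=rank_df.index)
    final = pd.Series(
        rankdata(geo.to_numpy(), method="min").astype(int), index=geo.index
    )
    out = rank_df.copy()
    out["geomean_exact"] = geo
    out["geomean"] = np.round(geo, 2)
    out["final_rank"] = final
    mean_rank = rank_df.mean(axis=1)
    out = out.loc[
        sorted(out.index, key=lambda g: (geo[g], mean_rank[g], g))
    ]
    out.index.name = "gene"
    return ComprehensiveRanking(out, tuple(t.algorithm for t in tables))


@dataclass
class ComprehensiveResult:
    """Full pipeline output: per-algorithm scores/ranks plus the aggregate."""

    ranking: ComprehensiveRanking
    scores: dict[str, StabilityScores] = field(default_factory=dict)
    genorm_detail: GenormResult | None = None

    def to_table(self) -> pd.DataFrame:
        """One row per gene (sorted by final rank) mirroring the standard
        report layout: geomean, final rank, then (value, rank) per algorithm."""
        t = self.ranking.table
        cols: dict[str, pd.Series] = {
            "geomean": t["geomean"],
            "final_rank": t["final_rank"],
        }
        for alg in self.ranking.algorithms:
            if alg in self.scores:
                cols[f"{alg}_value"] = self.scores[alg].scores.reindex(t.index)
            cols[f"{alg}_rank"] = t[f"{alg}_rank"]
        out = pd.DataFrame(cols)
        out.index.name = "gene"
        return out


def comprehensive_table(
    matrix: CqMatrix,
    eff: EfficiencyTable,
    algorithms: Iterable[Algorithm] = ALGORITHMS,
    v_cutoff: float = 0.15,
    dispersion: str = "sd",
) -> ComprehensiveResult:
    """Run the full stability pipeline on a collapsed Cq matrix.

    Efficiency-corrects Cq, derives relative quantities, runs the requested
    algorithms (geNorm and NormFinder on quantities, BestKeeper and delta-Ct
    on corrected Cq), ranks each, and aggregates by geometric mean of ranks.
    """
    algorithms = tuple(algorithms)
    if not algorithms:
        raise ValidationError("at least one algorithm is required")
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
    matrix.validate()
    corrected = correct_cq(matrix, eff)
    q = relative_quantity(corrected)

    scores: dict[str, StabilityScores] = {}
    genorm_detail = None
    for alg in algorithms:
        if alg == "genorm":
            genorm_detail = genorm(q, v_cutoff=v_cutoff)
            scores[alg] = genorm_detail.scores()
        elif alg == "normfinder":
            scores[alg] = normfinder(np.log2(q)).scores()
        elif alg == "bestkeeper":
            scores[alg] = bestkeeper(corrected, dispersion=dispersion).scores()
        elif alg == "delta_ct":
            scores[alg] = delta_ct(corrected)

    ranking = aggregate_geomean(assign_ranks(s) for s in scores.values())
    return ComprehensiveResult(ranking, scores, genorm_detail)
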