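"""Amplification-efficiency handling and efficiency-corrected Cq.

qPCR amplification efficiency E (percent) is estimated from the slope of a
standard curve of Cq against log10 relative template dilution:

    E = (10^(-1/slope) - 1) * 100

An efficiency of 100% means exact product doubling each cycle; the
amplification factor is f = 1 + E/100 (so f = 2 at 100%). When f differs
from 2, raw Cq differences no longer map one cycle to one two-fold change.
The corrected Cq rescales each gene's Cq so they do:

    dCq      = Cq - Cq_min            (Cq_min = lowest Cq of that gene)
    Cq_corr  = Cq_min - log2(f^(-dCq)) = Cq_min + dCq * log2(f)

from which the relative quantity Q = 2^(Cq_min - Cq_corr) = f^(-dCq),
scaled per gene to a maximum of 1 at the highest-expressing sample.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CqMatrix
from .errors import FormatError, ValidationError

#: efficiencies outside this percent window get a warning flag
EFFICIENCY_OPTIMAL_RANGE = (95.0, 105.0)


def efficiency_from_slope(slope: float) -> float:
    """Percent efficiency from a standard-curve slope (cycles per log10 dilution)."""
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_percent: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    return -1.0 / np.log10(1.0 + efficiency_percent / 100.0)


@dataclass
class StandardCurve:
    gene_id: str
    points: list[tuple[float, float]]  # (log10 relative dilution, mean Cq)
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    positive_slope_warning: bool = False


@dataclass
class EfficiencyTable:
    """Per-gene percent amplification efficiency.

    ``table`` is indexed by gene_id with columns ``efficiency_percent``,
    ``amplification_factor`` (f = 1 + E/100) and ``out_of_range`` (True when
    E falls outside the 95-105% optimal window).
    """

    table: pd.DataFrame

    @classmethod
    def from_percent(cls, eff: dict[str, float] | pd.Series) -> "EfficiencyTable":
        s = pd.Series(eff, dtype=float)
        f = 1.0 + s / 100.0
        if (f <= 1.0).any():
            bad = s[f <= 1.0].index.tolist()
            raise ValidationError(
                f"amplification factor must exceed 1 (efficiency > 0%); offending genes: {bad}"
            )
        lo, hi = EFFICIENCY_OPTIMAL_RANGE
        return cls(
            pd.DataFrame(
                {
                    "efficiency_percent": s,
                    "amplification_factor": f,
                    "out_of_range": (s < lo) | (s > hi),
                }
            )
        )

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def factor(self, gene_id: str) -> float:
        return float(self.table.loc[gene_id, "amplification_factor"])

    def percent(self, gene_id: str) -> float:
        return float(self.table.loc[gene_id, "efficiency_percent"])


def read_efficiency(path: str | Path) -> EfficiencyTable:
    """Read a per-gene efficiency CSV.

    Exactly one of ``efficiency_percent`` or ``slope`` must be present
    alongside ``gene``; slopes are converted through the standard-curve
    equation.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"efficiency file not found: {path}")
    df = pd.read_csv(path, comment="#")
    if "gene" not in df.columns:
        raise FormatError(f"efficiency table {path} is missing required column 'gene'")
    has_pct = "efficiency_percent" in df.columns
    has_slope = "slope" in df.columns
    if has_pct == has_slope:
        raise FormatError(
            f"efficiency table {path} must have exactly one of "
            "'efficiency_percent' or 'slope'"
        )
    df = df.set_index("gene")
    if has_pct:
        eff = df["efficiency_percent"].astype(float)
    else:
        eff = df["slope"].astype(float).map(efficiency_from_slope)
    return EfficiencyTable.from_percent(eff)


def mean_efficiency(estimates: Sequence[float]) -> float:
    """Combine replicate standard-curve E estimates (arithmetic mean of percents)."""
    if len(estimates) == 0:
        raise ValidationError("no efficiency estimates to average")
    return float(np.mean(estimates))


def fit_standard_curve(
    points: Sequence[tuple[float, float]], gene_id: str = ""
) -> StandardCurve:
    """OLS fit of Cq on log10 dilution; efficiency from the slope.

    Requires at least 3 points with non-zero dilution spread. A positive
    slope (template increases Cq) is physically invalid; the curve is still
    returned, flagged, with E computed from the fitted slope.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValidationError(f"standard curve needs >= 3 points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValidationError("standard curve dilutions have zero spread")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise ValidationError("standard curve slope is exactly zero; E undefined")
    return StandardCurve(
        gene_id=gene_id,
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_percent=efficiency_from_slope(float(fit.slope)),
        positive_slope_warning=fit.slope > 0,
    )


@dataclass
class CorrectedCqMatrix:
    """Efficiency-corrected Cq with the per-gene raw Cq minima recorded."""

    values: pd.DataFrame  # genes x samples, cycles
    cq_min: pd.Series  # per gene, cycles (minimum of the *raw* data)
    sample_annotations: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def correct_cq(matrix: CqMatrix, eff: EfficiencyTable) -> CorrectedCqMatrix:
    """Efficiency-correct a collapsed Cq matrix.

    Per gene, dCq = Cq - Cq_min over the analyzed samples and
    Cq_corr = Cq_min + dCq * log2(f). With f = 2 (E = 100%) this is the
    identity; Cq_min itself always maps to itself. Cq_min is recomputed on
    whatever sample set the matrix holds, so subsampled analyses rescale
    against their own minimum.
    """
    missing = [g for g in matrix.genes if g not in eff.table.index]
    if missing:
        raise ValidationError(f"no efficiency entry for gene(s): {missing}")
    v = matrix.values
    f = eff.table["amplification_factor"].reindex(v.index)
    cq_min = v.min(axis=1)
    dcq = v.sub(cq_min, axis=0)
    log2f = np.log2(f)
    corrected = dcq.mul(log2f, axis=0).add(cq_min, axis=0)
    # at exactly 100% efficiency the map is the identity, bitwise
    exact = log2f == 1.0
    if exact.any():
        corrected.loc[exact] = v.loc[exact]
    return CorrectedCqMatrix(corrected, cq_min, matrix.sample_annotations)


def relative_quantity(corrected: CorrectedCqMatrix) -> pd.DataFrame:
    """Relative quantities Q = 2^(Cq_min - Cq_corr), per-gene max of exactly 1."""
    q = np.exp2(corrected.values.rsub(corrected.cq_min, axis=0))
    return q
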