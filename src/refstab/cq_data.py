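"""Cq data model, readers/writers, triplicate collapsing and QC.

Quantification-cycle (Cq) measurements arrive either as replicate-level long
tables (one row per technical replicate) or as collapsed gene x sample
matrices. This module holds both representations, collapses technical
triplicates under the conventional SD < 0.5 cycle acceptance rule, and
computes per-gene QC statistics (mean/min/max Cq, range, transcript-level
class).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

# Cq values outside this window are rejected: a 45-cycle protocol cannot
# produce a Cq above 45, and non-positive cycles are meaningless.
CQ_MIN_VALID = 0.0
CQ_MAX_VALID = 45.0

#: mean Cq below this -> "high" transcript-level class, at/above -> "low"
HIGH_EXPRESSION_CQ_CUTOFF = 25.0

#: per-gene max-min Cq range at/above this many cycles is flagged
CQ_RANGE_FLAG_CYCLES = 5.0

LONG_REQUIRED_COLUMNS = ("sample", "gene", "replicate", "cq")
LONG_OPTIONAL_COLUMNS = ("animal", "condition")

DropPolicy = Literal["error", "drop_sample", "drop_gene"]


@dataclass(frozen=True)
class CqRecord:
    """A single technical-replicate Cq measurement."""

    sample_id: str
    gene_id: str
    replicate_index: int
    cq: float
    animal_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1, got {self.replicate_index}"
            )
        if not np.isfinite(self.cq) or not (CQ_MIN_VALID < self.cq <= CQ_MAX_VALID):
            raise ValidationError(
                f"Cq must be finite and in ({CQ_MIN_VALID}, {CQ_MAX_VALID}], "
                f"got {self.cq!r} for sample={self.sample_id} gene={self.gene_id}"
            )


@dataclass
class CqMatrix:
    """Collapsed Cq values as a genes x samples grid.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns, in
    cycles. ``sample_annotations`` (optional) is indexed by sample_id and may
    carry ``animal`` and ``condition`` columns.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self, min_genes: int = 3, min_samples: int = 3) -> "CqMatrix":
        """Check completeness and size requirements for stability analysis."""
        v = self.values
        if v.isna().any().any():
            bad = int(v.isna().sum().sum())
            raise ValidationError(f"Cq matrix has {bad} missing cell(s); a complete design is required")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValidationError("Cq matrix contains non-finite values")
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValidationError("duplicate gene or sample identifiers")
        if self.n_genes < min_genes or self.n_samples < min_samples:
            raise ValidationError(
                f"stability analysis needs >= {min_genes} genes and >= {min_samples} "
                f"samples, got {self.n_genes} x {self.n_samples}"
            )
        return self

    def subset_samples(self, sample_ids: Sequence[str]) -> "CqMatrix":
        ann = None
        if self.sample_annotations is not None:
            ann = self.sample_annotations.loc[list(sample_ids)]
        return CqMatrix(self.values[list(sample_ids)].copy(), ann)

    def to_wide_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path)


@dataclass
class CqDataset:
    """Result of reading a Cq file: replicate records (long) or a matrix (wide)."""

    records: list[CqRecord] = field(default_factory=list)
    matrix: CqMatrix | None = None

    @property
    def layout(self) -> str:
        return "wide" if self.matrix is not None else "long"


@dataclass
class QcSummary:
    """Per-gene Cq descriptive statistics and transcript-level classes.

    ``per_gene`` columns: mean_cq, min_cq, max_cq, range, level
    ("high"/"low"), range_flag. ``class_counts`` maps level -> gene count.
    """

    per_gene: pd.DataFrame
    class_counts: dict[str, int]

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out = self.per_gene.copy()
            out.index.name = "gene"
            out.to_csv(fh, sep="\t")


def read_cq(path: str | Path, layout: Literal["long", "wide"]) -> CqDataset:
    """Read a Cq table from CSV.

    Long layout requires columns ``sample, gene, replicate, cq`` (plus
    optional ``animal, condition``) and yields replicate records. Wide layout
    has a ``gene`` first column and one column per sample of collapsed Cq,
    and yields a :class:`CqMatrix` directly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    if layout == "long":
        return _read_long(path)
    if layout == "wide":
        return _read_wide(path)
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def _read_long(path: Path) -> CqDataset:
    df = pd.read_csv(path, dtype=str)
    for col in LONG_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"long Cq table {path} is missing required column '{col}'")
    records: list[CqRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row_d = dict(zip(df.columns, row))
        try:
            cq = float(row_d["cq"])
        except (TypeError, ValueError):
            raise FormatError(
                f"non-numeric cq value {row_d['cq']!r} at row {pos} of {path}"
            ) from None
        try:
            rep = int(row_d["replicate"])
        except (TypeError, ValueError):
            raise FormatError(
                f"non-integer replicate index {row_d['replicate']!r} at row {pos} of {path}"
            ) from None
        key = (row_d["sample"], row_d["gene"], rep)
        if key in seen:
            raise ValidationError(
                f"duplicate (sample, gene, replicate) = {key} at row {pos} of {path}"
            )
        seen.add(key)
        records.append(
            CqRecord(
                sample_id=row_d["sample"],
                gene_id=row_d["gene"],
                replicate_index=rep,
                cq=cq,
                animal_id=row_d.get("animal"),
                condition=row_d.get("condition"),
            )
        )
    if not records:
        raise ValidationError(f"no Cq records in {path}")
    return CqDataset(records=records)


def _read_wide(path: Path) -> CqDataset:
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "gene":
        raise FormatError(
            f"wide Cq table {path} must have 'gene' as its first column, "
            f"got {df.columns[0]!r}"
        )
    df = df.set_index("gene")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene rows in {path}: {dup}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cq cell in {path}: {exc}") from None
    _check_cq_range(values)
    return CqDataset(matrix=CqMatrix(values))


def _check_cq_range(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    bad = ~((arr > CQ_MIN_VALID) & (arr <= CQ_MAX_VALID)) & ~np.isnan(arr)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"Cq value {arr[g, s]} out of ({CQ_MIN_VALID}, {CQ_MAX_VALID}] at "
            f"gene={values.index[g]!r} sample={values.columns[s]!r}"
        )


def records_to_frame(records: Iterable[CqRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in records],
            "animal": [r.animal_id for r in records],
            "condition": [r.condition for r in records],
            "gene": [r.gene_id for r in records],
            "replicate": [r.replicate_index for r in records],
            "cq": [r.cq for r in records],
        }
    )


def write_long_csv(records: Iterable[CqRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    if df["animal"].isna().all():
        df = df.drop(columns=["animal"])
    if "condition" in df and df["condition"].isna().all():
        df = df.drop(columns=["condition"])
    df.to_csv(path, index=False)


def collapse_triplicates(
    records: Iterable[CqRecord],
    sd_threshold: float = 0.5,
    drop_policy: DropPolicy = "error",
) -> tuple[CqMatrix, pd.DataFrame]:
    """Collapse technical replicates to one Cq per (gene, sample) cell.

    A cell's replicates are averaged when their sample SD (n-1 denominator)
    is below ``sd_threshold`` cycles; otherwise the cell is excluded and
    flagged ``high_sd``. Single-replicate cells are accepted (SD defined as
    0) and flagged ``single_replicate``. ``drop_policy`` controls what
    happens to the matrix when excluded cells would leave holes:

    - ``error``: raise, naming the offending cells (default);
    - ``drop_sample`` / ``drop_gene``: remove every sample/gene touching an
      excluded cell.

    Returns the collapsed matrix and a flags table with columns
    ``sample, gene, n_replicates, sd, flag``.
    """
    records = list(records)
    if not records:
        raise ValidationError("no Cq records to collapse")
    df = records_to_frame(records)
    gene_order = list(dict.fromkeys(df["gene"]))
    sample_order = list(dict.fromkeys(df["sample"]))

    grouped = df.groupby(["gene", "sample"], sort=False)["cq"]
    stats = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    stats["sd"] = stats["sd"].fillna(0.0)  # single replicate -> SD 0

    flags = []
    for row in stats.itertuples(index=False):
        if row.n == 1:
            flags.append((row.sample, row.gene, row.n, row.sd, "single_replicate"))
        elif row.sd >= sd_threshold:
            flags.append((row.sample, row.gene, row.n, row.sd, "high_sd"))
    flags_df = pd.DataFrame(
        flags, columns=["sample", "gene", "n_replicates", "sd", "flag"]
    )

    wide = stats.pivot(index="gene", columns="sample", values="mean")
    wide = wide.reindex(index=gene_order, columns=sample_order)
    # excluded cells become missing
    high_sd = flags_df[flags_df["flag"] == "high_sd"]
    for row in high_sd.itertuples(index=False):
        wide.loc[row.gene, row.sample] = np.nan

    if wide.isna().any().any():
        if drop_policy == "drop_sample":
            wide = wide.loc[:, ~wide.isna().any(axis=0)]
        elif drop_policy == "drop_gene":
            wide = wide.loc[~wide.isna().any(axis=1), :]
        else:
            cells = [
                (g, s)
                for g in wide.index
                for s in wide.columns
                if pd.isna(wide.loc[g, s])
            ]
            raise ValidationError(
                f"{len(cells)} cell(s) excluded by the replicate SD >= {sd_threshold} "
                f"rule or absent, leaving an incomplete matrix: {cells[:10]}; "
                "set drop_policy to 'drop_sample' or 'drop_gene' to proceed"
            )

    ann = (
        df.drop_duplicates("sample")
        .set_index("sample")[["animal", "condition"]]
        .reindex(wide.columns)
    )
    if ann["animal"].isna().all() and ann["condition"].isna().all():
        ann = None
    return CqMatrix(wide, ann), flags_df


def qc_summary(matrix: CqMatrix) -> QcSummary:
    """Per-gene Cq descriptives, transcript-level class, and range flags.

    Genes with mean Cq strictly below 25 cycles are classed "high"
    (highly transcribed), the rest "low"; a max-min range of 5 cycles or
    more raises ``range_flag``.
    """
    v = matrix.values
    per_gene = pd.DataFrame(
        {
            "mean_cq": v.mean(axis=1),
            "min_cq": v.min(axis=1),
            "max_cq": v.max(axis=1),
        }
    )
    per_gene["range"] = per_gene["max_cq"] - per_gene["min_cq"]
    per_gene["level"] = np.where(
        per_gene["mean_cq"] < HIGH_EXPRESSION_CQ_CUTOFF, "high", "low"
    )
    per_gene["range_flag"] = per_gene["range"] >= CQ_RANGE_FLAG_CYCLES
    counts = per_gene["level"].value_counts().to_dict()
    return QcSummary(per_gene, {"high": counts.get("high", 0), "low": counts.get("low", 0)})
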