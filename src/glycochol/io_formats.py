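"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain tab-separated text.  Readers validate and
reject malformed input rather than coercing it; every writer/reader pair
round-trips exactly for strings and to float precision for reals.

Coordinate conventions: BED intervals are 0-based half-open as in the BED
standard; SEG rows are 1-based inclusive on disk and converted to 0-based
half-open :class:`CnvSegment` records on read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalRecord",
    "GeneSetCollection",
    "CnvSegment",
    "GeneInterval",
    "Mutation",
    "MUTATION_CLASSES",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_seg",
    "write_seg",
    "read_bed",
    "write_bed",
    "read_clinical",
    "write_clinical",
    "read_mutations",
    "write_mutations",
    "clinical_to_frame",
    "DAYS_PER_MONTH",
]

#: Average month length used when converting day-scale survival to months.
DAYS_PER_MONTH = 30.44

SCALE_TAGS = ("counts", "tpm", "log10tpm", "standardized")
MUTATION_CLASSES = ("SNV", "INDEL")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A gene-by-sample abundance matrix with a scale annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Values must be finite, and non-negative unless the matrix
        is on the ``standardized`` scale.
    scale_tag
        One of ``counts``, ``tpm``, ``log10tpm`` or ``standardized``.
    """

    values: pd.DataFrame
    scale_tag: str = "counts"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dupes)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale_tag != "standardized" and arr.size and arr.min() < 0:
            raise ValueError(
                f"negative values not allowed on scale {self.scale_tag!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, scale_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, scale_tag=scale_tag)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale_tag)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids), :], self.scale_tag)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical annotation used by the survival and purity stages."""

    sample_id: str
    os_months: float
    event: int
    cohort: str
    purity: float | None = None
    metastatic: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.os_months) or self.os_months < 0:
            raise ValueError(
                f"sample {self.sample_id}: os_months must be >= 0, got {self.os_months}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id}: event must be 0/1")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"sample {self.sample_id}: purity outside [0, 1]")
        if self.metastatic is not None and self.metastatic not in (0, 1):
            raise ValueError(f"sample {self.sample_id}: metastatic must be 0/1")


@dataclass
class GeneSetCollection:
    """Named gene sets with a category per set.

    Categories are free labels; the subtyping pipeline looks for
    ``glycolytic`` and ``cholesterogenic``, the alignment stage for
    ``signature``.
    """

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def by_category(self, category: str) -> list[str]:
        """Union of member genes over all sets with the given category."""
        out: list[str] = []
        seen: set[str] = set()
        for name, members in self.sets.items():
            if self.categories.get(name) == category:
                for g in members:
                    if g not in seen:
                        seen.add(g)
                        out.append(g)
        return out


@dataclass(frozen=True)
class CnvSegment:
    """A segmented copy-number call, 0-based half-open coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    seg_mean: float
    copy_status: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not math.isfinite(self.seg_mean):
            raise ValueError("seg_mean must be finite")


@dataclass(frozen=True)
class GeneInterval:
    """Gene coding interval, 0-based half-open (BED convention)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Mutation:
    """A simple per-sample small-variant record (SNV or INDEL)."""

    gene: str
    sample_id: str
    mut_class: str

    def __post_init__(self) -> None:
        if self.mut_class not in MUTATION_CLASSES:
            raise ValueError(
                f"mutation class {self.mut_class!r} not in {MUTATION_CLASSES}"
            )


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale_tag: str = "counts") -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene IDs, header sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene rows {dupes}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression values") from exc
    return ExpressionMatrix(values=df, scale_tag=scale_tag)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, categories: dict[str, str] | None = None) -> GeneSetCollection:
    """Read GMT: one set per line, ``name<TAB>description<TAB>member...``.

    Empty members produced by trailing tabs are dropped with a warning and
    duplicate members within one line are deduplicated with a warning.
    Set categories may be supplied explicitly or are parsed from an optional
    ``category=<label>`` token in the description field.
    """
    sets: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members: list[str] = []
            seen: set[str] = set()
            for raw in fields[2:]:
                g = raw.strip()
                if not g:
                    warnings.warn(f"{path}:{lineno}: empty member dropped")
                    continue
                if g in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate member {g!r} dropped")
                    continue
                seen.add(g)
                members.append(g)
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            if desc.startswith("category="):
                cats[name] = desc.split("=", 1)[1]
    if categories:
        cats.update(categories)
    return GeneSetCollection(sets=sets, categories=cats)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            cat = collection.categories.get(name)
            desc = f"category={cat}" if cat else "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def read_seg(path: str | Path) -> list[CnvSegment]:
    """Read a SEG file (1-based inclusive on disk -> 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SEG columns {missing}")
    has_copy = "copy_status" in df.columns
    segments: list[CnvSegment] = []
    for row in df.itertuples(index=False):
        vals = dict(zip(df.columns, row))
        start1 = int(vals["loc.start"])
        end1 = int(vals["loc.end"])
        if start1 >= end1:
            raise ValueError(
                f"{path}: segment {vals['sample']} {vals['chrom']}:{start1}-{end1} "
                "has loc.start >= loc.end"
            )
        copy_status = None
        if has_copy and not pd.isna(vals["copy_status"]):
            copy_status = int(vals["copy_status"])
        segments.append(
            CnvSegment(
                sample_id=str(vals["sample"]).strip(),
                chrom=str(vals["chrom"]).strip(),
                start=start1 - 1,
                end=end1,
                n_probes=int(vals["num.mark"]),
                seg_mean=float(vals["seg.mean"]),
                copy_status=copy_status,
            )
        )
    return segments


def write_seg(segments: Iterable[CnvSegment], path: str | Path) -> None:
    rows = []
    any_copy = False
    seglist = list(segments)
    for s in seglist:
        any_copy = any_copy or s.copy_status is not None
    with open(path, "w") as fh:
        cols = list(_SEG_COLUMNS) + (["copy_status"] if any_copy else [])
        fh.write("\t".join(cols) + "\n")
        for s in seglist:
            row = [
                s.sample_id,
                s.chrom,
                str(s.start + 1),
                str(s.end),
                str(s.n_probes),
                f"{s.seg_mean:.17g}",
            ]
            if any_copy:
                row.append("" if s.copy_status is None else str(s.copy_status))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read a 4-column BED file of gene coding intervals."""
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
            chrom, start, end, name = (f.strip() for f in fields[:4])
            intervals.append(
                GeneInterval(gene_id=name, chrom=chrom, start=int(start), end=int(end))
            )
    return intervals


def write_bed(intervals: Iterable[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\n")


# ---------------------------------------------------------------------------
# clinical TSV
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ["sample_id", "os_months", "event", "cohort", "purity", "metastatic"]


def read_clinical(path: str | Path, time_unit: str = "months") -> list[ClinicalRecord]:
    """Read the clinical table.

    ``time_unit="days"`` converts survival to months by dividing by
    :data:`DAYS_PER_MONTH`.
    """
    if time_unit not in ("months", "days"):
        raise ValueError("time_unit must be 'months' or 'days'")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _CLINICAL_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    records: list[ClinicalRecord] = []
    for vals in df.to_dict(orient="records"):
        t = float(vals["os_months"])
        if time_unit == "days":
            t = t / DAYS_PER_MONTH
        purity = vals.get("purity")
        purity = None if purity is None or pd.isna(purity) else float(purity)
        meta = vals.get("metastatic")
        meta = None if meta is None or pd.isna(meta) else int(meta)
        records.append(
            ClinicalRecord(
                sample_id=str(vals["sample_id"]).strip(),
                os_months=t,
                event=int(vals["event"]),
                cohort=str(vals["cohort"]).strip(),
                purity=purity,
                metastatic=meta,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample_id rows")
    return records


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "os_months": [r.os_months for r in records],
            "event": [r.event for r in records],
            "cohort": [r.cohort for r in records],
            "purity": [np.nan if r.purity is None else r.purity for r in records],
            "metastatic": [
                np.nan if r.metastatic is None else r.metastatic for r in records
            ],
        }
    )
    return df.set_index("sample_id", drop=False)


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CLINICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        f"{r.os_months:.17g}",
                        str(r.event),
                        r.cohort,
                        "" if r.purity is None else f"{r.purity:.17g}",
                        "" if r.metastatic is None else str(r.metastatic),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# mutation TSV
# ---------------------------------------------------------------------------


def read_mutations(path: str | Path) -> list[Mutation]:
    """Read the mutation table (columns: gene, sample, class)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "sample", "class") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mutation columns {missing}")
    return [
        Mutation(
            gene=str(vals["gene"]).strip(),
            sample_id=str(vals["sample"]).strip(),
            mut_class=str(vals["class"]).strip(),
        )
        for vals in df.to_dict(orient="records")
    ]


def write_mutations(mutations: Sequence[Mutation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsample\tclass\n")
        for m in mutations:
            fh.write(f"{m.gene}\t{m.sample_id}\t{m.mut_class}\n")
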