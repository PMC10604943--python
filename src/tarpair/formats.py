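"""Shared data model and file formats.

Defines the in-memory containers used by every pipeline stage
(:class:`TranscriptRecord`, :class:`CountMatrix`, :class:`CtTable`) and
readers/writers for the plain-text formats they travel in: 9-field GTF
(1-based, inclusive coordinates — the convention assumed by all window
arithmetic downstream), TSV count matrices, and TSV Ct tables.

The GTF reader accepts both transcript+exon files (StringTie style) and
exon-only files (NONCODE style): when a transcript has no ``transcript``
feature line, its span is the min/max of its exons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptRecord",
    "CountMatrix",
    "CtTable",
    "GtfParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_count_matrix",
    "read_library_sizes",
    "write_results",
    "read_results",
    "read_ct_table",
    "write_ct_table",
]

BIOTYPES = ("mRNA", "lncRNA", "novel")


class GtfParseError(ValueError):
    """A GTF line that cannot be parsed; message names the line number."""


class ValidationError(ValueError):
    """Structurally parseable input violating a data-model invariant."""


@dataclass
class TranscriptRecord:
    """One annotated transcript.

    Coordinates are 1-based and inclusive on both ends. ``exons`` is the
    sorted, non-overlapping list of (start, end) pairs; the transcript
    span covers all of them.  ``biotype`` is one of ``mRNA``, ``lncRNA``
    or ``novel`` (novel transcripts are resolved by the coding-potential
    consensus later, not here).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "novel"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"transcript {self.transcript_id}: invalid span ({self.start}, {self.end})"
            )
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"transcript {self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = 0
        for a, b in self.exons:
            if a > b:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon ({a}, {b}) has end < start"
                )
            if a <= prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping or unsorted exons"
                )
            if a < self.start or b > self.end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon ({a}, {b}) outside span"
                )
            prev_end = b

    @property
    def effective_length(self) -> int:
        """Exonic length in bp (sum of end - start + 1 over exons)."""
        return sum(b - a + 1 for a, b in self.exons)


@dataclass
class CountMatrix:
    """Raw integer counts, transcripts x samples.

    ``library_size`` may exceed the in-matrix column sum (total mapped
    fragments can include reads outside the final matrix) but must be
    positive for every sample.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_of: dict[str, str]
    library_size: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        nt, ns = self.counts.shape
        if nt != len(self.transcript_ids) or ns != len(self.sample_ids):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match id lists "
                f"({len(self.transcript_ids)} transcripts, {len(self.sample_ids)} samples)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at transcript {self.transcript_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples missing a group label: {missing}")
        for s in self.sample_ids:
            if self.library_size.get(s, 0) <= 0:
                raise ValidationError(
                    f"sample {s!r}: library size must be > 0 "
                    f"(got {self.library_size.get(s)})"
                )

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.transcript_ids, columns=self.sample_ids)


@dataclass
class CtTable:
    """qPCR Ct measurements in long form.

    ``data`` has columns target_id, sample_id, group, replicate, ct;
    ``reference_ids`` names the housekeeping targets (e.g. HPRT, GAPDH)
    used for within-sample normalization.
    """

    data: pd.DataFrame
    reference_ids: list[str]

    REQUIRED = ("target_id", "sample_id", "group", "replicate", "ct")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"Ct table missing columns: {missing_cols}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be > 0")
        targets = set(self.data["target_id"])
        refs = set(self.reference_ids)
        if not refs:
            raise ValidationError("at least one reference (housekeeping) target required")
        if not refs <= targets:
            raise ValidationError(
                f"reference targets absent from table: {sorted(refs - targets)}"
            )

    @property
    def target_ids(self) -> list[str]:
        return sorted(set(self.data["target_id"]) - set(self.reference_ids))


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse a GTF file into one :class:`TranscriptRecord` per transcript.

    Accepts transcript+exon and exon-only dialects.  Biotype comes from a
    ``transcript_biotype`` or ``gene_biotype`` attribute and defaults to
    ``novel`` when absent.  Raises :class:`GtfParseError` naming the line
    number on a malformed line, :class:`ValidationError` on coordinate or
    duplicate-transcript violations.
    """
    path = Path(path)
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
                ) from None
            if end < start:
                raise ValidationError(f"{path.name}:{lineno}: end {end} < start {start}")
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"{path.name}:{lineno}: missing transcript_id attribute")
            if tid not in meta:
                order.append(tid)
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("transcript_biotype")
                    or attrs.get("gene_biotype")
                    or "novel",
                }
            if feature == "transcript":
                if tid in spans:
                    raise ValidationError(
                        f"{path.name}:{lineno}: duplicate transcript feature for {tid!r}"
                    )
                spans[tid] = {"start": start, "end": end}
            elif feature == "exon":
                exons.setdefault(tid, []).append((start, end))

    records = []
    for tid in order:
        m = meta[tid]
        ex = sorted(exons.get(tid, []))
        if tid in spans:
            start, end = spans[tid]["start"], spans[tid]["end"]
        elif ex:
            start, end = ex[0][0], max(b for _, b in ex)
        else:
            continue  # attribute-only line types (gene, CDS, ...) with no span info
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                start=start,
                end=end,
                exons=ex,
                biotype=m["biotype"] if m["biotype"] in BIOTYPES else "novel",
            )
        )
    return records


def write_gtf(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as transcript+exon GTF lines (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'transcript_biotype "{r.biotype}";'
            )
            fh.write(
                f"{r.chrom}\ttarpair\ttranscript\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
            for a, b in r.exons:
                fh.write(
                    f"{r.chrom}\ttarpair\texon\t{a}\t{b}\t.\t{r.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# count matrix / generic tables


def read_count_matrix(
    path: str | Path,
    groups: Mapping[str, str],
    library_size: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Read a TSV count matrix (transcript rows, sample columns).

    ``library_size`` defaults to in-matrix column sums; pass the true
    per-sample mapped-fragment totals when they are known (column sums
    undercount whenever reads map outside the final matrix).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) if arr.dtype != object else np.zeros(arr.shape, bool)
    if arr.dtype == object or bad.any() or not np.all(arr.astype(float) == np.floor(arr.astype(float))):
        fl = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(fl) | (fl != np.floor(fl))
        if bad.any():
            t, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-integer cell at row {df.index[t]!r}, column {df.columns[s]!r}"
            )
        arr = fl.astype(np.int64)
    if library_size is None:
        library_size = {s: int(c) for s, c in zip(df.columns, arr.sum(axis=0))}
    return CountMatrix(
        transcript_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=arr.astype(np.int64),
        group_of={s: groups[s] for s in df.columns} if all(s in groups for s in df.columns)
        else _fail_missing_groups(df.columns, groups),
        library_size=dict(library_size),
    )


def _fail_missing_groups(samples: Sequence[str], groups: Mapping[str, str]):
    missing = [s for s in samples if s not in groups]
    raise ValidationError(f"samples missing from group map: {missing}")


def read_library_sizes(path: str | Path) -> dict[str, int]:
    """Read a sidecar TSV of per-sample mapped-fragment totals
    (columns sample_id, library_size)."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "library_size"} <= set(df.columns):
        raise ValidationError("library-size table needs sample_id and library_size columns")
    return {str(s): int(n) for s, n in zip(df["sample_id"], df["library_size"])}


def write_results(table: pd.DataFrame, path: str | Path, float_digits: int = 6) -> None:
    """Write a results table as TSV.

    String and integer columns round-trip bit-identically through
    :func:`read_results`; reals are serialized with ``float_digits``
    significant digits.
    """
    if table.columns.empty:
        raise ValidationError("results table must have a non-empty header")
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ct_table(path: str | Path, reference_ids: Sequence[str]) -> CtTable:
    """Read a long-form qPCR Ct TSV (target_id, sample_id, group, replicate, ct)."""
    df = pd.read_csv(path, sep="\t")
    return CtTable(data=df, reference_ids=list(reference_ids))


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False)
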