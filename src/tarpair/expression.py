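"""FPKM quantification and expression-level prefiltering.

FPKM (fragments per kilobase of transcript per million mapped fragments)
for transcript t in sample s is

    fpkm[t, s] = counts[t, s] * 1e9 / (effective_length[t] * library_size[s])

with effective length the exonic length (sum of exon spans), not the
genomic span.  The prefilter drops transcripts that never reach a
minimum FPKM in enough samples; rank correlations on all-zero vectors
are undefined, so the pairing stage expects prefiltered input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import CountMatrix, TranscriptRecord, ValidationError

__all__ = ["ExpressionMatrix", "compute_fpkm", "filter_expressed"]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Length- and depth-normalized expression (FPKM), transcripts x samples."""

    transcript_ids: list[str]
    sample_ids: list[str]
    fpkm: np.ndarray
    effective_length: dict[str, int]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValidationError("FPKM matrix shape does not match id lists")
        if not np.all(np.isfinite(self.fpkm)) or (self.fpkm < 0).any():
            raise ValidationError("FPKM values must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpkm, index=self.transcript_ids, columns=self.sample_ids)

    def subset(self, transcript_ids: list[str]) -> "ExpressionMatrix":
        idx = {t: i for i, t in enumerate(self.transcript_ids)}
        rows = [idx[t] for t in transcript_ids]
        return ExpressionMatrix(
            transcript_ids=list(transcript_ids),
            sample_ids=list(self.sample_ids),
            fpkm=self.fpkm[rows, :],
            effective_length={t: self.effective_length[t] for t in transcript_ids},
            group_of=dict(self.group_of),
        )


def compute_fpkm(counts: CountMatrix, annotation: list[TranscriptRecord]) -> ExpressionMatrix:
    """Convert raw counts to FPKM using exonic lengths from the annotation.

    Raises if any transcript in the matrix lacks an annotation record or
    has zero effective length.
    """
    length_of = {r.transcript_id: r.effective_length for r in annotation}
    missing = [t for t in counts.transcript_ids if t not in length_of]
    if missing:
        raise ValidationError(
            f"{len(missing)} transcripts missing annotation, e.g. {missing[:5]}"
        )
    lengths = np.array([length_of[t] for t in counts.transcript_ids], dtype=float)
    if (lengths <= 0).any():
        bad = [t for t, l in zip(counts.transcript_ids, lengths) if l <= 0]
        raise ValidationError(f"zero effective length for {bad[:5]}")
    libs = np.array([counts.library_size[s] for s in counts.sample_ids], dtype=float)
    fpkm = counts.counts * 1e9 / (lengths[:, None] * libs[None, :])
    return ExpressionMatrix(
        transcript_ids=list(counts.transcript_ids),
        sample_ids=list(counts.sample_ids),
        fpkm=fpkm,
        effective_length={t: int(length_of[t]) for t in counts.transcript_ids},
        group_of=dict(counts.group_of),
    )


def filter_expressed(
    expr: ExpressionMatrix, min_fpkm: float = 0.1, min_samples: int | None = None
) -> ExpressionMatrix:
    """Keep transcripts with FPKM >= ``min_fpkm`` in >= ``min_samples`` samples.

    ``min_samples`` defaults to half the samples (rounded up).  Order is
    preserved.  ``min_fpkm=0, min_samples=0`` is the identity.
    """
    if min_fpkm < 0:
        raise ValidationError("min_fpkm must be >= 0")
    n_samples = len(expr.sample_ids)
    if min_samples is None:
        min_samples = (n_samples + 1) // 2
    if not 0 <= min_samples <= n_samples:
        raise ValidationError(f"min_samples must be in [0, {n_samples}]")
    keep = (expr.fpkm >= min_fpkm).sum(axis=1) >= min_samples
    kept_ids = [t for t, k in zip(expr.transcript_ids, keep) if k]
    n_dropped = len(expr.transcript_ids) - len(kept_ids)
    if n_dropped:
        log.info(
            "expression prefilter (FPKM >= %g in >= %d samples) dropped %d of %d transcripts",
            min_fpkm, min_samples, n_dropped, len(expr.transcript_ids),
        )
    return expr.subset(kept_ids)
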