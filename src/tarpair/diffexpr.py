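"""Poisson exact-test differential expression with BH FDR.

The test compares one tag count per library between two libraries of
known sizes (the Audic-Claverie test).  Conditional on the count x in
library 1, the count y' in library 2 follows

    p(y'|x) = (N2/N1)^y' * (x+y')! / (x! * y'! * (1 + N2/N1)^(x+y'+1))

which is the negative-binomial NB(x+1, N1/(N1+N2)) mass in y'.  The
two-sided p-value doubles the smaller tail; because the conditional rule
is not exactly exchangeable in (x, y), we take the more significant of
the two conditioning orientations, which makes the test exactly
symmetric under (x, N1) <-> (y, N2).

Replicates are pooled by summation within group before testing (the test
is a two-library test); a warning is logged when the replicate
variance/mean ratio suggests overdispersion the Poisson model ignores.

Two significance tiers mirror the screen used in FUS-mutant iPSC
transcriptome comparisons: *significant* requires fold change >= 2 (either
direction) and FDR <= 0.001; *candidate* requires p < 0.05 and
|log2FC| >= 1.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .formats import CountMatrix, ValidationError

__all__ = [
    "DEThresholds",
    "DEResult",
    "ac_test",
    "log2_fold_change",
    "bh_adjust",
    "run_de",
    "compare_overlap",
    "de_to_frame",
]

log = logging.getLogger(__name__)

TIER_ORDER = {"significant": 0, "candidate": 1, "ns": 2}


@dataclass(frozen=True)
class DEThresholds:
    """Significance thresholds for the two-tier screen."""

    fc_min: float = 2.0          # fold-change bound for the significant tier
    fdr_max: float = 0.001       # BH FDR bound for the significant tier
    p_max: float = 0.05          # raw p bound for the candidate tier
    abs_log2fc_min: float = 1.5  # |log2FC| bound for the candidate tier
    pseudocount: float = 0.01    # FPKM pseudocount for fold changes only


@dataclass
class DEResult:
    """Per-transcript differential-expression outcome (B relative to A)."""

    transcript_id: str
    mean_fpkm_A: float
    mean_fpkm_B: float
    fold_change: float
    log2fc: float
    p_value: float
    fdr: float = 1.0
    tier: str = "ns"
    direction: str = "none"


def ac_test(x, y, N1, N2):
    """Two-sided exact Poisson test of count ``x`` (library size ``N1``)
    against count ``y`` (library size ``N2``).

    Accepts scalars or arrays (broadcast).  Exactly symmetric:
    ``ac_test(x, y, N1, N2) == ac_test(y, x, N2, N1)``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("counts must be finite")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("counts must be >= 0")
    if np.any(np.asarray(N1) <= 0) or np.any(np.asarray(N2) <= 0):
        raise ValidationError("library sizes must be > 0")
    p1 = N1 / (N1 + N2)
    p2 = N2 / (N1 + N2)
    # orientation 1: Y | x  ~  NB(x+1, p1);  orientation 2: X | y ~ NB(y+1, p2)
    lower1 = stats.nbinom.cdf(y, x + 1, p1)
    upper1 = stats.nbinom.sf(y - 1, x + 1, p1)
    lower2 = stats.nbinom.cdf(x, y + 1, p2)
    upper2 = stats.nbinom.sf(x - 1, y + 1, p2)
    p = 2.0 * np.minimum.reduce([lower1, upper1, lower2, upper2])
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def log2_fold_change(mean_A: float, mean_B: float, pseudo: float = 0.01) -> float:
    """log2((mean_B + pseudo) / (mean_A + pseudo)); antisymmetric under swap."""
    if mean_A < 0 or mean_B < 0 or pseudo < 0:
        raise ValidationError("means and pseudocount must be >= 0")
    if pseudo == 0 and (mean_A == 0 or mean_B == 0):
        raise ValidationError("pseudocount required when a mean is zero")
    return math.log2((mean_B + pseudo) / (mean_A + pseudo))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _assign_tier(fc: float, log2fc: float, p: float, q: float, th: DEThresholds) -> str:
    if (fc >= th.fc_min or fc <= 1.0 / th.fc_min) and q <= th.fdr_max:
        return "significant"
    if p < th.p_max and abs(log2fc) >= th.abs_log2fc_min:
        return "candidate"
    return "ns"


def run_de(
    counts: CountMatrix,
    expr: ExpressionMatrix,
    group_A: str,
    group_B: str,
    thresholds: DEThresholds = DEThresholds(),
) -> list[DEResult]:
    """Differential expression of ``group_B`` relative to ``group_A``.

    Counts are pooled (summed) within each group, library sizes likewise;
    the exact test is applied per transcript and BH adjustment runs over
    all tested transcripts.  Fold changes come from mean FPKM with a
    pseudocount, leaving the exact test untouched.
    """
    samples_A = counts.samples_in_group(group_A)
    samples_B = counts.samples_in_group(group_B)
    if not samples_A or not samples_B:
        raise ValidationError(
            f"both groups need >= 1 sample (got {len(samples_A)} in {group_A!r}, "
            f"{len(samples_B)} in {group_B!r})"
        )
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    idx_A = [col[s] for s in samples_A]
    idx_B = [col[s] for s in samples_B]
    x = counts.counts[:, idx_A].sum(axis=1)
    y = counts.counts[:, idx_B].sum(axis=1)
    N1 = sum(counts.library_size[s] for s in samples_A)
    N2 = sum(counts.library_size[s] for s in samples_B)

    for label, block in ((group_A, counts.counts[:, idx_A]), (group_B, counts.counts[:, idx_B])):
        if block.shape[1] >= 2:
            m = block.mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(m > 0, block.var(axis=1, ddof=1) / np.where(m > 0, m, 1), 1.0)
            med = float(np.median(ratio[m > 0])) if (m > 0).any() else 1.0
            if med > 2:
                log.warning(
                    "group %r: median variance/mean ratio %.2f > 2; counts look "
                    "overdispersed relative to the Poisson model of the exact test",
                    label, med,
                )

    p = ac_test(x, y, float(N1), float(N2))
    q = bh_adjust(p)

    ef = expr.to_frame()
    mean_A = ef[samples_A].mean(axis=1).reindex(counts.transcript_ids)
    mean_B = ef[samples_B].mean(axis=1).reindex(counts.transcript_ids)
    if mean_A.isna().any():
        missing = list(mean_A.index[mean_A.isna()])[:5]
        raise ValidationError(f"transcripts missing from expression matrix, e.g. {missing}")

    results = []
    for i, tid in enumerate(counts.transcript_ids):
        a, b = float(mean_A.iloc[i]), float(mean_B.iloc[i])
        l2 = log2_fold_change(a, b, thresholds.pseudocount)
        fc = 2.0 ** l2
        tier = _assign_tier(fc, l2, float(p[i]), float(q[i]), thresholds)
        direction = "none" if l2 == 0 else ("up" if l2 > 0 else "down")
        results.append(
            DEResult(
                transcript_id=tid, mean_fpkm_A=a, mean_fpkm_B=b,
                fold_change=fc, log2fc=l2, p_value=float(p[i]), fdr=float(q[i]),
                tier=tier, direction=direction,
            )
        )
    return results


def compare_overlap(
    de_A: list[DEResult], de_B: list[DEResult], tier: str = "significant"
) -> tuple[int, int, int]:
    """Venn-style overlap of transcripts at the given tier or better.

    Returns (n only in A, n shared, n only in B).
    """
    if tier not in TIER_ORDER:
        raise ValidationError(f"unknown tier {tier!r}")
    rank = TIER_ORDER[tier]
    set_A = {r.transcript_id for r in de_A if TIER_ORDER[r.tier] <= rank}
    set_B = {r.transcript_id for r in de_B if TIER_ORDER[r.tier] <= rank}
    return len(set_A - set_B), len(set_A & set_B), len(set_B - set_A)


def de_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "mean_fpkm_A": [r.mean_fpkm_A for r in results],
            "mean_fpkm_B": [r.mean_fpkm_B for r in results],
            "fold_change": [r.fold_change for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "tier": [r.tier for r in results],
            "direction": [r.direction for r in results],
        }
    )
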