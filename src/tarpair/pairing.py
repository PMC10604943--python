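"""lncRNA-mRNA target-pair prediction and the TAR-pair fold cascade.

Candidate pairs are lncRNA x mRNA combinations whose expression
correlates across all samples with both Spearman and Pearson
coefficients at or above a threshold (default 0.6).  Each candidate is
then classified:

* **cis** — the lncRNA gene span intersects a window around the mRNA
  extending 10 kb upstream of the TSS and 20 kb downstream of the TES,
  oriented by the mRNA's strand (for a minus-strand mRNA the upstream
  side is the higher-coordinate side).  Gene-body overlap is cis; the
  window boundary is inclusive.
* **trans** — outside the window, but supported by a predicted
  RNA-RNA hybridization energy at or below a cutoff (default
  -30 kcal/mol; energies come from an external table, RNAplex-style).
* otherwise rejected.

TAR pairs are target pairs whose two members are both differentially
expressed; ``build_tarpairs`` applies the 2-fold cross-referencing
filter, ``refine_tarpairs`` the 5-fold cascade on the smaller of the two
member fold changes (folds below 1 are inverted first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, TIER_ORDER
from .expression import ExpressionMatrix
from .formats import TranscriptRecord, ValidationError

__all__ = [
    "TargetPair",
    "TarPairHit",
    "correlate",
    "candidate_pairs",
    "classify_cis_trans",
    "span_distance",
    "classify_pairs",
    "read_energy_table",
    "build_tarpairs",
    "refine_tarpairs",
    "tarpairs_to_frame",
]

log = logging.getLogger(__name__)

DEFAULT_UP_BP = 10_000
DEFAULT_DOWN_BP = 20_000
DEFAULT_ENERGY_MAX = -30.0


@dataclass
class TargetPair:
    """A correlated lncRNA-mRNA pair with its cis/trans classification."""

    lnc_id: str
    mrna_id: str
    pearson: float
    spearman: float
    mode: str  # "cis" | "trans"
    distance_bp: int | None = None  # cis only: closest-edge gene-span distance
    energy: float | None = None     # trans only: kcal/mol


@dataclass
class TarPairHit:
    """A TargetPair whose members are both differentially expressed."""

    pair: TargetPair
    lnc_de: DEResult
    mrna_de: DEResult
    min_abs_fold: float
    congruence: str  # "congruent" | "inverse"


def correlate(x, y) -> tuple[float, float]:
    """(Pearson, Spearman) of two expression vectors.

    Spearman is Pearson on average ranks (ties get the mean rank).
    Raises on length mismatch, fewer than 3 points, or a constant vector
    (undefined correlation — callers must prefilter).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError("need >= 3 points for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation matrix between rows of a and rows of b."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def candidate_pairs(
    expr: ExpressionMatrix,
    lnc_ids: list[str],
    mrna_ids: list[str],
    rho_min: float = 0.6,
    log_transform: bool = False,
) -> list[tuple[str, str, float, float]]:
    """All lncRNA x mRNA pairs with Pearson >= rho_min AND Spearman >= rho_min.

    Correlations are computed jointly across every sample of every
    group, on raw FPKM by default (``log_transform`` applies log1p
    first; Spearman is unaffected, Pearson becomes a correlation of
    log-expression).  Constant-expression transcripts are skipped with
    a warning.  Output is sorted by (lnc_id, mrna_id).
    """
    if set(lnc_ids) & set(mrna_ids):
        raise ValidationError("lncRNA and mRNA id sets must be disjoint")
    if not lnc_ids or not mrna_ids:
        log.warning("candidate_pairs: empty id set (%d lncRNAs, %d mRNAs)",
                    len(lnc_ids), len(mrna_ids))
        return []
    ef = expr.to_frame()
    if log_transform:
        ef = np.log1p(ef)
    present_lnc = [t for t in lnc_ids if t in ef.index]
    present_mrna = [t for t in mrna_ids if t in ef.index]
    a = ef.loc[present_lnc].to_numpy(dtype=float)
    b = ef.loc[present_mrna].to_numpy(dtype=float)
    ok_a = np.ptp(a, axis=1) > 0
    ok_b = np.ptp(b, axis=1) > 0
    if (~ok_a).any() or (~ok_b).any():
        log.warning("skipping %d constant-expression transcripts",
                    int((~ok_a).sum() + (~ok_b).sum()))
    lnc_keep = [t for t, k in zip(present_lnc, ok_a) if k]
    mrna_keep = [t for t, k in zip(present_mrna, ok_b) if k]
    if not lnc_keep or not mrna_keep:
        return []
    a, b = a[ok_a], b[ok_b]
    pear = _rowwise_corr(a, b)
    ranks_a = np.apply_along_axis(stats.rankdata, 1, a)
    ranks_b = np.apply_along_axis(stats.rankdata, 1, b)
    spear = _rowwise_corr(ranks_a, ranks_b)
    out = []
    hit_i, hit_j = np.where((pear >= rho_min) & (spear >= rho_min))
    for i, j in zip(hit_i, hit_j):
        out.append((lnc_keep[i], mrna_keep[j], float(pear[i, j]), float(spear[i, j])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def span_distance(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Closest-edge distance between two gene spans (0 when overlapping)."""
    if a.start > b.end:
        return a.start - b.end
    if b.start > a.end:
        return b.start - a.end
    return 0


def classify_cis_trans(
    lnc: TranscriptRecord,
    mrna: TranscriptRecord,
    up_bp: int = DEFAULT_UP_BP,
    down_bp: int = DEFAULT_DOWN_BP,
    energy: float | None = None,
    energy_max: float = DEFAULT_ENERGY_MAX,
) -> str:
    """Classify a pair as "cis", "trans" or "rejected".

    The window is anchored on the mRNA and oriented by the mRNA's
    strand; the lncRNA's own strand is ignored.  Boundary inclusive.
    """
    if mrna.strand not in ("+", "-") or lnc.strand not in ("+", "-"):
        raise ValidationError("both records need a '+' or '-' strand")
    if lnc.chrom == mrna.chrom:
        if mrna.strand == "+":
            win_lo, win_hi = mrna.start - up_bp, mrna.end + down_bp
        else:
            win_lo, win_hi = mrna.start - down_bp, mrna.end + up_bp
        if lnc.start <= win_hi and lnc.end >= win_lo:
            return "cis"
    if energy is not None and energy <= energy_max:
        return "trans"
    return "rejected"


def classify_pairs(
    pairs: list[tuple[str, str, float, float]],
    annotation: dict[str, TranscriptRecord],
    energies: dict[tuple[str, str], float] | None = None,
    up_bp: int = DEFAULT_UP_BP,
    down_bp: int = DEFAULT_DOWN_BP,
    energy_max: float = DEFAULT_ENERGY_MAX,
) -> list[TargetPair]:
    """Apply cis/trans classification to candidate pairs; rejected pairs drop."""
    energies = energies or {}
    out = []
    for lnc_id, mrna_id, pearson, spearman in pairs:
        lnc, mrna = annotation[lnc_id], annotation[mrna_id]
        energy = energies.get((lnc_id, mrna_id))
        mode = classify_cis_trans(lnc, mrna, up_bp, down_bp, energy, energy_max)
        if mode == "cis":
            out.append(TargetPair(lnc_id, mrna_id, pearson, spearman, "cis",
                                  distance_bp=span_distance(lnc, mrna)))
        elif mode == "trans":
            out.append(TargetPair(lnc_id, mrna_id, pearson, spearman, "trans",
                                  energy=energy))
    return out


def read_energy_table(path) -> dict[tuple[str, str], float]:
    """Read a TSV of predicted hybridization energies (lnc_id, mrna_id, energy).

    Duplicate keys: last row wins, with a warning.  Positive energies are
    accepted with a warning (they never pass the default cutoff).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"lnc_id", "mrna_id", "energy"}
    if not required <= set(df.columns):
        raise ValidationError(f"energy table needs columns {sorted(required)}")
    energies = pd.to_numeric(df["energy"], errors="coerce")
    if energies.isna().any():
        bad = df.loc[energies.isna(), "energy"].iloc[0]
        raise ValidationError(f"non-numeric energy value {bad!r}")
    out: dict[tuple[str, str], float] = {}
    for lnc_id, mrna_id, energy in zip(df["lnc_id"], df["mrna_id"], energies):
        key = (str(lnc_id), str(mrna_id))
        if key in out:
            log.warning("duplicate energy entry for %s; keeping the last", key)
        if energy > 0:
            log.warning("positive hybridization energy %.2f for %s", energy, key)
        out[key] = float(energy)
    return out


def _folded_up(fold: float) -> float:
    return fold if fold >= 1.0 else 1.0 / fold


def build_tarpairs(
    pairs: list[TargetPair],
    de_lnc: list[DEResult],
    de_mrna: list[DEResult],
    tier: str = "significant",
    fold_min: float = 2.0,
) -> list[TarPairHit]:
    """Cross-reference target pairs against DE lncRNAs (DELs) and DE
    mRNAs (DEGs).

    Keeps pairs whose lncRNA and mRNA are both at the given tier or
    better and whose members each changed by >= fold_min (in either
    direction).  Congruence records whether the two members moved the
    same way.
    """
    if tier not in TIER_ORDER:
        raise ValidationError(f"unknown tier {tier!r}")
    lnc_idx = {r.transcript_id: r for r in de_lnc}
    mrna_idx = {r.transcript_id: r for r in de_mrna}
    collisions = set(lnc_idx) & set(mrna_idx)
    if collisions:
        raise ValidationError(
            f"ids present in both lncRNA and mRNA DE sets: {sorted(collisions)[:5]}"
        )
    rank = TIER_ORDER[tier]
    hits = []
    for p in pairs:
        ld = lnc_idx.get(p.lnc_id)
        md = mrna_idx.get(p.mrna_id)
        if ld is None or md is None:
            continue
        if TIER_ORDER[ld.tier] > rank or TIER_ORDER[md.tier] > rank:
            continue
        f_l, f_m = _folded_up(ld.fold_change), _folded_up(md.fold_change)
        if f_l < fold_min or f_m < fold_min:
            continue
        congruence = "congruent" if ld.direction == md.direction else "inverse"
        hits.append(TarPairHit(p, ld, md, min_abs_fold=min(f_l, f_m),
                               congruence=congruence))
    return hits


def refine_tarpairs(hits: list[TarPairHit], fold_min: float = 5.0) -> list[TarPairHit]:
    """Keep hits whose weaker member still changed by >= fold_min.

    ``refine_tarpairs(build_tarpairs(..., fold_min=2), 5)`` is identical
    to ``build_tarpairs(..., fold_min=5)`` on the same inputs.
    """
    return [h for h in hits if h.min_abs_fold >= fold_min]


def tarpairs_to_frame(hits: list[TarPairHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [h.pair.lnc_id for h in hits],
            "mrna_id": [h.pair.mrna_id for h in hits],
            "pearson": [h.pair.pearson for h in hits],
            "spearman": [h.pair.spearman for h in hits],
            "mode": [h.pair.mode for h in hits],
            "distance_bp": [h.pair.distance_bp for h in hits],
            "energy": [h.pair.energy for h in hits],
            "lnc_log2fc": [h.lnc_de.log2fc for h in hits],
            "mrna_log2fc": [h.mrna_de.log2fc for h in hits],
            "min_abs_fold": [h.min_abs_fold for h in hits],
            "congruence": [h.congruence for h in hits],
        }
    )
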