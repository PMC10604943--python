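"""Coding-potential consensus classification of novel transcripts.

Novel transcripts are labelled mRNA or lncRNA from up to four
independent signals: CPC score, CNCI score, txCdsPredict score and the
presence of a pfam domain hit.  Each signal casts a coding/noncoding
vote against fixed thresholds — CPC < 0, CNCI < 0 and txCdsPredict < 500
vote noncoding; a pfam hit votes coding — and a transcript is labelled
only when at least three votes agree; ties and insufficient evidence
yield ``unclassified``, which is excluded from downstream lncRNA sets.

External tool outputs are ingested from a normalized TSV.  For
self-contained runs, :func:`heuristic_coding_score` provides an internal
surrogate scorer from sequence alone (ORF fraction, ORF length, and a
hexamer log-odds score against human codon-usage-derived backgrounds);
it does not reimplement the external tools and never asserts a pfam hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ValidationError

__all__ = [
    "CodingScores",
    "CodingCall",
    "apply_thresholds",
    "consensus_classify",
    "classify_table",
    "heuristic_coding_score",
    "read_score_table",
    "calls_to_frame",
]

CPC_THRESHOLD = 0.0
CNCI_THRESHOLD = 0.0
TXCDS_THRESHOLD = 500.0
METHODS = ("cpc", "cnci", "txcds", "pfam")


@dataclass
class CodingScores:
    """Raw per-method scores for one transcript; any field may be missing."""

    transcript_id: str
    cpc_score: float | None = None
    cnci_score: float | None = None
    txcds_score: float | None = None
    pfam_hit: bool | None = None

    def n_present(self) -> int:
        return sum(
            v is not None
            for v in (self.cpc_score, self.cnci_score, self.txcds_score, self.pfam_hit)
        )


@dataclass
class CodingCall:
    transcript_id: str
    votes: dict[str, str] = field(default_factory=dict)
    label: str = "unclassified"


def apply_thresholds(scores: CodingScores) -> dict[str, str]:
    """Threshold each method's score into a coding/noncoding/missing vote.

    Inequalities are strict: a score exactly at the threshold votes coding.
    """
    def vote(value, threshold):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "missing"
        return "noncoding" if value < threshold else "coding"

    votes = {
        "cpc": vote(scores.cpc_score, CPC_THRESHOLD),
        "cnci": vote(scores.cnci_score, CNCI_THRESHOLD),
        "txcds": vote(scores.txcds_score, TXCDS_THRESHOLD),
    }
    if scores.pfam_hit is None:
        votes["pfam"] = "missing"
    else:
        votes["pfam"] = "coding" if scores.pfam_hit else "noncoding"
    return votes


def consensus_classify(votes: dict[str, str], transcript_id: str = "") -> CodingCall:
    """Label lncRNA / mRNA when >= 3 votes agree; otherwise unclassified.

    Only vote counts matter; method identity is irrelevant.  Missing
    votes are not counted toward either side.
    """
    if len(votes) > 4:
        raise ValidationError(f"more than 4 votes supplied: {sorted(votes)}")
    values = list(votes.values())
    unknown = set(values) - {"coding", "noncoding", "missing"}
    if unknown:
        raise ValidationError(f"unknown vote values: {sorted(unknown)}")
    n_noncoding = values.count("noncoding")
    n_coding = values.count("coding")
    if n_noncoding >= 3:
        label = "lncRNA"
    elif n_coding >= 3:
        label = "mRNA"
    else:
        label = "unclassified"
    return CodingCall(transcript_id=transcript_id, votes=dict(votes), label=label)


def classify_table(scores: list[CodingScores]) -> list[CodingCall]:
    return [consensus_classify(apply_thresholds(s), s.transcript_id) for s in scores]


# ---------------------------------------------------------------------------
# internal surrogate scorer

# Human codon usage, occurrences per 1000 codons.  Used to build the
# coding hexamer background (two adjacent in-frame codons) for the
# cnci-like log-odds score; the noncoding background is the product of
# the implied mononucleotide frequencies.
_CODON_USAGE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}
_STOPS = ("TAA", "TAG", "TGA")


def _codon_probs() -> dict[str, float]:
    total = sum(_CODON_USAGE.values())
    return {c: v / total for c, v in _CODON_USAGE.items()}


def _nt_probs() -> dict[str, float]:
    p = _codon_probs()
    nt = {b: 0.0 for b in "ACGT"}
    for codon, prob in p.items():
        for b in codon:
            nt[b] += prob / 3.0
    return nt


_CODON_P = _codon_probs()
_NT_P = _nt_probs()


def _longest_orf(seq: str) -> int:
    """Longest ORF length in nt (ATG through stop inclusive, or to the
    sequence end when no stop follows), over the three forward frames."""
    best = 0
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                j = i
                while j + 3 <= n and seq[j : j + 3] not in _STOPS:
                    j += 3
                length = (j + 3 - i) if j + 3 <= n else (j - i)
                best = max(best, length)
                i = j + 3
            else:
                i += 3
    return best


def _hexamer_log_odds(seq: str) -> float:
    """Mean log2 odds per in-frame hexamer (two codons) of the best frame,
    coding background vs mononucleotide background."""
    floor = 1e-6
    best = -math.inf
    for frame in range(3):
        total, count = 0.0, 0
        for i in range(frame, len(seq) - 5, 3):
            hexamer = seq[i : i + 6]
            if "N" in hexamer:
                continue
            p_cod = _CODON_P.get(hexamer[:3], floor) * _CODON_P.get(hexamer[3:], floor)
            p_bg = 1.0
            for b in hexamer:
                p_bg *= _NT_P[b]
            total += math.log2(p_cod / p_bg)
            count += 1
        if count:
            best = max(best, total / count)
    return best if best > -math.inf else -1.0


def heuristic_coding_score(sequence: str) -> CodingScores:
    """Surrogate coding-potential scores from sequence alone.

    cpc-like: longest-ORF fraction of the sequence, centred at 0.5 and
    scaled to [-1, 1].  txcds-like: 2x longest ORF length in nt (so a
    >= 250 nt ORF clears the 500 coding threshold).  cnci-like: hexamer
    log-odds against codon-usage backgrounds.  ``pfam_hit`` is always
    False — no domain database is shipped.  Deterministic.
    """
    seq = sequence.upper()
    if len(seq) < 200:
        raise ValidationError(f"sequence too short ({len(seq)} nt < 200)")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    orf = _longest_orf(seq)
    return CodingScores(
        transcript_id="",
        cpc_score=2.0 * (orf / len(seq)) - 1.0,
        txcds_score=2.0 * orf,
        cnci_score=_hexamer_log_odds(seq),
        pfam_hit=False,
    )


# ---------------------------------------------------------------------------
# ingest

_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE"}


def read_score_table(path) -> list[CodingScores]:
    """Read a normalized coding-score TSV.

    Header: transcript_id, cpc, cnci, txcds, pfam_hit with pfam_hit in
    {0, 1, true, false}; empty cells are missing scores.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pfam_hit": str})
    required = {"transcript_id", "cpc", "cnci", "txcds", "pfam_hit"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"score table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        def opt(v):
            return None if pd.isna(v) else float(v)

        pf = row.pfam_hit
        if pd.isna(pf):
            pfam = None
        elif str(pf).strip() in _TRUTHY:
            pfam = True
        elif str(pf).strip() in _FALSY:
            pfam = False
        else:
            raise ValidationError(f"pfam_hit value {pf!r} not in {{0,1,true,false}}")
        out.append(
            CodingScores(
                transcript_id=str(row.transcript_id),
                cpc_score=opt(row.cpc),
                cnci_score=opt(row.cnci),
                txcds_score=opt(row.txcds),
                pfam_hit=pfam,
            )
        )
    return out


def calls_to_frame(calls: list[CodingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            **{m: [c.votes.get(m, "missing") for c in calls] for m in METHODS},
            "label": [c.label for c in calls],
        }
    )
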