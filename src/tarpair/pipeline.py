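"""End-to-end orchestration: expression -> DE -> coding calls -> pairing
-> TAR-pair cascade, with deterministic, hash-stamped outputs.

One control group is compared against each mutant group in turn (no
cross-mutant DE).  All randomness lives in the synthetic-data
generator; given identical inputs and configuration the pipeline's
``summary.json`` is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coding_potential as cp
from .diffexpr import DEThresholds, de_to_frame, run_de
from .expression import compute_fpkm, filter_expressed
from .formats import read_count_matrix, read_gtf, read_library_sizes, write_results
from .pairing import (
    DEFAULT_DOWN_BP,
    DEFAULT_ENERGY_MAX,
    DEFAULT_UP_BP,
    build_tarpairs,
    candidate_pairs,
    classify_pairs,
    read_energy_table,
    refine_tarpairs,
    tarpairs_to_frame,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every path and threshold of the analysis in one place."""

    counts: str
    gtf: str
    control: str = "control"
    mutants: list[str] = field(default_factory=lambda: ["mutant"])
    scores: str | None = None
    energies: str | None = None
    library_sizes: str | None = None  # sidecar TSV of mapped-fragment totals
    sample_groups: dict[str, str] | None = None  # default: sample name minus trailing _N
    # thresholds
    fc_min: float = 2.0
    fdr_max: float = 0.001
    p_max: float = 0.05
    abs_log2fc_min: float = 1.5
    rho_min: float = 0.6
    up_bp: int = DEFAULT_UP_BP
    down_bp: int = DEFAULT_DOWN_BP
    energy_max: float = DEFAULT_ENERGY_MAX
    cascade_fold: float = 5.0
    min_fpkm: float = 0.1
    tier: str = "significant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control in self.mutants:
            raise PipelineError("control label must be distinct from mutant labels")
        for name in ("fc_min", "rho_min", "cascade_fold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def de_thresholds(self) -> DEThresholds:
        return DEThresholds(
            fc_min=self.fc_min, fdr_max=self.fdr_max,
            p_max=self.p_max, abs_log2fc_min=self.abs_log2fc_min,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _infer_groups(sample_ids: list[str]) -> dict[str, str]:
    return {s: s.rsplit("_", 1)[0] for s in sample_ids}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the result bundle into ``outdir``.

    Outputs: de_<mutant>.tsv, calls.tsv, tarpairs_2x_<mutant>.tsv,
    tarpairs_5x_<mutant>.tsv and summary.json.  Any stage error aborts
    with the stage name; partial outputs are removed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, frame) -> None:
        path = outdir / name
        write_results(frame, path)
        written.append(path)

    try:
        stage = "expression"
        annotation = read_gtf(config.gtf)
        ann_by_id = {r.transcript_id: r for r in annotation}
        raw = pd.read_csv(config.counts, sep="\t", index_col=0, nrows=0)
        groups = config.sample_groups or _infer_groups(list(raw.columns.astype(str)))
        libsizes = read_library_sizes(config.library_sizes) if config.library_sizes else None
        counts = read_count_matrix(config.counts, groups, library_size=libsizes)
        expr = compute_fpkm(counts, annotation)

        stage = "coding_potential"
        calls = []
        if config.scores:
            calls = cp.classify_table(cp.read_score_table(config.scores))
            emit("calls.tsv", cp.calls_to_frame(calls))
        label_of = {c.transcript_id: c.label for c in calls}
        lnc_ids, mrna_ids = [], []
        for r in annotation:
            label = r.biotype if r.biotype != "novel" else label_of.get(r.transcript_id, "unclassified")
            if label == "lncRNA":
                lnc_ids.append(r.transcript_id)
            elif label == "mRNA":
                mrna_ids.append(r.transcript_id)

        energies = read_energy_table(config.energies) if config.energies else {}

        summary: dict = {
            "inputs": {
                key: _sha256(p)
                for key, p in (
                    ("counts", config.counts), ("gtf", config.gtf),
                    ("scores", config.scores), ("energies", config.energies),
                    ("library_sizes", config.library_sizes),
                )
                if p
            },
            "thresholds": {
                k: v for k, v in asdict(config).items()
                if k not in ("counts", "gtf", "scores", "energies",
                             "library_sizes", "sample_groups")
            },
            "n_lnc": len(lnc_ids),
            "n_mrna": len(mrna_ids),
            "comparisons": {},
        }

        th = config.de_thresholds()
        tiers_ok = {"significant": ("significant",),
                    "candidate": ("significant", "candidate")}[config.tier]
        for mutant in config.mutants:
            stage = f"diffexpr[{config.control} vs {mutant}]"
            de = run_de(counts, expr, config.control, mutant, th)
            emit(f"de_{mutant}.tsv", de_to_frame(de))
            de_lnc = [r for r in de if r.transcript_id in set(lnc_ids)]
            de_mrna = [r for r in de if r.transcript_id in set(mrna_ids)]
            n_del = sum(r.tier in tiers_ok for r in de_lnc)
            n_deg = sum(r.tier in tiers_ok for r in de_mrna)

            stage = f"pairing[{config.control} vs {mutant}]"
            pair_samples = [
                s for s in counts.sample_ids
                if counts.group_of[s] in (config.control, mutant)
            ]
            sub = expr.to_frame()[pair_samples]
            from .expression import ExpressionMatrix

            sub_expr = ExpressionMatrix(
                transcript_ids=list(sub.index), sample_ids=pair_samples,
                fpkm=sub.to_numpy(),
                effective_length=expr.effective_length,
                group_of={s: counts.group_of[s] for s in pair_samples},
            )
            filtered = filter_expressed(sub_expr, config.min_fpkm)
            kept = set(filtered.transcript_ids)
            cands = candidate_pairs(
                filtered,
                [t for t in lnc_ids if t in kept],
                [t for t in mrna_ids if t in kept],
                rho_min=config.rho_min,
            )
            pairs = classify_pairs(
                cands, ann_by_id, energies,
                up_bp=config.up_bp, down_bp=config.down_bp,
                energy_max=config.energy_max,
            )

            stage = f"cascade[{config.control} vs {mutant}]"
            hits2 = build_tarpairs(pairs, de_lnc, de_mrna, tier=config.tier, fold_min=2.0)
            hits5 = refine_tarpairs(hits2, fold_min=config.cascade_fold)
            emit(f"tarpairs_2x_{mutant}.tsv", tarpairs_to_frame(hits2))
            emit(f"tarpairs_5x_{mutant}.tsv", tarpairs_to_frame(hits5))

            summary["comparisons"][mutant] = {
                "n_DEG": n_deg,
                "n_DEL": n_del,
                "n_candidates": len(cands),
                "n_pairs": len(pairs),
                "n_tarpairs_2x": len(hits2),
                "n_tarpairs_5x": len(hits5),
            }

        stage = "summary"
        spath = outdir / "summary.json"
        with open(spath, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(spath)
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {exc}") from exc
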