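"""Synthetic transcriptome bundles with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a
two-group (control vs FUS-mutant style) replicate count matrix with
planted differentially expressed transcripts, planted co-expressed
lncRNA-mRNA pairs placed inside (cis) or far outside (trans) the
10 kb-upstream / 20 kb-downstream genomic window, Poisson (optionally
gamma-overdispersed) counting noise, coding-potential score tables with
a controlled dissent rate, RNAplex-style hybridization energies for the
planted trans pairs, and qPCR Ct tables.

Layout is deterministic given the seed: mRNAs occupy evenly spaced
slots on chr1 (alternating strand), cis-pair lncRNAs sit inside their
partner's strand-oriented window, trans-pair lncRNAs live on chr2 and
the remaining lncRNAs on chr3 — so no non-planted pair can satisfy the
cis window by accident, and planted trans pairs need their energy entry.

Co-expression is induced by a shared log-normal latent factor
multiplying both pair members' means: each member's log-factor is
``latent_sd * (sqrt(rho) * Z_shared + sqrt(1 - rho) * Z_own)``, so the
latent correlation equals ``pair_correlation`` and both Pearson and
Spearman respond (the transform is monotone).  Planted pair members are
also differentially expressed (congruently, alternating sign by pair),
which is what makes them recoverable TAR pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    CountMatrix,
    CtTable,
    TranscriptRecord,
    ValidationError,
    write_gtf,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_annotation",
    "generate_counts",
    "generate_score_table",
    "generate_energy_table",
    "generate_ct_table",
    "generate_bundle",
]

SLOT_BP = 200_000  # per-transcript spacing; >> cis window, so slots never interact


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults describe a desk-scale version of a two-condition iPSC
    transcriptome comparison: 6 replicates per group, mean depth 200
    fragments per transcript, planted |log2FC| 2.5 (~5.7-fold, past the
    5-fold cascade), pair co-expression 0.95, Poisson noise.
    """

    n_mrna: int = 60
    n_lnc: int = 40
    n_replicates_per_group: int = 6
    groups: tuple[str, ...] = ("control", "mutant")
    n_de_mrna: int = 20
    n_de_lnc: int = 16
    de_log2fc: float = 2.5
    n_cis_pairs: int = 8
    n_trans_pairs: int = 4
    pair_correlation: float = 0.95
    baseline_mean: float = 200.0
    dispersion: float = 0.0
    genome_length: int = 30_000_000
    seed: int = 0
    # secondary knobs
    latent_sd: float = 0.5        # sd of the log-normal latent factor
    flip_rate: float = 0.1        # per-method dissent rate in score tables
    novel_fraction: float = 0.25  # non-pair transcripts written with biotype "novel"
    ct_noise_sd: float = 0.2      # cycles
    ct_replicates: int = 3
    library_extra: int = 2_000_000  # mapped fragments outside the quantified matrix

    @property
    def n_pairs(self) -> int:
        return self.n_cis_pairs + self.n_trans_pairs

    def validate(self) -> None:
        if self.n_replicates_per_group < 2:
            raise ConfigurationError("need >= 2 replicates per group")
        if len(self.groups) < 2 or len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("need >= 2 distinct group labels")
        if not (0 < self.pair_correlation <= 1):
            raise ConfigurationError("pair_correlation must be in (0, 1]")
        if self.dispersion < 0 or self.baseline_mean <= 0:
            raise ConfigurationError("dispersion >= 0 and baseline_mean > 0 required")
        if min(self.n_mrna, self.n_lnc, self.n_de_mrna, self.n_de_lnc,
               self.n_cis_pairs, self.n_trans_pairs) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.n_de_mrna > self.n_mrna or self.n_de_lnc > self.n_lnc:
            raise ConfigurationError("planted DE counts exceed transcript counts")
        if self.n_pairs > min(self.n_lnc, self.n_mrna):
            raise ConfigurationError("more planted pairs than available transcripts")
        if self.n_pairs > self.n_de_mrna or self.n_pairs > self.n_de_lnc:
            raise ConfigurationError(
                "planted pair members are always DE; n_de_mrna and n_de_lnc "
                f"must each be >= n_cis_pairs + n_trans_pairs = {self.n_pairs}"
            )
        needed = 100_000 + SLOT_BP * max(self.n_mrna, self.n_lnc, 1)
        if self.genome_length < needed:
            raise ConfigurationError(
                f"genome_length {self.genome_length} too small to place "
                f"transcripts without forced overlap (need >= {needed})"
            )


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    de_transcripts: dict[str, float] = field(default_factory=dict)  # id -> signed log2FC
    planted_pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (lnc, mrna, mode)
    coding_labels: dict[str, str] = field(default_factory=dict)  # id -> mRNA | lncRNA

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_transcripts=d["de_transcripts"],
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            coding_labels=d["coding_labels"],
        )


def _mrna_id(i: int) -> str:
    return f"MRNA_{i:04d}"


def _lnc_id(i: int) -> str:
    return f"LNC_{i:04d}"


def generate_annotation(config: SimConfig) -> tuple[list[TranscriptRecord], SimTruth]:
    """Deterministic annotation with planted cis/trans pair geometry."""
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 11])
    truth = SimTruth()
    records: list[TranscriptRecord] = []

    mrnas: list[TranscriptRecord] = []
    for i in range(config.n_mrna):
        s = 50_000 + i * SLOT_BP
        strand = "+" if i % 2 == 0 else "-"
        mrnas.append(
            TranscriptRecord(
                transcript_id=_mrna_id(i), gene_id=f"G{_mrna_id(i)}",
                chrom="chr1", strand=strand, start=s, end=s + 1999,
                exons=[(s, s + 799), (s + 1200, s + 1999)], biotype="mRNA",
            )
        )

    lncs: list[TranscriptRecord] = []
    for j in range(config.n_lnc):
        lid = _lnc_id(j)
        if j < config.n_cis_pairs:
            partner = mrnas[j]
            if partner.strand == "+":
                a = partner.end + 3_000       # 20 kb downstream side
            else:
                a = partner.start - 4_000     # downstream of a minus-strand mRNA
            chrom, start, end = "chr1", a, a + 999
            truth.planted_pairs.append((lid, partner.transcript_id, "cis"))
        elif j < config.n_pairs:
            partner = mrnas[j]
            chrom = "chr2"
            start = 50_000 + j * SLOT_BP
            end = start + 999
            truth.planted_pairs.append((lid, partner.transcript_id, "trans"))
        else:
            chrom = "chr3"
            start = 50_000 + j * SLOT_BP
            end = start + 999
        lncs.append(
            TranscriptRecord(
                transcript_id=lid, gene_id=f"G{lid}", chrom=chrom,
                strand="+", start=start, end=end, biotype="lncRNA",
            )
        )

    for i, r in enumerate(mrnas):
        truth.coding_labels[r.transcript_id] = "mRNA"
        sign = 1.0 if i % 2 == 0 else -1.0
        if i < config.n_de_mrna:
            truth.de_transcripts[r.transcript_id] = sign * config.de_log2fc
    for j, r in enumerate(lncs):
        truth.coding_labels[r.transcript_id] = "lncRNA"
        if j < config.n_pairs:
            # congruent with the partner mRNA's direction
            truth.de_transcripts[r.transcript_id] = truth.de_transcripts[_mrna_id(j)]
        elif j < config.n_de_lnc:
            sign = 1.0 if j % 2 == 0 else -1.0
            truth.de_transcripts[r.transcript_id] = sign * config.de_log2fc

    # a fraction of NON-pair transcripts carries the "novel" biotype so the
    # coding-potential stage has work; planted pairs keep annotated biotypes
    pair_ids = {i for p in truth.planted_pairs for i in p[:2]}
    for r in mrnas + lncs:
        if r.transcript_id not in pair_ids and rng.random() < config.novel_fraction:
            r.biotype = "novel"
        records.append(r)
    return records, truth


def generate_counts(
    annotation: list[TranscriptRecord], truth: SimTruth, config: SimConfig
) -> CountMatrix:
    """Replicate count matrix with planted DE and pair co-expression."""
    config.validate()
    ids = [r.transcript_id for r in annotation]
    unknown = set(truth.de_transcripts) - set(ids)
    if unknown:
        raise ConfigurationError(f"truth references unknown transcripts: {sorted(unknown)[:5]}")
    rng = np.random.default_rng([config.seed % (2**31), 13])
    samples = [f"{g}_{r + 1}" for g in config.groups for r in range(config.n_replicates_per_group)]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    control = config.groups[0]

    idx = {t: i for i, t in enumerate(ids)}
    n_t, n_s = len(ids), len(samples)
    log2fc = np.zeros(n_t)
    for t, l2 in truth.de_transcripts.items():
        log2fc[idx[t]] = l2
    is_mutant = np.array([group_of[s] != control for s in samples], dtype=float)
    means = config.baseline_mean * np.power(2.0, np.outer(log2fc, is_mutant))

    sd = config.latent_sd
    rho = config.pair_correlation
    for lnc_id, mrna_id, _mode in truth.planted_pairs:
        z_shared = rng.standard_normal(n_s)
        for member in (lnc_id, mrna_id):
            z_own = rng.standard_normal(n_s)
            L = sd * (math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * z_own)
            means[idx[member], :] *= np.exp(L - sd * sd / 2.0)

    if config.dispersion == 0:
        counts = rng.poisson(means)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, means / shape)
        counts = rng.poisson(lam)

    # library size = in-matrix fragments + fragments mapping elsewhere, so
    # depth normalization is not driven by the planted DE composition
    library_size = {
        s: max(1, int(c) + config.library_extra)
        for s, c in zip(samples, counts.sum(axis=0))
    }
    return CountMatrix(
        transcript_ids=ids, sample_ids=samples, counts=counts.astype(np.int64),
        group_of=group_of, library_size=library_size,
    )


def generate_score_table(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Coding-potential score table honouring the planted labels.

    Each method independently dissents with probability ``flip_rate``,
    creating the minority-dissent cases the 3-of-4 vote must absorb.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 17])
    rows = []
    for tid, label in truth.coding_labels.items():
        if label not in ("mRNA", "lncRNA"):
            raise ConfigurationError(f"unknown coding label {label!r} for {tid!r}")
        coding = label == "mRNA"
        flips = rng.random(4) < config.flip_rate
        side = [coding != f for f in flips]  # True -> score on the coding side
        rows.append(
            {
                "transcript_id": tid,
                "cpc": rng.uniform(0.5, 3.0) if side[0] else rng.uniform(-3.0, -0.5),
                "cnci": rng.uniform(0.1, 2.0) if side[1] else rng.uniform(-2.0, -0.1),
                "txcds": rng.uniform(600, 1500) if side[2] else rng.uniform(100, 450),
                "pfam_hit": int(side[3]),
            }
        )
    return pd.DataFrame(rows)


def generate_energy_table(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Hybridization energies: strong for planted trans pairs, weak decoys
    for a few non-pair combinations (never past the default cutoff)."""
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 19])
    rows = []
    for lnc_id, mrna_id, mode in truth.planted_pairs:
        if mode == "trans":
            rows.append({"lnc_id": lnc_id, "mrna_id": mrna_id,
                         "energy": rng.uniform(-50.0, -35.0)})
    planted = {(l, m) for l, m, _ in truth.planted_pairs}
    n_decoys = min(5, config.n_lnc * config.n_mrna)
    attempts = 0
    while n_decoys > 0 and attempts < 100 and config.n_lnc and config.n_mrna:
        attempts += 1
        key = (_lnc_id(int(rng.integers(config.n_lnc))),
               _mrna_id(int(rng.integers(config.n_mrna))))
        if key in planted:
            continue  # decoys must not shadow a planted pair's energy
        rows.append({"lnc_id": key[0], "mrna_id": key[1],
                     "energy": rng.uniform(-10.0, -2.0)})
        n_decoys -= 1
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "energy"])


def generate_ct_table(
    config: SimConfig,
    planted_folds: dict[str, float] | None = None,
    references: tuple[str, ...] = ("HPRT", "GAPDH"),
    noise_sd: float | None = None,
) -> CtTable:
    """qPCR Ct table: mutant-group target Ct shifted by -log2(planted fold),
    references at fold 1, Gaussian cycle noise."""
    config.validate()
    if planted_folds is None:
        planted_folds = {"VAL_UP": 4.0, "VAL_DOWN": 0.25}
    if not references:
        raise ConfigurationError("need >= 1 reference target")
    noise = config.ct_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng([config.seed % (2**31), 23])
    control = config.groups[0]
    base_ct = {t: 24.0 + 2.0 * i for i, t in enumerate(planted_folds)}
    base_ct.update({r: 20.0 + i for i, r in enumerate(references)})
    rows = []
    for group in config.groups:
        for rep in range(1, config.ct_replicates + 1):
            sample = f"{group}_{rep}"
            for target, fold in planted_folds.items():
                ct = base_ct[target]
                if group != control:
                    ct -= math.log2(fold)
                rows.append({"target_id": target, "sample_id": sample, "group": group,
                             "replicate": rep, "ct": ct + noise * rng.standard_normal()})
            for ref in references:
                rows.append({"target_id": ref, "sample_id": sample, "group": group,
                             "replicate": rep, "ct": base_ct[ref] + noise * rng.standard_normal()})
    return CtTable(data=pd.DataFrame(rows), reference_ids=list(references))


def generate_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete input bundle (GTF, counts, scores, energies, Ct,
    truth JSON) and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = generate_annotation(config)
    counts = generate_counts(annotation, truth, config)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "counts": outdir / "counts.tsv",
        "library_sizes": outdir / "library_sizes.tsv",
        "scores": outdir / "scores.tsv",
        "energies": outdir / "energies.tsv",
        "ct": outdir / "ct.tsv",
        "truth": outdir / "truth.json",
    }
    write_gtf(annotation, paths["annotation"])
    counts.to_frame().to_csv(paths["counts"], sep="\t")
    pd.DataFrame(
        {"sample_id": counts.sample_ids,
         "library_size": [counts.library_size[s] for s in counts.sample_ids]}
    ).to_csv(paths["library_sizes"], sep="\t", index=False)
    generate_score_table(truth, config).to_csv(paths["scores"], sep="\t", index=False)
    generate_energy_table(truth, config).to_csv(paths["energies"], sep="\t", index=False)
    generate_ct_table(config).data.to_csv(paths["ct"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
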