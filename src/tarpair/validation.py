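"""qPCR 2^-ddCt quantification and gene-set over-representation.

Relative qPCR quantification: within each sample, the target Ct is
normalized to the arithmetic mean of the reference (housekeeping) gene
Cts — equivalent to a geometric mean of linear quantities — giving a
per-replicate dCt.  ddCt is the group-mean dCt minus the control
group's, and the reported fold is 2^-ddCt, with a two-sided Student's
t-test on the replicate dCt values (Welch optional).  Normalization
makes the result exactly invariant to adding a constant to every Ct in
a sample.

Over-representation uses the one-sided hypergeometric tail P(X >= k)
per gene set with BH adjustment across sets.  Term databases (GO/KEGG
style) are supplied by the caller as GMT files; none are shipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .formats import CtTable, ValidationError

__all__ = [
    "DdctRecord",
    "EnrichmentRow",
    "ddct",
    "ora_enrichment",
    "read_gmt",
    "ddct_to_frame",
    "enrichment_to_frame",
]

log = logging.getLogger(__name__)


@dataclass
class DdctRecord:
    target_id: str
    group: str
    delta_ct_mean: float  # cycles
    ddct: float           # cycles, vs the control group
    fold: float           # 2 ** -ddct
    p_value: float        # t-test on replicate dCt, group vs control
    n_replicates: int


@dataclass
class EnrichmentRow:
    set_name: str
    k_hits: int
    n_query: int
    K_set: int
    N_universe: int
    p_value: float
    fdr: float = 1.0


def ddct(ct: CtTable, control_group: str, welch: bool = False) -> list[DdctRecord]:
    """2^-ddCt relative quantification against ``control_group``.

    One record per (target, group) including the control group itself
    (whose ddCt is 0 and fold 1 by definition; its p-value is 1).
    """
    df = ct.data
    refs = list(ct.reference_ids)
    targets = ct.target_ids
    bad = set(refs) & set(targets)  # target_ids already excludes refs; guard anyway
    if bad:
        raise ValidationError(f"references also requested as targets: {sorted(bad)}")
    groups = list(dict.fromkeys(df["group"]))
    if control_group not in groups:
        raise ValidationError(f"control group {control_group!r} absent from Ct table")

    # mean reference Ct per sample
    ref_rows = df[df["target_id"].isin(refs)]
    ref_mean = ref_rows.groupby(["sample_id", "replicate"])["ct"].mean()
    all_samples = set(map(tuple, df[["sample_id", "replicate"]].itertuples(index=False)))
    missing = all_samples - set(ref_mean.index)
    if missing:
        raise ValidationError(
            f"reference Cts missing for samples: {sorted(missing)[:5]}"
        )

    records = []
    for target in targets:
        sub = df[df["target_id"] == target].copy()
        keys = list(zip(sub["sample_id"], sub["replicate"]))
        sub["dct"] = sub["ct"].to_numpy() - ref_mean.loc[keys].to_numpy()
        dct_control = sub.loc[sub["group"] == control_group, "dct"].to_numpy()
        if len(dct_control) < 2:
            raise ValidationError(
                f"target {target!r}: need >= 2 control replicates for the t-test"
            )
        control_mean = float(dct_control.mean())
        for group in groups:
            dct_g = sub.loc[sub["group"] == group, "dct"].to_numpy()
            if len(dct_g) < 2:
                raise ValidationError(
                    f"target {target!r}, group {group!r}: need >= 2 replicates"
                )
            delta = float(dct_g.mean())
            dd = delta - control_mean
            if group == control_group:
                p = 1.0
            elif dct_g.var() == 0 and dct_control.var() == 0:
                # degenerate (noise-free) replicates: the t statistic is
                # undefined, but the outcome is not ambiguous
                p = 1.0 if np.isclose(dd, 0.0) else 0.0
            else:
                p = float(
                    stats.ttest_ind(dct_g, dct_control, equal_var=not welch).pvalue
                )
            records.append(
                DdctRecord(
                    target_id=target, group=group, delta_ct_mean=delta,
                    ddct=dd, fold=2.0 ** (-dd), p_value=p,
                    n_replicates=len(dct_g),
                )
            )
    return records


def ora_enrichment(
    query_ids: set[str],
    universe_ids: set[str],
    gene_sets: dict[str, set[str]],
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation of ``query_ids`` in
    each gene set, BH-adjusted across sets, sorted by p.

    Each set is intersected with the universe before testing; sets
    disjoint from the universe are skipped with a warning.
    """
    universe = set(universe_ids)
    query = set(query_ids)
    if not universe:
        raise ValidationError("empty universe")
    stray = query - universe
    if stray:
        raise ValidationError(f"query ids outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            log.warning("gene set %r shares no members with the universe; skipped", name)
            continue
        K = len(in_universe)
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(name, k, n, K, N, min(p, 1.0)))
    if rows:
        fdrs = bh_adjust([r.p_value for r in rows])
        for r, q in zip(rows, fdrs):
            r.fdr = float(q)
    rows.sort(key=lambda r: (r.p_value, r.set_name))
    return rows


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, tab-separated member ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line {lineno}: need name, description, members")
            sets[fields[0]] = set(fields[2:])
    return sets


def ddct_to_frame(records: list[DdctRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
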