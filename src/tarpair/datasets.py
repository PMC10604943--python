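"""Small bundled reference tables.

``read_qc_summary`` returns the published per-condition sequencing read
totals (BGISEQ-500, control and two FUS-mutant iPSC lines) used to
sanity-check the clean-read-ratio arithmetic; raw data live in the
BioProject archive and are not required by the pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["read_qc_summary", "clean_read_ratios"]


def read_qc_summary() -> pd.DataFrame:
    """Per-sample total raw and clean (post-QC) read counts."""
    with resources.files("tarpair.data").joinpath("read_qc_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def clean_read_ratios() -> pd.Series:
    """Clean/raw read percentage per sample, indexed by sample name."""
    df = read_qc_summary()
    ratios = 100.0 * df["total_clean_reads"] / df["total_raw_reads"]
    ratios.index = df["sample"]
    return ratios
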