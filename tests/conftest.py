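import numpy as np
import pytest

from tarpair.formats import CountMatrix, TranscriptRecord
from tarpair.simdata import SimConfig, generate_annotation, generate_bundle, generate_counts


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=3)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, sim_config):
    """A complete synthetic input bundle on disk (seed 3)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_bundle(sim_config, outdir)


@pytest.fixture(scope="session")
def sim_annotation(sim_config):
    return generate_annotation(sim_config)


@pytest.fixture(scope="session")
def sim_counts(sim_annotation, sim_config):
    annotation, truth = sim_annotation
    return generate_counts(annotation, truth, sim_config)


def make_record(tid="T1", chrom="chr1", strand="+", start=100, end=500, **kw):
    return TranscriptRecord(
        transcript_id=tid, gene_id=f"G{tid}", chrom=chrom, strand=strand,
        start=start, end=end, **kw,
    )


def make_counts(counts, transcript_ids=None, groups=("A", "A", "B", "B"), library_size=None):
    counts = np.asarray(counts)
    tids = transcript_ids or [f"T{i}" for i in range(counts.shape[0])]
    sids = [f"{g}_{i + 1}" for i, g in enumerate(groups)]
    if library_size is None:
        library_size = {s: max(1, int(c)) for s, c in zip(sids, counts.sum(axis=0))}
    else:
        library_size = {s: library_size for s in sids}
    return CountMatrix(
        transcript_ids=tids, sample_ids=sids, counts=counts,
        group_of={s: g for s, g in zip(sids, groups)}, library_size=library_size,
    )
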