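import numpy as np
import pytest

from methylenr import simulate
from methylenr.io import CytosineRecord


def make_record(chrom="chr1", pos=1000, strand="+", context="CpG", meth=8, unmeth=2):
    return CytosineRecord(chrom, pos, strand, context, meth, unmeth)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared by slower integration tests."""
    cfg = simulate.SimulationConfig(
        n_cpg=4000,
        n_cph=800,
        seed=11,
        frac_age_dm=0.05,
        frac_counteracted=0.32,
        effect_size=0.35,
        motif_enrichment_factor=10.0,
        enhancer_enrichment_factor=3.0,
    )
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    cfg = simulate.SimulationConfig(
        n_cpg=3000,
        n_cph=600,
        seed=5,
        frac_age_dm=0.05,
        frac_counteracted=0.32,
        effect_size=0.35,
        motif_enrichment_factor=10.0,
    )
    out = tmp_path_factory.mktemp("fixture") / "fix"
    simulate.emit_fixture(cfg, out)
    return out


def two_group_records(counts_by_sample):
    """Build per-sample record lists from {sample: [(meth, total), ...]}
    at consecutive positions on chr1."""
    per_sample = {}
    for sample, counts in counts_by_sample.items():
        per_sample[sample] = [
            CytosineRecord("chr1", 100 + 50 * i, "+", "CpG", m, t - m)
            for i, (m, t) in enumerate(counts)
            if t is not None
        ]
    return per_sample
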