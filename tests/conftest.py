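import numpy as np
import pytest

import tcrclone as tc


@pytest.fixture(scope="session")
def trb():
    return tc.trb_like_locus()


@pytest.fixture(scope="session")
def trg():
    return tc.trg_like_locus()


@pytest.fixture(scope="session")
def tra_trd():
    return tc.tra_trd_like_loci()


@pytest.fixture()
def params():
    """Pipeline params with known simulated library depth."""
    return tc.ClonalityParams(tumor_lib_depth=30.0, normal_lib_depth=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


def make_signal(values, bin_size=100, start=0):
    values = np.asarray(values, dtype=float)
    positions = start + bin_size * np.arange(len(values))
    return tc.Signal(positions, values, bin_size)


@pytest.fixture(scope="session")
def trg_biallelic_pair():
    """High-purity biallelic TRG deletion pair (shared across tests)."""
    locus = tc.trg_like_locus()
    iv = tc.GenomicInterval(locus.extent.chrom, 30_000, 141_500)
    spec = tc.CloneSimSpec(
        locus=locus,
        tumor_fraction=0.93,
        allele1_deletion=iv,
        allele2_deletion=iv,
        background=tc.PolyclonalSpec(fraction_rearranged=0.0),
        mean_depth=30.0,
        bin_size=25,
        seed=7,
    )
    tumor, normal, truth = tc.simulate_sample(spec)
    return spec, tumor, normal, truth
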