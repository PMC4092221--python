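import numpy as np
import pandas as pd
import pytest

from sdspatial import (BinInteractionSet, ContactModel, SyntheticGenomeSpec,
                       generate_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _make_links(rows, bin_size=20_000, chrom="chrT"):
    df = pd.DataFrame(rows, columns=["binA_start", "binB_start", "count"])
    return BinInteractionSet(df, bin_size=bin_size, chrom=chrom)


@pytest.fixture
def make_links():
    """Factory: BinInteractionSet from (binA_start, binB_start, count) rows."""
    return _make_links


@pytest.fixture
def small_genome():
    """A 400 kb chromosome with one >99% SD pair, genes and feature tracks."""
    spec = SyntheticGenomeSpec(
        chrom_name="chrT", chrom_length=400_000, bin_size=20_000,
        sd_pairs={"gt99": 1}, sd_length=30_000, n_genes=5, n_alus=20,
        n_g4=10, seed=7)
    return generate_genome(spec)


@pytest.fixture
def flat_model():
    return ContactModel(decay_exponent=1.0, base_count_at_1bin=30.0)
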