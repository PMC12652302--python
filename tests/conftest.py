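import numpy as np
import pandas as pd
import pytest

from cfcna.bins import BinSet


def make_binset(n, chrom="1", span=100, gc=None, seed=0):
    """Uniform-span test BinSet on one chromosome."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * span,
            "end": np.arange(n) * span + span,
            "n_mappable": 50,
            "gc_ratio": gc if gc is not None else rng.uniform(0.3, 0.7, n),
        }
    )
    return BinSet(df)


@pytest.fixture
def binset_200():
    return make_binset(200)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated normal panel shared across normalization tests."""
    from cfcna.simulate import SimulationConfig, make_pseudo_binset, simulate_normals

    config = SimulationConfig(n_bins=1500, n_normals=5, seed=42)
    bin_set = make_pseudo_binset(1500, seed=42)
    profiles, truth = simulate_normals(config, bin_set)
    return config, bin_set, profiles, truth
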