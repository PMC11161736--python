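import numpy as np
import pandas as pd
import pytest

from proteosub import OmicsMatrix, SynthConfig, generate_panel


@pytest.fixture(scope="session")
def small_config():
    """A reduced separable panel for fast unit tests."""
    return SynthConfig(n_proteins=150, n_sites=240, n_ysites=120,
                       n_kinases=8, substrates_per_kinase=8, seed=7)


@pytest.fixture(scope="session")
def panel(small_config):
    return generate_panel(small_config)


@pytest.fixture()
def toy_wp():
    """A tiny complete WP matrix with two obvious sample groups."""
    rng = np.random.default_rng(0)
    base = rng.normal(20, 1, size=(30, 6))
    base[:10, 3:] += 5.0
    cols = [f"S{i}" for i in range(6)]
    rows = [f"P{i:03d}" for i in range(30)]
    return OmicsMatrix("WP", pd.DataFrame(base, index=rows, columns=cols))
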