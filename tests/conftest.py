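import numpy as np
import pytest

from pooltox import PoolSimParams, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One modest two-stage study: 61 genes × 3 sites plus the hairpin SNP.

    Gene 1 carries three planted sites and the mir-33 hairpin carries one,
    all at |f_R − f_S| = 0.8 with 200× per-library depth.
    """
    params = PoolSimParams(
        n_sites=184,
        n_genes=61,
        depth_mean=200.0,
        n_selected_sites=4,
        delta_f=0.8,
        seed=1,
    )
    return simulate_bundle(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
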