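import numpy as np
import pytest

import pepconn as pc


@pytest.fixture(scope="session")
def roster():
    return pc.canonical_roster()


@pytest.fixture(scope="session")
def small_dataset():
    """An 80-neuron synthetic triple with every planted motif enabled."""
    cfg = pc.SynthConfig(
        n_neurons=80, n_npp=15, n_gpcr=15, seed=11,
        n_broadcaster=1, broadcaster_npp_breadth=5, broadcaster_gpcr_breadth=60,
        n_integrative=1, integrative_npp_breadth=60, integrative_gpcr_breadth=5,
        n_enriched_pairs=2, enriched_overlap=15,
        n_autocrine_neurons=6, rich_club_h=10,
    )
    return pc.generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_digraph(n, p, rng):
    A = rng.random((n, n)) < p
    np.fill_diagonal(A, False)
    return A
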