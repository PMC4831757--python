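import numpy as np
import pytest

from ribostrain import simulate as sim


@pytest.fixture(scope="session")
def toy_pair():
    """Small two-strain dataset with planted effects of every kind."""
    cfg = sim.SimConfig(
        n_genes=10,
        seed=7,
        fold_change_spec=[(0, "mrna", 2.0), (1, "rfp", 2.0)],
        orf_variant_spec=[(2, "extension-5p", 4), (3, "readthrough-3p", 6)],
    )
    return sim.simulate_strain_pair(cfg)


@pytest.fixture(scope="session")
def toy_coverage(toy_pair):
    return sim.simulate_coverage(toy_pair)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
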