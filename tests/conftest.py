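import numpy as np
import pytest

import stabkin as sk
from stabkin.synthetic import generate_dataset, preset


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # trigger the one-off numba compilation outside of timed assertions
    sk.step_extent(np.array([0.1, 1.0]), 1.2, 0.5)


@pytest.fixture(scope="session")
def mab_dataset():
    cfg = preset("mab-acidic-variants")
    ds, truth = generate_dataset(cfg, seed=42)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def mab_obs(mab_dataset):
    cfg, ds, _ = mab_dataset
    return sk.to_extent(ds, cfg.transform)


@pytest.fixture(scope="session")
def titer_dataset():
    cfg = preset("live-attenuated-titer")
    ds, truth = generate_dataset(cfg, seed=3)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def first_order_ranking(titer_dataset):
    """Single-model screening of the titer data: fast bootstrap substrate."""
    cfg, ds, _ = titer_dataset
    obs = sk.to_extent(ds, cfg.transform)
    return cfg, sk.screen_models(sk.ModelCatalog([_first_order()]), obs)


def _first_order():
    from stabkin.kinetics import first_order_spec

    return first_order_spec()
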