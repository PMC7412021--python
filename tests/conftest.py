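import numpy as np
import pytest

import polgsv as pg
from polgsv.polarimetry import fuse_table, temporal_average


@pytest.fixture(scope="session")
def scene_cfg():
    """Default study conditions, fixed seed."""
    return pg.SceneConfig(seed=11)


@pytest.fixture(scope="session")
def plots(scene_cfg):
    return pg.gen_plots(scene_cfg)


@pytest.fixture(scope="session")
def feature_tables(scene_cfg, plots):
    """Per-acquisition fused FeatureTables plus the 4-acquisition average."""
    tabs = {k: fuse_table(v) for k, v in pg.gen_powers(plots, scene_cfg).items()}
    tabs["1,2,3,4"] = temporal_average(tabs, ["1", "2", "3", "4"])
    return tabs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_psd_t3(rng, n):
    """Random Hermitian PSD 3x3 matrices via A A^H."""
    A = rng.standard_normal((n, 3, 3)) + 1j * rng.standard_normal((n, 3, 3))
    return A @ np.swapaxes(A, -1, -2).conj()
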