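import numpy as np
import pytest

from cytoshape import morphometry as mm
from cytoshape import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _paired_table(preset: str, n: int, seed: int, zero_effect: bool = False):
    """Feature table for a paired experiment via the fast single-cell path."""
    if zero_effect:
        low_p = syn.ShapePopulationParams(label="low")
        high_p = syn.ShapePopulationParams(label="high")
    else:
        low_p, high_p = syn.preset_populations(preset)
    inst_low, _ = syn.single_cell_instances(low_p, n, seed=seed)
    inst_high, _ = syn.single_cell_instances(high_p, n, seed=seed + 1)
    table = mm.feature_table(inst_low + inst_high)
    return table


@pytest.fixture(scope="session")
def type1_table():
    """100 cells per line, type-1 effect sizes, measured descriptors."""
    return _paired_table("type1", 100, seed=7)


@pytest.fixture(scope="session")
def null_table():
    """Two samples from one population: no planted effect.  Same size as
    the real study (100 cells per line) so the validation pools support
    stable 10-cell sampling."""
    return _paired_table("type1", 100, seed=11, zero_effect=True)


@pytest.fixture
def disk_mask():
    from skimage import draw

    mask = np.zeros((140, 140), dtype=bool)
    rr, cc = draw.disk((70, 70), 50)
    mask[rr, cc] = True
    return mask
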