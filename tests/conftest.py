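import numpy as np
import pytest

from cmpens import synthetic_data
from cmpens.aggregation import CMPStack


def make_stack(values, **kwargs) -> CMPStack:
    """CMPStack from an (H, W, M) array, or an (M,) vector as a 1x1xM stack."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, None, :]
    return CMPStack(values=values, **kwargs)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 96x96 synthetic micrograph with its mask."""
    cfg = synthetic_data.SceneConfig(height=96, width=96, seed=7)
    return synthetic_data.generate_micrograph(cfg)


@pytest.fixture(scope="session")
def default_stack(small_scene):
    """100-member Gaussian-noise CMP stack over the small scene's mask."""
    _, mask = small_scene
    return synthetic_data.generate_cmp_stack(
        mask, synthetic_data.NoiseConfig(n_members=100, seed=11)
    )
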