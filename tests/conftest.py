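import numpy as np
import pytest

from lidmetrics.pipeline import process_scene
from lidmetrics.synthetic_scene import SceneParams, generate_scene

#: fixed seed for every stochastic test in the suite
SEED = 1234


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Gauss-digitized disk centred on a pixel centre (odd array side)."""
    n = 2 * radius + 2 * pad + 1
    rr, cc = np.mgrid[:n, :n]
    return (rr + 0.5 - n / 2) ** 2 + (cc + 0.5 - n / 2) ** 2 <= radius**2


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneParams())


@pytest.fixture(scope="session")
def default_result(default_scene):
    res = process_scene(default_scene, "oracle")
    assert res.ok, res.error
    return res
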