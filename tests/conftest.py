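import numpy as np
import pytest
from hypothesis import settings

from graincount import PipelineConfig, generate_scene

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def ellipse_mask(shape, cy, cx, rr, rc, rotation=0.0):
    from skimage.draw import ellipse

    m = np.zeros(shape, dtype=bool)
    ys, xs = ellipse(cy, cx, rr, rc, shape=shape, rotation=rotation)
    m[ys, xs] = True
    return m


@pytest.fixture(scope="session")
def wheat_scene_no_adhesion():
    return generate_scene(
        n=50, preset="wheat", adhesion_frac=0.0, seed=42,
        px_per_mm=6.0, canvas=(720, 960),
    )


@pytest.fixture(scope="session")
def wheat_scene_adhesion():
    return generate_scene(
        n=60, preset="wheat", adhesion_frac=0.3, seed=7,
        px_per_mm=6.0, canvas=(720, 960),
    )
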