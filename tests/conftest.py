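import numpy as np
import pytest

from steatoquant import PipelineConfig, SyntheticSpec, generate_slide


@pytest.fixture(scope="session")
def small_config():
    """Pipeline config for desk-scale 512-px slides (smaller edge crop)."""
    return PipelineConfig(edge_crop=40)


@pytest.fixture(scope="session")
def slide10():
    """One 512-px slide at 10% true fraction with all artifact types."""
    spec = SyntheticSpec(
        size=(512, 512), target_fraction=0.10,
        n_vessels=2, n_tears=1, n_glare=1, rng_seed=11,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def clean_slide():
    """Artifact-free 512-px slide at 8% true fraction."""
    spec = SyntheticSpec(size=(512, 512), target_fraction=0.08, rng_seed=5)
    return generate_slide(spec)


def rasterize_disc(radius: int, pad: int = 10) -> np.ndarray:
    s = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:s, 0:s]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
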