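import numpy as np
import pytest
from hypothesis import settings

import woundarea as wa

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210826)


@pytest.fixture()
def random_masks(rng):
    """A batch of small random binary masks for morphology/contour properties."""
    return [(rng.random((h, w)) < p).astype(np.uint8) * 255
            for h, w, p in [(24, 24, 0.3), (24, 24, 0.5), (24, 24, 0.7),
                            (17, 31, 0.4), (31, 17, 0.6), (16, 16, 0.1)]]


@pytest.fixture(scope="session")
def reference_pairs():
    return wa.load_reference_pairs()


@pytest.fixture()
def ellipse_scene():
    """A mid-sized single-ellipse synthetic scene and its ground truth."""
    spec = wa.SyntheticWoundSpec(
        canvas=(640, 480),
        lesions=(wa.Lesion(center=(320.0, 240.0), semi_axes=(140.0, 105.0)),),
        seed=99,
    )
    pixels, meta, truth = wa.generate(spec)
    return spec, pixels, meta, truth
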