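import numpy as np
import pytest

from grimkit.synthetic_faces import make_template


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def template_params(template):
    return template.parameters.as_dict()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_valid_landmarks(rng, template, jitter_px: float = 8.0):
    """Perturb the template into a random but still valid landmark set."""
    from grimkit.landmark_model import LandmarkSet

    pts = {
        name: (x + rng.uniform(-jitter_px, jitter_px), y + rng.uniform(-jitter_px, jitter_px))
        for name, (x, y) in template.landmarks.points.items()
    }
    return LandmarkSet(pts, side="right-profile")
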