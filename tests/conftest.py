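import numpy as np
import pytest

from gaitopt.gait_io import detect_steps, segment_to_image, window_by_steps
from gaitopt.synthetic import GaitSimParams, generate_cohort


def cohort_images(seed: int, **overrides):
    """Windows of a default synthetic cohort encoded as gait images."""
    params = GaitSimParams(seed=seed, **overrides)
    records, _ = generate_cohort(params)
    images = []
    for rec in records:
        seg = detect_steps(rec)
        for w, window in enumerate(window_by_steps(rec, seg)):
            img = segment_to_image(window)
            img.window_index = w
            images.append(img)
    return images


@pytest.fixture(scope="session")
def default_cohort_images():
    return cohort_images(seed=2024)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
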