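"""Shared fixtures: synthetic somitoids, HCR stacks and clock movies.

Everything is generated at test time from seeded specs; expensive fixtures
are session-scoped and treated as read-only by the tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from somitometry import midline as ml
from somitometry import segmentation as seg
from somitometry import synthgen


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.logical_and(a, b).sum() / np.logical_or(a, b).sum())


@pytest.fixture(scope="session")
def default_somitoid():
    """Default 8-somite somitoid image + ground truth (seed 0)."""
    return synthgen.generate_somitoid(synthgen.SomitoidSpec(seed=0))


@pytest.fixture(scope="session")
def default_mask(default_somitoid):
    img, _ = default_somitoid
    return seg.segment(img, method="yen")


@pytest.fixture(scope="session")
def default_curve(default_somitoid, default_mask):
    _, truth = default_somitoid
    return ml.extract_midline(default_mask, truth.posterior_anchor,
                              truth.anterior_anchor)


@pytest.fixture(scope="session")
def default_profile(default_mask, default_curve):
    return ml.compute_width_profile(default_mask, default_curve)


@pytest.fixture(scope="session")
def default_calls(default_profile):
    extrema = ml.find_profile_extrema(default_profile)
    return ml.call_somites(default_profile, extrema)


@pytest.fixture(scope="session")
def sinusoidal_somitoid():
    spec = synthgen.SomitoidSpec(seed=5, midline_shape="sinusoidal")
    return synthgen.generate_somitoid(spec)


@pytest.fixture(scope="session")
def hcr_noiseless():
    return synthgen.generate_hcr_stack(
        synthgen.HcrSpec(seed=0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def clock_movie():
    return synthgen.generate_clock_movie(
        synthgen.ClockSpec(seed=0, n_frames=90, noise_sigma=0.0))


@pytest.fixture(autouse=True)
def _quiet_pixel_size_warnings():
    """The 1 µm/px working-resolution warning is expected noise in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
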