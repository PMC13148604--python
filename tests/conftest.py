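"""Shared fixtures: seeded synthetic frames used across the suite."""

import numpy as np
import pytest

from paganin_autotune import (Image2D, default_spec, make_dataset,
                              normalize_flat)


def normalized_phantom(seed: int, shape=(64, 64), **overrides) -> Image2D:
    """Flat-field-normalized noisy phantom frame for one seed."""
    ds = make_dataset(default_spec(seed, shape=shape, **overrides))
    return normalize_flat(ds.I, ds.I0)


@pytest.fixture(scope="session")
def noisy_frame() -> Image2D:
    """The standard fixed-seed noisy 64x64 test frame."""
    return normalized_phantom(1)


@pytest.fixture(scope="session")
def noisy_frame_128() -> Image2D:
    """A larger fixed-seed frame for spectral-resolution-sensitive checks."""
    return normalized_phantom(7, shape=(128, 128))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
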