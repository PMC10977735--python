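"""Shared fixtures: tiny analytic masks and one cached synthetic field."""

import numpy as np
import pytest

from mitomorph.synthgen import SynthParams, generate_field


@pytest.fixture
def bar_mask():
    """Horizontal 100x5 bar inside a 64x128 frame."""
    mask = np.zeros((64, 128), dtype=bool)
    mask[30:35, 10:110] = True
    return mask


@pytest.fixture
def cross_mask():
    """Plus sign: two 61-px-long, 3-px-wide arms crossing at the centre."""
    mask = np.zeros((80, 80), dtype=bool)
    mask[39:42, 10:71] = True
    mask[10:71, 39:42] = True
    return mask


@pytest.fixture(scope="session")
def synth_field():
    """One default synthetic field plus its ground truth (session-cached)."""
    return generate_field(SynthParams(seed=11))


@pytest.fixture(scope="session")
def noiseless_field():
    """A noise-free, lightly blurred field for recovery checks."""
    return generate_field(SynthParams(seed=11, noise_level=0.0, psf_sigma=0.5))
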