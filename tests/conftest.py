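"""Shared fixtures: small synthetic curves and batches.

Everything is generated programmatically with fixed seeds; hypothesis runs
derandomized so the suite is reproducible bit-for-bit.
"""

import numpy as np
import pytest
from hypothesis import settings

from afmcp import SampleProfile, generate_curve

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_profile() -> SampleProfile:
    return SampleProfile(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_curve(noiseless_profile):
    """One ideal thin-sample curve (h = 3 um) with ground truth."""
    return generate_curve(noiseless_profile, seed=7, h_true=3000.0)


@pytest.fixture(scope="session")
def noisy_curve():
    """One realistic curve: 1 nm deflection noise, random thickness."""
    return generate_curve(SampleProfile(noise_sd=1.0), seed=3)


@pytest.fixture(scope="session")
def small_profile() -> SampleProfile:
    """Coarser sampling for fast pipeline/CLI tests."""
    return SampleProfile(noise_sd=0.5, n_points=512)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
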