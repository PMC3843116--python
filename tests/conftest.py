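"""Shared fixtures: expensive model objects built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from lamellae.analysis import get_modulus_interpolator
from lamellae.homogenization import FibrilArrayParams, fibril_array_stiffness


@pytest.fixture(scope="session")
def default_params() -> FibrilArrayParams:
    return FibrilArrayParams()


@pytest.fixture(scope="session")
def array_tensor(default_params):
    """Fibril-array stiffness at the default parameter set (phi=0.38)."""
    return fibril_array_stiffness(default_params)


@pytest.fixture(scope="session")
def modulus_interp(default_params):
    """Cached (phi, theta) interpolation grid of the full model chain."""
    return get_modulus_interpolator(default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130501)
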