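"""Shared fixtures: synthetic fields and a small equilibrated membrane."""

import numpy as np
import pytest

import ldpf


@pytest.fixture(scope="session")
def stripe_field():
    """Half-Lo / half-Ld stripe; Lo area fraction exactly 0.5."""
    return ldpf.make_fixture_field("stripe", L=64)


@pytest.fixture(scope="session")
def uniform_field():
    """Constant cbar = 0.75 (all Ld)."""
    return ldpf.make_fixture_field("uniform", L=64)


@pytest.fixture(scope="session")
def bimodal_field():
    """Smoothed two-level random field mimicking a phase-separated membrane."""
    return ldpf.make_fixture_field("bimodal", L=64, seed=42)


def make_uniform(value, L=32):
    """A constant normalized field with arbitrary cbar level."""
    return ldpf.NormalizedField(cbar=np.full((L, L), float(value)),
                                c_min=0.0, c_max=1.0, dx=1.0)


@pytest.fixture(scope="session")
def model5_field_64():
    """Reservoir-coupled membrane (model 5) equilibrated on a 64^2 grid."""
    state = ldpf.equilibrate_model(5, L=64, seed=1)
    return ldpf.normalize_field(state)
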