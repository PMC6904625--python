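"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from stromametry import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A reduced phantom (96x128x128, 20 vesicles) for fast unit tests."""
    return PhantomSpec(shape=(96, 128, 128), n_vesicles=20, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def eight_phantoms():
    """Eight full-size phantom replicates (seeds 1..8), one per placenta."""
    return [generate_phantom(PhantomSpec(seed=s)) for s in range(1, 9)]


class FixedRng:
    """Minimal generator stub producing predetermined draws, for tests
    that pin the random start or grid offset."""

    def __init__(self, integers=0, uniforms=0.0):
        self._integers = integers
        self._uniforms = uniforms

    def integers(self, low, high=None):
        return self._integers

    def uniform(self, low, high):
        return low + self._uniforms * (high - low)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
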