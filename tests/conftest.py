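import numpy as np
import pytest

from polimage import MediumSpec, SphereSpec, TwoSphereSystem


@pytest.fixture(scope="session")
def vacuum():
    return MediumSpec(1.0)


@pytest.fixture(scope="session")
def fig2_factory(vacuum):
    """Two a = 1.25 nm spheres, Q1 = -1e, Q2 = -7e, eps = 20, in vacuum —
    the canonical charge-asymmetric system that exhibits like-charge
    attraction at short separations."""

    def make(R: float) -> TwoSphereSystem:
        return TwoSphereSystem(
            SphereSpec(a=1.25, eps_in=20.0, Q=-1.0),
            SphereSpec(a=1.25, eps_in=20.0, Q=-7.0),
            vacuum,
            R,
        )

    return make


def numeric_derivative(f, x, h):
    """Richardson-extrapolated central difference (for cross-checking
    analytic derivatives in tests)."""
    d1 = (f(x + h) - f(x - h)) / (2 * h)
    d2 = (f(x + h / 2) - f(x - h / 2)) / h
    return (4 * d2 - d1) / 3


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
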