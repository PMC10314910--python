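import numpy as np
import pytest

from nemshell.geometry import ShapeProfile, build_surface_grid


@pytest.fixture(scope="session")
def sphere_profile() -> ShapeProfile:
    """Unit sphere: theta = pi s / Ls, Ls = pi, all amplitudes zero."""
    return ShapeProfile(np.pi, np.zeros(16), np.pi)


@pytest.fixture(scope="session")
def sphere_grid(sphere_profile):
    return build_surface_grid(sphere_profile, 41, 41)


@pytest.fixture()
def wavy_profile() -> ShapeProfile:
    """A smooth, closed, mildly deformed shape for refinement oracles.

    Even-mode perturbations preserve mirror symmetry, so the profile closes
    identically; amplitudes are small enough that rho > 0 in the interior.
    """
    amps = np.zeros(8)
    amps[1] = 0.22   # a_2
    amps[3] = -0.05  # a_4
    return ShapeProfile(np.pi, amps, np.pi)
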