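"""Axisymmetric surface geometry from a Fourier tangent-angle parameterization.

A closed surface of revolution is described by its profile curve in the
(rho, z) half-plane, parameterized by arc length s in [0, Ls].  The tangent
angle theta(s) (measured from the plane perpendicular to the symmetry axis)
is expanded as

    theta(s) = theta0 * s/Ls + sum_i a_i sin(pi * i * s / Ls),

so that theta(0)=0 and theta(Ls)=theta0 hold identically; theta0 = pi for a
smooth closed shell of spherical topology.  The profile coordinates follow
by quadrature, rho(s) = int cos(theta), z(s) = int sin(theta), and the
closure condition rho(Ls)=0 is the only remaining constraint.

All lengths are measured in units of R = sqrt(A / 4*pi); after every shape
update the profile is rescaled so that the total area is exactly 4*pi
(see :func:`rescale_to_unit_area`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

__all__ = [
    "ShapeProfile",
    "SurfaceGrid",
    "GeometryMeasures",
    "eval_theta",
    "integrate_profile",
    "principal_curvatures",
    "geodesic_curvature_parallels",
    "surface_measures",
    "closure_residual",
    "build_surface_grid",
    "rescale_to_unit_area",
    "simpson_weights",
]


@dataclass(frozen=True)
class ShapeProfile:
    """Complete shape degree of freedom: Fourier amplitudes plus curve length.

    Attributes
    ----------
    theta0:
        Tangent angle at the end of the profile curve (radians); pi for
        closed smooth shells of spherical topology.
    amplitudes:
        Fourier amplitudes a_1 .. a_N (dimensionless).
    Ls:
        Length of the profile curve, in units of R.
    """

    theta0: float
    amplitudes: np.ndarray
    Ls: float

    def __post_init__(self) -> None:
        if self.Ls <= 0:
            raise ValueError(f"profile curve length must be positive, got {self.Ls}")
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))

    @property
    def n_modes(self) -> int:
        return self.amplitudes.size

    def with_amplitudes(self, amplitudes: np.ndarray) -> "ShapeProfile":
        return replace(self, amplitudes=np.asarray(amplitudes, dtype=float))


@dataclass
class SurfaceGrid:
    """Discretized geometry of the surface of revolution on an (s, phi) grid.

    The s grid is uniform and includes both poles; phi covers [0, 2*pi) with
    n_phi equally spaced points (periodic, no duplicate endpoint).  With the
    arc-length parameterization the first fundamental form has E = rho^2,
    F = 0, G = 1, so the Jacobian is J = rho.
    """

    s_nodes: np.ndarray
    phi_nodes: np.ndarray
    rho: np.ndarray
    z: np.ndarray
    theta: np.ndarray
    dtheta: np.ndarray  # d(theta)/ds, analytic from the Fourier series
    C1: np.ndarray
    C2: np.ndarray
    H: np.ndarray
    K: np.ndarray
    D: np.ndarray
    kg2: np.ndarray  # geodesic curvature of parallels; 0 stored at poles
    J: np.ndarray
    self_intersecting: bool = False
    profile: ShapeProfile | None = None
    _w_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_s(self) -> int:
        return self.s_nodes.size

    @property
    def n_phi(self) -> int:
        return self.phi_nodes.size

    @property
    def ds(self) -> float:
        return float(self.s_nodes[1] - self.s_nodes[0])

    @property
    def dphi(self) -> float:
        return 2.0 * np.pi / self.n_phi

    @property
    def w_s(self) -> np.ndarray:
        """Composite-Simpson weights for line integrals along s."""
        if self._w_s is None:
            self._w_s = simpson_weights(self.n_s, self.ds)
        return self._w_s

    @property
    def height(self) -> float:
        """Pole-to-pole extent along the symmetry axis."""
        return float(self.z[-1] - self.z[0])


@dataclass(frozen=True)
class GeometryMeasures:
    area: float
    volume: float
    reduced_volume: float
    R_eff: float


def simpson_weights(n: int, ds: float) -> np.ndarray:
    """Composite Simpson weights on a uniform grid of n (odd) nodes."""
    if n < 3 or n % 2 == 0:
        raise ValueError(f"Simpson rule needs an odd number of nodes >= 3, got {n}")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (ds / 3.0)


def eval_theta(profile: ShapeProfile, s_nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate theta(s) and its analytic derivative on the given nodes.

    Returns
    -------
    theta, dtheta : arrays of the tangent angle and d(theta)/ds.
    """
    s = np.asarray(s_nodes, dtype=float)
    eps = 1e-12 * max(profile.Ls, 1.0)
    if np.any(s < -eps) or np.any(s > profile.Ls + eps):
        raise ValueError("arc-length samples must lie within [0, Ls]")
    i = np.arange(1, profile.n_modes + 1)
    phase = np.outer(s, i) * (np.pi / profile.Ls)  # (n_s, N)
    theta = profile.theta0 * s / profile.Ls + np.sin(phase) @ profile.amplitudes
    dtheta = profile.theta0 / profile.Ls + np.cos(phase) @ (
        profile.amplitudes * i * np.pi / profile.Ls
    )
    return theta, dtheta


def integrate_profile(profile: ShapeProfile, n_s: int) -> SurfaceGrid:
    """Cumulative quadrature of the profile curve on a uniform s grid.

    Fills s_nodes, rho, z, theta, dtheta of a :class:`SurfaceGrid`; the
    curvature fields are completed by :func:`principal_curvatures` /
    :func:`build_surface_grid`.  A trial profile with negative intermediate
    rho (self-intersecting) is flagged, not clipped.
    """
    if n_s < 3:
        raise ValueError("need at least 3 s nodes")
    s = np.linspace(0.0, profile.Ls, n_s)
    theta, dtheta = eval_theta(profile, s)
    rho = cumulative_simpson(np.cos(theta), x=s, initial=0.0)
    z = cumulative_simpson(np.sin(theta), x=s, initial=0.0)
    ds = s[1] - s[0]
    flag = bool(np.any(rho[1:-1] < -1e-9 * ds))
    nan = np.full(n_s, np.nan)
    return SurfaceGrid(
        s_nodes=s,
        phi_nodes=np.zeros(0),
        rho=rho,
        z=z,
        theta=theta,
        dtheta=dtheta,
        C1=nan.copy(),
        C2=nan.copy(),
        H=nan.copy(),
        K=nan.copy(),
        D=nan.copy(),
        kg2=nan.copy(),
        J=rho.copy(),
        self_intersecting=flag,
        profile=profile,
    )


def _pole_mask(grid: SurfaceGrid) -> np.ndarray:
    mask = np.zeros(grid.n_s, dtype=bool)
    mask[0] = mask[-1] = True
    return mask


def principal_curvatures(grid: SurfaceGrid) -> tuple[np.ndarray, np.ndarray]:
    """Principal curvatures C1 = d(theta)/ds and C2 = sin(theta)/rho.

    At the two pole nodes C2 is assigned the limit value C1 (umbilic pole of
    a smooth axisymmetric surface).  A vanishing rho at a non-pole node is a
    degenerate shape and raises.
    """
    interior = ~_pole_mask(grid)
    if np.any(np.abs(grid.rho[interior]) < 1e-13):
        raise ValueError("rho vanishes at a non-pole node: degenerate shape")
    C1 = grid.dtheta.copy()
    C2 = np.empty_like(C1)
    C2[interior] = np.sin(grid.theta[interior]) / grid.rho[interior]
    C2[0], C2[-1] = C1[0], C1[-1]
    grid.C1, grid.C2 = C1, C2
    grid.H = 0.5 * (C1 + C2)
    grid.K = C1 * C2
    grid.D = 0.5 * (C1 - C2)
    return C1, C2


def geodesic_curvature_parallels(grid: SurfaceGrid) -> np.ndarray:
    """Geodesic curvature of the parallels, kg2 = rho_,s / rho = cos(theta)/rho.

    Diverges at the poles; the stored pole value is 0 and pole rings are
    excluded from kg2-weighted integrands (their area element J vanishes
    there in any case).
    """
    interior = ~_pole_mask(grid)
    kg2 = np.zeros(grid.n_s)
    kg2[interior] = np.cos(grid.theta[interior]) / grid.rho[interior]
    grid.kg2 = kg2
    return kg2


def surface_measures(grid: SurfaceGrid) -> GeometryMeasures:
    """Area, enclosed volume, reduced volume and effective radius.

    A = 2*pi * int rho ds and V = pi * int rho^2 sin(theta) ds under the
    arc-length parameterization (composite Simpson); the reduced volume is
    v = V / V0 with V0 = (4*pi/3) * R_eff^3 the volume of the sphere with
    the same area.
    """
    s = grid.s_nodes
    area = 2.0 * np.pi * simpson(grid.rho, x=s)
    volume = np.pi * simpson(grid.rho**2 * np.sin(grid.theta), x=s)
    R_eff = np.sqrt(area / (4.0 * np.pi))
    v = volume / ((4.0 * np.pi / 3.0) * R_eff**3)
    return GeometryMeasures(area=float(area), volume=float(volume),
                            reduced_volume=float(v), R_eff=float(R_eff))


def closure_residual(profile: ShapeProfile, n_s: int = 201) -> float:
    """rho(Ls) = int_0^Ls cos(theta) ds; zero for admissible closed shapes."""
    s = np.linspace(0.0, profile.Ls, n_s if n_s % 2 == 1 else n_s + 1)
    theta, _ = eval_theta(profile, s)
    return float(simpson(np.cos(theta), x=s))


def build_surface_grid(profile: ShapeProfile, n_s: int, n_phi: int = 0) -> SurfaceGrid:
    """Integrate the profile and fill all curvature fields in one call."""
    grid = integrate_profile(profile, n_s)
    grid.phi_nodes = np.linspace(0.0, 2.0 * np.pi, max(n_phi, 0), endpoint=False)
    principal_curvatures(grid)
    geodesic_curvature_parallels(grid)
    return grid


def rescale_to_unit_area(profile: ShapeProfile, n_s: int = 201) -> ShapeProfile:
    """Rescale the profile length so that the surface area is exactly 4*pi.

    Amplitudes and theta0 are dimensionless and unchanged; only Ls scales.
    This pins the length unit to R = sqrt(A/4*pi) = 1.
    """
    grid = integrate_profile(profile, n_s if n_s % 2 == 1 else n_s + 1)
    area = 2.0 * np.pi * simpson(grid.rho, x=grid.s_nodes)
    if area <= 0:
        raise ValueError("non-positive area; profile is degenerate")
    return replace(profile, Ls=profile.Ls * np.sqrt(4.0 * np.pi / area))
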