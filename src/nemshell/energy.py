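"""Free energy of a closed flexible shell with in-plane nematic order.

Four densities are integrated over the surface:

    f_b = (kappa/2) (C1 + C2 - C0)^2            isotropic Helfrich bending
    f_c = -alpha Tr Q^2 + (beta/2)(Tr Q^2)^2    nematic condensation
    f_i = (k_i/2) |grad_s Q|^2                  intrinsic elasticity
    f_e = (k_e/2) (C - Cp)^2                    deviatoric molecular bending

with Tr Q^2 = 2 (q0^2 + qm^2) and C = H + D cos(2 eta) the normal curvature
seen by a molecule at angle eta from the first principal direction (Euler's
relation).  Energies are reported in units of k_i; lengths in units of R.

In the disordered phase (or inside defect cores) all molecular orientations
are equally probable, so f_e is replaced by its uniform average over eta,
(k_e/2)[(H - Cp)^2 + D^2/2], which acts as an effective isotropic
spontaneous-curvature preference.  A linear blend over
lambda/lambda0 in [0.05, 0.15] connects the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import SurfaceGrid
from .nematic import NematicTexture, gradient_energy_density

__all__ = [
    "ModelParams",
    "EnergyBreakdown",
    "bending_density",
    "condensation_density",
    "euler_curvature",
    "deviatoric_density",
    "total_free_energy",
    "equilibrium_lambda",
]

#: blend window of lambda/lambda0 between orientation-averaged and
#: director forms of the deviatoric density
LAM_ISO_LO = 0.05
LAM_ISO_HI = 0.15


@dataclass(frozen=True)
class ModelParams:
    """Physical coefficients, in units of k_i = 1 and lengths of R = 1.

    alpha > 0 is the nematic (ordered) phase, alpha < 0 the isotropic one;
    its magnitude is set by the order-parameter correlation length through
    |alpha| = (R/xi)^2 * k_i.  beta = beta_factor * |alpha|; the default
    beta = 4|alpha| corresponds to sqrt(alpha/beta) = 1/2, placing the
    equilibrium order amplitude lambda0 = sqrt(alpha/(2 beta)) ~ 0.354
    comfortably inside the admissible interval [0, 1/2].
    """

    kappa: float = 1.0 / 60.0
    C0: float = 0.0
    Cp: float = 0.0
    ke: float = 0.2
    ki: float = 1.0
    R_over_xi: float = 10.0
    beta_factor: float = 4.0
    fe_order_weighted: bool = False  # scale the ordered-phase deviatoric
    # density by lambda/lambda0 (off: the plain density already covers the
    # ordered-phase phenomenology)
    nematic_phase: bool = True
    v_target: float = 0.6
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        a = self.ki * self.R_over_xi**2
        object.__setattr__(self, "alpha", a if self.nematic_phase else -a)
        object.__setattr__(self, "beta", self.beta_factor * a)

    def quenched(self) -> "ModelParams":
        """Same material across the order-disorder transition: flip sign of alpha."""
        return replace(self, nematic_phase=not self.nematic_phase)

    @property
    def lam0(self) -> float:
        return equilibrium_lambda(self.alpha, self.beta)

    @property
    def xi(self) -> float:
        return np.sqrt(self.ki / abs(self.alpha))


@dataclass(frozen=True)
class EnergyBreakdown:
    """Integrated contributions, in units of k_i."""

    Fb: float
    Fc: float
    Fi: float
    Fe: float

    @property
    def Ftot(self) -> float:
        return self.Fb + self.Fc + self.Fi + self.Fe

    def as_dict(self) -> dict[str, float]:
        return {"Fb": self.Fb, "Fc": self.Fc, "Fi": self.Fi, "Fe": self.Fe,
                "Ftot": self.Ftot}


def equilibrium_lambda(alpha: float, beta: float) -> float:
    """Minimizer of the condensation density, lambda0 = sqrt(alpha/(2 beta)).

    With Tr Q^2 = 2 lambda^2 the density reads -2 alpha lambda^2
    + 2 beta lambda^4, minimized at lambda^2 = alpha/(2 beta) where it
    equals -alpha^2/(2 beta).  Returns 0 in the isotropic phase
    (alpha <= 0).
    """
    if alpha <= 0.0:
        return 0.0
    return float(np.sqrt(alpha / (2.0 * beta)))


def bending_density(grid: SurfaceGrid, params: ModelParams) -> np.ndarray:
    """Helfrich density (kappa/2)(C1 + C2 - C0)^2 per s node."""
    return 0.5 * params.kappa * (grid.C1 + grid.C2 - params.C0) ** 2


def condensation_density(texture: NematicTexture, params: ModelParams) -> np.ndarray:
    trq2 = 2.0 * (texture.q0**2 + texture.qm**2)
    return -params.alpha * trq2 + 0.5 * params.beta * trq2**2


def euler_curvature(H: np.ndarray, D: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Normal curvature C = H + D cos(2 eta) seen at angle eta from e1."""
    return H + D * np.cos(2.0 * np.asarray(eta))


def deviatoric_density(
    texture: NematicTexture, grid: SurfaceGrid, params: ModelParams
) -> np.ndarray:
    """Deviatoric molecular bending density (k_e/2)(C - Cp)^2 per node.

    Uses the director angle where the local order is well developed and the
    uniform orientation average (H - Cp)^2 + D^2/2 where it is not, with a
    linear blend over lambda/lambda0 in [0.05, 0.15].
    """
    H = grid.H[:, None]
    D = grid.D[:, None]
    f_avg = 0.5 * params.ke * ((H - params.Cp) ** 2 + 0.5 * D**2)
    lam0 = params.lam0
    if lam0 <= 0.0:
        return np.broadcast_to(f_avg, texture.shape).copy()
    lam = texture.lam
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2eta = np.where(lam > 0.0, texture.q0 / np.where(lam > 0.0, lam, 1.0), 0.0)
    f_dir = 0.5 * params.ke * (H + D * cos2eta - params.Cp) ** 2
    if params.fe_order_weighted:
        f_dir = f_dir * np.minimum(lam / lam0, 1.0)
    t = np.clip((lam / lam0 - LAM_ISO_LO) / (LAM_ISO_HI - LAM_ISO_LO), 0.0, 1.0)
    return t * f_dir + (1.0 - t) * f_avg


def _integrate(grid: SurfaceGrid, density: np.ndarray) -> float:
    """Surface integral of a density field with the Jacobian J = rho.

    Accepts a per-row (s only) or full (s, phi) field; composite Simpson in
    s, uniform (trapezoid) rule in the periodic phi direction.
    """
    # rho < 0 marks unphysical overlap in a trial shape; such nodes carry no
    # area (and must not enter as negative weights the relaxation could mine)
    wJ = grid.w_s * np.maximum(grid.J, 0.0)
    if density.ndim == 1:
        return float(2.0 * np.pi * (wJ @ density))
    return float((wJ @ density.sum(axis=1)) * grid.dphi)


def total_free_energy(
    texture: NematicTexture,
    grid: SurfaceGrid,
    params: ModelParams,
    include_extrinsic: bool = False,
) -> EnergyBreakdown:
    """Integrate the four densities over the shell surface."""
    fb = bending_density(grid, params)
    fc = condensation_density(texture, params)
    fi = gradient_energy_density(texture, grid, params.ki, include_extrinsic)
    fe = deviatoric_density(texture, grid, params)
    for name, f in (("bending", fb), ("condensation", fc),
                    ("intrinsic", fi), ("deviatoric", fe)):
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"NaN/inf in {name} density")
    return EnergyBreakdown(
        Fb=_integrate(grid, fb),
        Fc=_integrate(grid, fc),
        Fi=_integrate(grid, fi),
        Fe=_integrate(grid, fe),
    )
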