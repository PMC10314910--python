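"""Surface nematic order: (q0, qm) fields, elastic energy and defects.

The in-plane order tensor on the surface is written in the orthonormal
principal frame {e1 (meridian), e2 (parallel)} as

    Q = q0 (e1 x e1 - e2 x e2) + qm (e1 x e2 + e2 x e1),

equivalently Q = lambda (n x n - n_perp x n_perp) with order amplitude
lambda = sqrt(q0^2 + qm^2) in [0, 1/2] and director angle eta measured from
the meridian, cos(2 eta) = q0/lambda, sin(2 eta) = qm/lambda.  Points with
lambda = 0 are topological defect cores; the total winding number on a
closed shell of spherical topology is 2 (Poincare-Hopf / Gauss-Bonnet).

The intrinsic elastic density f_i = (k_i/2)|grad_s Q|^2 is evaluated with
the tangential part of the surface gradient only: on a surface of
revolution the frame rotates along the parallels at the geodesic-curvature
rate kg2, so the covariant components are

    D_s q0 = d(q0)/ds,                 D_s qm = d(qm)/ds,
    D_p q0 = (1/rho) d(q0)/dphi - 2 kg2 qm,
    D_p qm = (1/rho) d(qm)/dphi + 2 kg2 q0,

and |grad_s Q|^2 = 2 [(D_s q0)^2 + (D_s qm)^2 + (D_p q0)^2 + (D_p qm)^2].
The normal (extrinsic) components -C1 v x e1, -C2 v x e2 of the frame
gradients are excluded by default — curvature coupling enters through the
deviatoric bending term instead — but can be switched on, adding
(C1^2 + C2^2) Tr Q^2 to |grad_s Q|^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import SurfaceGrid

__all__ = [
    "NematicTexture",
    "Defect",
    "DefectSet",
    "order_and_director",
    "gradient_energy_density",
    "detect_defects",
    "total_charge",
]


@dataclass
class NematicTexture:
    """(q0, qm) scalar fields on the (s, phi) grid, periodic in phi."""

    q0: np.ndarray
    qm: np.ndarray

    def __post_init__(self) -> None:
        self.q0 = np.asarray(self.q0, dtype=float)
        self.qm = np.asarray(self.qm, dtype=float)
        if self.q0.shape != self.qm.shape:
            raise ValueError("q0 and qm must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.q0.shape

    @property
    def lam(self) -> np.ndarray:
        """Order amplitude lambda = sqrt(q0^2 + qm^2)."""
        return np.hypot(self.q0, self.qm)

    def copy(self) -> "NematicTexture":
        return NematicTexture(self.q0.copy(), self.qm.copy())


@dataclass
class Defect:
    s: float
    phi: float
    m: float
    rows: tuple[int, int]  # s-row span of the core region
    kind: str = "interior"  # interior | pole | ring
    confident: bool = True


@dataclass
class DefectSet:
    defects: list[Defect] = field(default_factory=list)

    def __iter__(self):
        return iter(self.defects)

    def __len__(self) -> int:
        return len(self.defects)

    @property
    def charges(self) -> list[float]:
        return [d.m for d in self.defects]


def total_charge(defects: DefectSet) -> float:
    """Sum of winding numbers; 2 for spherical topology with isolated zeros."""
    return float(sum(d.m for d in defects))


def order_and_director(texture: NematicTexture) -> tuple[np.ndarray, np.ndarray]:
    """Order amplitude and director angle fields.

    Returns lambda and eta = (1/2) atan2(qm, q0) mapped to [0, pi); the
    director is headless.  Where lambda = 0 the angle is undefined and NaN
    is returned there (defect flag).
    """
    lam = texture.lam
    eta = 0.5 * np.arctan2(texture.qm, texture.q0)
    eta = np.mod(eta, np.pi)
    eta = np.where(lam > 0.0, eta, np.nan)
    return lam, eta


def _shift_fwd_s(f: np.ndarray, ds: float) -> np.ndarray:
    out = np.zeros_like(f)
    out[:-1] = (f[1:] - f[:-1]) / ds
    return out


def _shift_bwd_s(f: np.ndarray, ds: float) -> np.ndarray:
    out = np.zeros_like(f)
    out[1:] = (f[1:] - f[:-1]) / ds
    return out


def gradient_energy_density(
    texture: NematicTexture,
    grid: SurfaceGrid,
    ki: float = 1.0,
    include_extrinsic: bool = False,
) -> np.ndarray:
    """Intrinsic elastic density f_i = (k_i/2)|grad_s Q|^2 per grid node.

    Each covariant component is discretized as the mean of the squared
    forward and backward one-sided differences (periodic in phi), which is
    second-order accurate for smooth fields and, unlike a plain central
    difference, leaves no checkerboard zero mode for the Monte Carlo
    relaxation to exploit.  The 1/rho azimuthal terms live on interior
    rings only; pole rows carry zero area weight and are stored as 0.
    """
    n_s, n_phi = texture.shape
    if n_s != grid.n_s or n_phi != grid.n_phi:
        raise ValueError("texture and grid dimensions differ")
    ds, dphi = grid.ds, grid.dphi
    q0, qm = texture.q0, texture.qm

    s_part = 0.5 * (
        _shift_fwd_s(q0, ds) ** 2 + _shift_bwd_s(q0, ds) ** 2
        + _shift_fwd_s(qm, ds) ** 2 + _shift_bwd_s(qm, ds) ** 2
    )

    inv_rho = np.zeros(n_s)
    inv_rho[1:-1] = 1.0 / grid.rho[1:-1]
    scale = (inv_rho / dphi)[:, None]
    kg2 = grid.kg2[:, None]
    fwd0 = scale * (np.roll(q0, -1, axis=1) - q0) - 2.0 * kg2 * qm
    bwd0 = scale * (q0 - np.roll(q0, 1, axis=1)) - 2.0 * kg2 * qm
    fwdm = scale * (np.roll(qm, -1, axis=1) - qm) + 2.0 * kg2 * q0
    bwdm = scale * (qm - np.roll(qm, 1, axis=1)) + 2.0 * kg2 * q0
    p_part = 0.5 * (fwd0**2 + bwd0**2 + fwdm**2 + bwdm**2)
    p_part[0] = p_part[-1] = 0.0

    f = ki * (s_part + p_part)
    if include_extrinsic:
        f = f + ki * (grid.C1**2 + grid.C2**2)[:, None] * (q0**2 + qm**2)
    return f


# ---------------------------------------------------------------------------
# Defect detection
# ---------------------------------------------------------------------------

def _principal(delta: np.ndarray | float):
    """Wrap an angle increment to (-pi, pi]."""
    return -((np.pi - np.asarray(delta)) % (2.0 * np.pi)) + np.pi


def detect_defects(
    texture: NematicTexture,
    grid: SurfaceGrid,
    lam0: float,
    lam_threshold: float = 0.2,
) -> DefectSet:
    """Locate defect cores and their winding numbers.

    The winding is accumulated on elementary grid plaquettes: the phase
    2*eta = atan2(qm, q0) is single-valued for a nematic, so summing its
    principal-value increments around each (s, phi) cell yields an exact
    multiple of 2*pi, i.e. a half-integer charge per cell.  The principal
    frame carries index +1 at each pole, so the cap regions inside the
    first/last regular ring contribute 1 +/- the ring winding.  By
    telescoping, the reported total charge is exactly 2 on any closed
    texture, as Poincare-Hopf requires.

    Nonzero plaquettes are clustered (8-connected, periodic in phi) into
    defects with summed charges; clusters within two rows of a pole are
    absorbed into the pole cap.  A defect is flagged low-confidence when a
    phase step on its plaquettes approaches the +/-pi unwrap ambiguity or
    when no order-parameter dip (lambda < lam_threshold * lam0) supports
    the core.
    """
    n_s, n_phi = texture.shape
    lam = texture.lam
    two_eta = np.arctan2(texture.qm, texture.q0)
    thr = lam_threshold * lam0
    out = DefectSet()

    # phase increments on links
    d_phi = _principal(np.roll(two_eta, -1, axis=1) - two_eta)  # (n_s, n_phi)
    d_s = _principal(two_eta[1:] - two_eta[:-1])                # (n_s-1, n_phi)
    wind = d_phi.sum(axis=1) / (4.0 * np.pi)                    # ring windings

    # charge per plaquette between rows i and i+1 (i = 1 .. n_s - 3);
    # the loop bottom(+phi) right(+s) top(-phi) left(-s) runs clockwise in
    # (phi, s), so the enclosed charge is minus the accumulated phase
    plaq = (d_phi[:-1] + np.roll(d_s, -1, axis=1) - d_phi[1:] - d_s)
    charge = -plaq / (4.0 * np.pi)
    charge = np.round(2.0 * charge) / 2.0
    pole_margin = 2
    charge[0] = 0.0          # cells touching the pole fan belong to the caps
    charge[n_s - 2 :] = 0.0
    risky = np.abs(d_phi) > np.pi - 0.05

    # pole caps: everything inside the first/last regular ring, plus any
    # clusters within pole_margin rows of the pole
    cap_rows_n = pole_margin
    cap_rows_s = n_s - 2 - pole_margin
    m_north = 1.0 + wind[1] + charge[1:cap_rows_n + 1].sum()
    m_south = 1.0 - wind[n_s - 2] + charge[cap_rows_s:].sum()
    m_north = round(2.0 * m_north) / 2.0
    m_south = round(2.0 * m_south) / 2.0
    charge[: cap_rows_n + 1] = 0.0
    charge[cap_rows_s:] = 0.0

    if m_north != 0.0 or lam[: pole_margin + 1].min() < thr:
        conf = not (risky[1].any() or risky[: pole_margin + 1].any())
        out.defects.append(Defect(s=float(grid.s_nodes[0]), phi=0.0,
                                  m=m_north, rows=(0, pole_margin),
                                  kind="pole", confident=bool(conf)))
    if m_south != 0.0 or lam[n_s - 1 - pole_margin :].min() < thr:
        conf = not (risky[n_s - 2].any() or risky[n_s - 1 - pole_margin :].any())
        out.defects.append(Defect(s=float(grid.s_nodes[-1]), phi=0.0,
                                  m=m_south, rows=(n_s - 1 - pole_margin, n_s - 1),
                                  kind="pole", confident=bool(conf)))

    mask = charge != 0.0
    if not mask.any():
        return out
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    # merge components across the periodic phi seam
    for i in range(mask.shape[0]):
        a, b = labels[i, 0], labels[i, -1]
        if a > 0 and b > 0 and a != b:
            labels[labels == max(a, b)] = min(a, b)
    s_mid = 0.5 * (grid.s_nodes[:-1] + grid.s_nodes[1:])
    phi_mid = grid.phi_nodes + 0.5 * grid.dphi if n_phi else np.zeros(0)
    for k in np.unique(labels[labels > 0]):
        sel = labels == k
        m = float(charge[sel].sum())
        wgt = np.abs(charge) * sel
        tot = wgt.sum()
        if tot == 0.0:
            wgt = sel.astype(float)
            tot = wgt.sum()
        s_pos = float((wgt.sum(axis=1) @ s_mid) / tot)
        c = (wgt * np.cos(phi_mid)[None, :]).sum()
        sn = (wgt * np.sin(phi_mid)[None, :]).sum()
        phi_pos = float(np.mod(np.arctan2(sn, c), 2.0 * np.pi))
        rows = np.where(sel.any(axis=1))[0]
        # confidence: unambiguous phase steps and a supporting order dip
        cells = np.argwhere(sel)
        rlo, rhi = cells[:, 0].min(), cells[:, 0].max() + 1
        dip = lam[rlo : rhi + 1].min() < thr
        conf = dip and not (risky[rlo : rhi + 1].any())
        out.defects.append(Defect(s=s_pos, phi=phi_pos, m=m,
                                  rows=(int(rows.min()), int(rows.max() + 1)),
                                  kind="interior", confident=bool(conf)))
    return out
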