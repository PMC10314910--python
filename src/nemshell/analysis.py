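"""Post-processing of relaxed configurations."""

from __future__ import annotations

import numpy as np

from .geometry import ShapeProfile, build_surface_grid
from .nematic import NematicTexture

__all__ = ["mean_tilt"]


def mean_tilt(
    texture: NematicTexture,
    profile: ShapeProfile,
    n_s: int,
    n_phi: int,
    theta_band: float = 0.35,
) -> float:
    """Mean director tilt relative to the symmetry axis, in [0, pi/2].

    Evaluated on the tube-like part of the surface (tangent angle within
    ``theta_band`` of pi/2, where the meridian runs along the axis) as the
    order- and area-weighted average of the node-wise tilt folded into
    [0, pi/2].  The folding makes the measure blind to the handedness of
    the spiral state (+eta and -eta tilts are degenerate and may coexist
    as domains).  On a tube, tilt 0 means molecules along the axis; pi/2
    means along the parallels (the orientation a strongly curved molecule
    prefers).
    """
    grid = build_surface_grid(profile, n_s, n_phi)
    rows = np.where(np.abs(grid.theta - 0.5 * np.pi) < theta_band)[0]
    rows = rows[(rows > 0) & (rows < n_s - 1)]
    if rows.size == 0:
        return float("nan")
    lam = texture.lam[rows]
    w = lam * (grid.w_s * np.maximum(grid.J, 0.0))[rows, None]
    if w.sum() <= 0.0:
        return float("nan")
    two_eta = np.arctan2(texture.qm[rows], texture.q0[rows])
    tilt = 0.5 * np.abs(two_eta)  # headless + mirror-degenerate: [0, pi/2]
    return float((w * tilt).sum() / w.sum())
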