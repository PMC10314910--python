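"""Alternating equilibrium search for shape and texture.

One outer iteration relaxes the (q0, qm) texture by annealed Metropolis
Monte Carlo on the frozen shape, then adjusts the shape by derivative-free
minimization over the Fourier amplitudes with the texture frozen.  The
surface area is pinned to 4*pi by exact rescaling of Ls after every shape
update, so the amplitudes are the only shape degrees of freedom; the
reduced volume, profile closure, non-negativity of rho, and the optional
minimum pole-to-pole height (stretching force) are enforced by quadratic
penalties with weight escalation.  Competing branches (oblate, prolate,
stomatocyte, ...) are run from their own seed profiles and compared by
total energy; near-ties mark discontinuous morphological transitions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import minimize as scipy_minimize
from scipy.signal import argrelmin

from . import _mc
from .energy import EnergyBreakdown, ModelParams, total_free_energy
from .fixtures import random_texture, seed_profile
from .geometry import (
    ShapeProfile,
    SurfaceGrid,
    build_surface_grid,
    closure_residual,
    eval_theta,
    integrate_profile,
    rescale_to_unit_area,
    surface_measures,
)
from .nematic import DefectSet, NematicTexture, detect_defects, total_charge

__all__ = [
    "RunConfig",
    "RunResult",
    "ShapeClassification",
    "mc_relax_texture",
    "optimize_shape",
    "alternate_minimize",
    "classify_shape",
    "branch_compare",
]


class RunConfig(BaseModel):
    """Numerical settings of one equilibrium run.

    Defaults follow the reference protocol (101 x 101 grid, 80 Fourier
    modes); :meth:`small` returns a reduced preset for desk-scale runs.
    """

    model_config = ConfigDict(extra="forbid")

    n_s: int = 101
    n_phi: int = 101
    n_modes: int = 80
    mc_sweeps: int = 2000         # sweeps in the first relaxation stage
    mc_sweeps_refine: int = 60    # sweeps per stage after the first
    t_cool: float = 0.995         # geometric cooling factor per sweep
    quench_fraction: float = 0.2  # trailing fraction of sweeps at T = 0
    step_q: float = 0.08          # Gaussian proposal width for q0, qm
    max_alternations: int = 30
    ftol: float = 1e-3            # relative energy change for convergence
    patience: int = 3
    shape_block: int = 10         # Fourier modes optimized per Powell block
    shape_maxfev: int = 400       # objective evaluations per block
    w_closure: float = 1e4
    w_volume: float = 1e5
    w_negative_rho: float = 1e6
    w_height: float = 1e4
    tol_v: float = 1e-3
    tol_closure: float = 1e-3
    lam_threshold: float = 0.2
    texture_init: str = "branch"  # branch | meridian | random | zero
    include_extrinsic: bool = True
    h_min: float = 0.0
    branch: str = "prolate"
    seed: int = 0

    def model_post_init(self, _ctx) -> None:
        if self.n_s < 11 or self.n_phi < 11:
            raise ValueError("grid dimensions must be at least 11")
        if self.n_s % 2 == 0:
            raise ValueError("n_s must be odd (composite Simpson rule)")
        if self.h_min < 0:
            raise ValueError("h_min must be non-negative")

    @classmethod
    def small(cls, **overrides) -> "RunConfig":
        """Reduced preset: 41 x 41 grid, 16 modes, shortened MC schedule."""
        base = dict(n_s=41, n_phi=41, n_modes=16, mc_sweeps=1000, t_cool=0.99,
                    mc_sweeps_refine=40, max_alternations=18, shape_maxfev=300)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ShapeClassification:
    label: str  # sphere | oblate | prolate | stomatocyte | phi_shape | necklace
    confident: bool = True

    @property
    def base(self) -> str:
        """Coarse class: phi_shape and necklace are prolate sub-labels."""
        return "prolate" if self.label in ("phi_shape", "necklace") else self.label


@dataclass
class RunResult:
    profile: ShapeProfile
    texture: NematicTexture
    energy: EnergyBreakdown
    defects: DefectSet
    shape_class: ShapeClassification
    params: ModelParams
    config: RunConfig
    trace: list[dict] = dc_field(default_factory=list)
    converged: bool = True
    v_residual: float = 0.0
    closure: float = 0.0
    seconds: float = 0.0

    @property
    def Ftot(self) -> float:
        return self.energy.Ftot


def _mc_arrays(grid: SurfaceGrid):
    W = grid.w_s * np.maximum(grid.J, 0.0) * grid.dphi
    inv_rho = np.zeros(grid.n_s)
    inv_rho[1:-1] = 1.0 / grid.rho[1:-1]
    return (W, 1.0 / (2.0 * grid.ds), 1.0 / (2.0 * grid.dphi), inv_rho,
            grid.kg2, grid.H, grid.D, grid.C1, grid.C2)


def mc_relax_texture(
    texture: NematicTexture,
    grid: SurfaceGrid,
    params: ModelParams,
    config: RunConfig,
    seed: int,
    n_sweeps: int | None = None,
    t_scale: float = 1.0,
) -> tuple[NematicTexture, dict]:
    """Annealed Metropolis relaxation of the texture on a frozen shape.

    Proposals mix steps in the (q0, qm) disc with pure director rotations
    (the soft direction of the stiff condensation potential).  The
    starting temperature is calibrated from the mean |dE| of probe moves
    (initial acceptance near 1/2), cooled geometrically each sweep, and
    the trailing ``quench_fraction`` of sweeps runs greedy (T = 0).
    A fixed seed gives a bit-identical trajectory.
    """
    geo = _mc_arrays(grid)
    phys = (params.alpha, params.beta, params.ki, params.ke, params.Cp,
            params.lam0, config.include_extrinsic, params.fe_order_weighted)
    q0 = np.ascontiguousarray(texture.q0)
    qm = np.ascontiguousarray(texture.qm)
    n = n_sweeps if n_sweeps is not None else config.mc_sweeps
    scale = _mc.probe_scale(q0, qm, *geo, *phys, config.step_q, 400,
                            (seed + 1) % 2**31)
    T0 = t_scale * 1.44 * scale
    n_quench = max(int(config.quench_fraction * n), 1)
    n_anneal = n - n_quench
    T_arr = np.concatenate([
        T0 * config.t_cool ** np.arange(n_anneal), np.zeros(n_quench)
    ])
    texture.q0, texture.qm = q0, qm
    chi0 = optimal_global_rotation(texture, grid, params)
    q0 = np.ascontiguousarray(texture.q0)
    qm = np.ascontiguousarray(texture.qm)
    trace, acc = _mc.mc_run(q0, qm, *geo, *phys, T_arr, np.full(n, 0.5),
                            config.step_q, seed % 2**31)
    # exact collective descent move, then a short greedy polish
    texture.q0, texture.qm = q0, qm
    chi1 = optimal_global_rotation(texture, grid, params)
    q0 = np.ascontiguousarray(texture.q0)
    qm = np.ascontiguousarray(texture.qm)
    n_polish = max(n // 10, 5)
    trace_p, acc_p = _mc.mc_run(q0, qm, *geo, *phys, np.zeros(n_polish),
                                np.full(n_polish, 0.5), config.step_q,
                                (seed + 5) % 2**31)
    trace = np.concatenate([trace, trace_p])
    acc = np.concatenate([acc, acc_p])
    stats = {
        "global_rotation": (float(chi0), float(chi1)),
        "T_start": float(T0),
        "acceptance": acc,
        "energy_trace": trace,
        "n_sweeps": n,
    }
    mean_acc = float(np.mean(acc[: max(n_anneal, 1)]))
    if not 0.05 <= mean_acc <= 0.95:
        stats["warning"] = f"acceptance rate {mean_acc:.2f} outside [0.05, 0.95]"
    texture.q0, texture.qm = q0, qm
    return texture, stats


def optimal_global_rotation(
    texture: NematicTexture,
    grid: SurfaceGrid,
    params: ModelParams,
) -> float:
    """Rotate the whole director field to minimize the deviatoric energy.

    A global rotation of (q0, qm) by chi (director by chi/2) leaves the
    condensation and intrinsic elastic energies exactly invariant, so the
    optimal chi minimizes only the deviatoric term — a closed quadratic
    form in (cos chi, sin chi), evaluated on a fine angle grid.  This
    collective move nucleates the uniformly tilted state on tubes, which
    single-site proposals cannot reach against the gradient barrier.
    Applies the rotation in place; returns chi.
    """
    lam0 = params.lam0
    if lam0 <= 0.0 or params.ke == 0.0:
        return 0.0
    from .energy import LAM_ISO_HI, LAM_ISO_LO

    lam = texture.lam
    with np.errstate(invalid="ignore"):
        u = np.where(lam > 0, texture.q0 / np.where(lam > 0, lam, 1.0), 0.0)
        v = np.where(lam > 0, texture.qm / np.where(lam > 0, lam, 1.0), 0.0)
    t = np.clip((lam / lam0 - LAM_ISO_LO) / (LAM_ISO_HI - LAM_ISO_LO), 0.0, 1.0)
    W = (grid.w_s * np.maximum(grid.J, 0.0) * grid.dphi)[:, None]
    w = W * t * 0.5 * params.ke
    a = (grid.H - params.Cp)[:, None]
    d = grid.D[:, None]
    s1 = float((w * a * d * u).sum())
    s2 = float((w * a * d * v).sum())
    s3 = float((w * d**2 * u**2).sum())
    s4 = float((w * d**2 * u * v).sum())
    s5 = float((w * d**2 * v**2).sum())
    chi = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)
    X, Y = np.cos(chi), np.sin(chi)
    fe = 2 * s1 * X - 2 * s2 * Y + s3 * X**2 - 2 * s4 * X * Y + s5 * Y**2
    best = float(chi[np.argmin(fe)])
    c, s = np.cos(best), np.sin(best)
    q0 = c * texture.q0 - s * texture.qm
    qm = s * texture.q0 + c * texture.qm
    texture.q0, texture.qm = q0, qm
    return best


def _penalized_energy(
    amplitudes: np.ndarray,
    base: ShapeProfile,
    texture: NematicTexture,
    params: ModelParams,
    config: RunConfig,
    weights: dict,
) -> float:
    prof = base.with_amplitudes(amplitudes)
    try:
        prof = rescale_to_unit_area(prof, config.n_s)
        grid = build_surface_grid(prof, config.n_s, config.n_phi)
        meas = surface_measures(grid)
        eb = total_free_energy(texture, grid, params, config.include_extrinsic)
    except (ValueError, FloatingPointError):
        return 1e12
    pen = weights["closure"] * grid.rho[-1] ** 2
    pen += weights["volume"] * (meas.reduced_volume - params.v_target) ** 2
    neg = np.minimum(grid.rho, 0.0)
    pen += weights["neg"] * float(neg @ neg) * grid.ds
    if config.h_min > 0.0:
        pen += weights["height"] * max(0.0, config.h_min - grid.height) ** 2
    return eb.Ftot + pen


def optimize_shape(
    profile: ShapeProfile,
    texture: NematicTexture,
    params: ModelParams,
    config: RunConfig,
) -> ShapeProfile:
    """Powell minimization over Fourier amplitudes, in low-to-high blocks.

    Area is held at 4*pi exactly by rescaling inside the objective; volume
    and closure are quadratic penalties whose weights escalate (x10, up to
    three times) until the residuals meet their tolerances.  The returned
    profile never has a larger penalized objective than the input.
    """
    weights = {"closure": config.w_closure, "volume": config.w_volume,
               "neg": config.w_negative_rho, "height": config.w_height}
    x = profile.amplitudes.copy()

    for _escalation in range(3):
        def obj(a):
            return _penalized_energy(a, profile, texture, params, config, weights)

        f_best = obj(x)
        x_best = x.copy()
        for _pass in range(3):
            f_pass_start = f_best
            for lo in range(0, x.size, config.shape_block):
                hi = min(lo + config.shape_block, x.size)
                sl = slice(lo, hi)

                def obj_block(xb, sl=sl):
                    y = x_best.copy()
                    y[sl] = xb
                    return obj(y)

                res = scipy_minimize(
                    obj_block, x_best[sl], method="Powell",
                    options={"maxfev": config.shape_maxfev, "xtol": 1e-5,
                             "ftol": 1e-8},
                )
                if res.fun < f_best:
                    f_best = res.fun
                    x_best[sl] = res.x
            if f_pass_start - f_best < 1e-6 * (1.0 + abs(f_best)):
                break
        x = x_best
        prof = rescale_to_unit_area(profile.with_amplitudes(x), config.n_s)
        grid = build_surface_grid(prof, config.n_s, config.n_phi)
        v = surface_measures(grid).reduced_volume
        cl = grid.rho[-1]
        if abs(v - params.v_target) <= config.tol_v and abs(cl) <= config.tol_closure:
            break
        weights = {k: 10.0 * w for k, w in weights.items()}
    return prof


def classify_shape(profile: ShapeProfile, n_s: int = 401) -> ShapeClassification:
    """Deterministic classification of a closed profile.

    stomatocyte: the tangent angle exceeds pi in the interior AND the
    profile ends on an enclosed invagination (the closing pole sits well
    below the top of the fold; a marginal theta overshoot on a deeply
    dimpled discocyte does not count).  Otherwise oblate if the equatorial
    radius exceeds the pole-to-pole half-height, else prolate, with
    sub-labels phi_shape (two necks framing the widest section) and
    necklace (any interior neck).
    """
    n_s = n_s if n_s % 2 == 1 else n_s + 1
    grid = integrate_profile(profile, n_s)
    s = grid.s_nodes
    theta, _ = eval_theta(profile, s)
    meas = surface_measures(grid)
    if meas.reduced_volume > 0.99:
        return ShapeClassification("sphere")
    z_span = float(grid.z.max() - grid.z.min())
    invag_depth = max(grid.z.max() - grid.z[-1], grid.z[0] - grid.z.min())
    if np.max(theta[1:-1]) > np.pi + 0.05 and invag_depth > 0.1 * z_span:
        return ShapeClassification(
            "stomatocyte", confident=np.max(theta[1:-1]) > np.pi + 0.2)
    rho_max = float(grid.rho.max())
    half_height = 0.5 * abs(grid.height)
    if rho_max > half_height:
        margin = rho_max / max(half_height, 1e-12)
        return ShapeClassification("oblate", confident=margin > 1.05)
    # prolate family: look for necks in the interior of the profile
    interior = slice(2, n_s - 2)
    minima = argrelmin(grid.rho[interior], order=max(3, n_s // 50))[0] + 2
    neck_level = 0.75 * rho_max
    necks = [int(i) for i in minima if grid.rho[i] < neck_level]
    if len(necks) >= 2:
        i_widest = int(np.argmax(grid.rho))
        if necks[0] < i_widest < necks[-1]:
            return ShapeClassification("phi_shape")
        return ShapeClassification("necklace")
    if len(necks) == 1:
        return ShapeClassification("necklace")
    confident = half_height / max(rho_max, 1e-12) > 1.05
    return ShapeClassification("prolate", confident=confident)


def _initial_texture(
    profile: ShapeProfile,
    params: ModelParams,
    config: RunConfig,
    rng: np.random.Generator,
) -> NematicTexture:
    """Starting texture for an equilibrium run.

    "branch" seeds each shape branch with the defect arrangement
    compatible with its geometry — four +1/2 cores near the equator for
    the oblate, +1 at each pole (a uniform meridian field) for tubular
    branches, the 2x(+1/2) outer + invaginated +1 split for the
    stomatocyte — mirroring the multi-initial-condition protocol for the
    shapes themselves.  "meridian" is the uniform minimal arrangement,
    "random" a fully disordered start, "zero" the isotropic state.
    """
    shape = (config.n_s, config.n_phi)
    if params.lam0 <= 0.0 or config.texture_init == "zero":
        return NematicTexture(np.zeros(shape), np.zeros(shape))
    if config.texture_init == "random":
        return random_texture(shape, 0.4, rng)
    mode = config.texture_init
    if mode == "branch":
        mode = {"oblate": "oblate", "stomatocyte": "stomatocyte"}.get(
            config.branch, "meridian")
    lam_bg = 0.95 * params.lam0
    if mode == "meridian":
        noise = random_texture(shape, 0.05, rng)
        return NematicTexture(np.full(shape, lam_bg) + noise.q0, noise.qm)
    from .fixtures import make_defect_texture

    grid = build_surface_grid(profile, config.n_s, config.n_phi)
    Ls = profile.Ls
    if mode == "oblate":
        placed = [(0.45 * Ls, 0.0, 0.5), (0.55 * Ls, 0.5 * np.pi, 0.5),
                  (0.45 * Ls, np.pi, 0.5), (0.55 * Ls, 1.5 * np.pi, 0.5)]
    elif mode == "stomatocyte":
        placed = [(0.3 * Ls, 0.0, 0.5), (0.3 * Ls, np.pi, 0.5),
                  (Ls, 0.0, 1.0)]
    else:
        raise ValueError(f"unknown texture_init {config.texture_init!r}")
    tex = make_defect_texture(grid, placed, lam_background=lam_bg)
    noise = random_texture(shape, 0.05, rng)
    return NematicTexture(tex.q0 + noise.q0, tex.qm + noise.qm)


def alternate_minimize(
    config: RunConfig,
    params: ModelParams,
    profile: ShapeProfile | None = None,
    texture: NematicTexture | None = None,
) -> RunResult:
    """Full equilibrium search: alternate MC texture relaxation and shape
    optimization until the total energy stalls.

    The seed shape comes from the branch fixture named in the config unless
    a profile is supplied; the texture starts from a seeded random state in
    the nematic phase (zero in the isotropic phase).
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    if profile is None:
        profile = seed_profile(config.branch, params.v_target, config.n_modes)
    elif profile.n_modes != config.n_modes:
        amps = np.zeros(config.n_modes)
        amps[: min(profile.n_modes, config.n_modes)] = profile.amplitudes[
            : min(profile.n_modes, config.n_modes)]
        profile = profile.with_amplitudes(amps)
    profile = rescale_to_unit_area(profile, config.n_s)
    if texture is None:
        texture = _initial_texture(profile, params, config, rng)

    trace: list[dict] = []
    F_prev = None
    stall = 0
    converged = False
    # refine stages get sweeps proportional to the number of sites so
    # large grids equilibrate as well per alternation as small ones
    site_factor = max(1, (config.n_s * config.n_phi) // (41 * 41))
    for it in range(config.max_alternations):
        grid = build_surface_grid(profile, config.n_s, config.n_phi)
        n_sweeps = (config.mc_sweeps if it == 0
                    else config.mc_sweeps_refine * site_factor)
        t_scale = 1.0 if it == 0 else 0.3
        texture, _stats = mc_relax_texture(
            texture, grid, params, config, seed=config.seed + 7919 * it,
            n_sweeps=n_sweeps, t_scale=t_scale)
        profile = optimize_shape(profile, texture, params, config)
        grid = build_surface_grid(profile, config.n_s, config.n_phi)
        eb = total_free_energy(texture, grid, params, config.include_extrinsic)
        meas = surface_measures(grid)
        rec = eb.as_dict()
        rec.update(iteration=it, v=meas.reduced_volume, closure=grid.rho[-1])
        trace.append(rec)
        if F_prev is not None:
            if abs(eb.Ftot - F_prev) < config.ftol * (1.0 + abs(eb.Ftot)):
                stall += 1
            else:
                stall = 0
            if stall >= config.patience:
                converged = True
                break
        F_prev = eb.Ftot

    grid = build_surface_grid(profile, config.n_s, config.n_phi)
    # final re-anneal and quench of the texture on the final shape
    texture, _ = mc_relax_texture(texture, grid, params, config,
                                  seed=config.seed + 104729,
                                  n_sweeps=config.mc_sweeps, t_scale=0.3)
    eb = total_free_energy(texture, grid, params, config.include_extrinsic)
    meas = surface_measures(grid)
    if params.lam0 > 0.0:
        defects = detect_defects(texture, grid, params.lam0, config.lam_threshold)
    else:
        defects = DefectSet()
    return RunResult(
        profile=profile,
        texture=texture,
        energy=eb,
        defects=defects,
        shape_class=classify_shape(profile),
        params=params,
        config=config,
        trace=trace,
        converged=converged,
        v_residual=meas.reduced_volume - params.v_target,
        closure=float(grid.rho[-1]),
        seconds=time.time() - t0,
    )


def branch_compare(
    results: list[RunResult], tie_tol: float = 1e-3
) -> tuple[RunResult, float, list[RunResult]]:
    """Pick the equilibrium among branch candidates by total energy.

    Returns (winner, margin to runner-up, coexisting results).  Energies
    within ``tie_tol * |Ftot|`` of the winner are reported as coexistence —
    the marker of a discontinuous morphological transition.  All results
    must share physical parameters.
    """
    if not results:
        raise ValueError("no results to compare")
    p0 = results[0].params
    if any(r.params != p0 for r in results[1:]):
        raise ValueError("branch comparison across different parameters")
    order = sorted(results, key=lambda r: r.Ftot)
    best = order[0]
    margin = order[1].Ftot - best.Ftot if len(order) > 1 else np.inf
    coexisting = [r for r in order[1:]
                  if r.Ftot - best.Ftot <= tie_tol * abs(best.Ftot)]
    return best, float(margin), coexisting
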