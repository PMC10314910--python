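"""Configuration, serialization and export plumbing for reproducible runs.

A run archive is a directory holding everything needed to inspect or
re-run a simulation: a YAML config snapshot, the profile curve as CSV, the
(q0, qm) texture in HDF5, the defect table as CSV, the energy breakdown as
JSON, the per-iteration trace as CSV and a legacy-ASCII VTK PolyData mesh
for 3D visualization.  Floats are serialized at full double precision so
that reloading reproduces energies bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .energy import ModelParams, total_free_energy
from .geometry import ShapeProfile, build_surface_grid
from .minimize import RunConfig, RunResult
from .nematic import DefectSet, NematicTexture, order_and_director

__all__ = [
    "ConfigFile",
    "load_config",
    "save_config",
    "write_profile_csv",
    "read_profile_csv",
    "write_texture",
    "read_texture",
    "write_defects_csv",
    "export_mesh",
    "save_run",
    "load_run",
]


class ConfigFile(BaseModel):
    """User-facing run configuration (YAML).  Unknown keys are rejected.

    Physical defaults follow the reference study: ke = ki/5, kappa = ki/60,
    C0 = 0, R/xi = 10; `v` and `cp` must be given explicitly.
    """

    model_config = ConfigDict(extra="forbid")

    v: float = Field(gt=0.0, lt=1.0)
    cp: float
    ke: float = 0.2
    kappa: float = 1.0 / 60.0
    c0: float = 0.0
    r_over_xi: float = 10.0
    nematic_phase: bool = True
    run: RunConfig = Field(default_factory=RunConfig)

    def to_params(self) -> ModelParams:
        return ModelParams(kappa=self.kappa, C0=self.c0, Cp=self.cp,
                           ke=self.ke, R_over_xi=self.r_over_xi,
                           nematic_phase=self.nematic_phase, v_target=self.v)


def load_config(path: str | Path) -> tuple[RunConfig, ModelParams]:
    """Parse a YAML config; validation errors name the offending key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = ConfigFile(**raw)
    except ValidationError as err:
        raise ValueError(f"invalid config {path}: {err}") from err
    return cfg.run, cfg.to_params()


def save_config(path: str | Path, config: RunConfig, params: ModelParams) -> None:
    doc = {
        "v": params.v_target, "cp": params.Cp, "ke": params.ke,
        "kappa": params.kappa, "c0": params.C0,
        "r_over_xi": params.R_over_xi, "nematic_phase": params.nematic_phase,
        "run": json.loads(config.model_dump_json()),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_profile_csv(path: str | Path, profile: ShapeProfile, n_s: int) -> None:
    grid = build_surface_grid(profile, n_s if n_s % 2 else n_s + 1)
    df = pd.DataFrame({
        "s": grid.s_nodes, "rho": grid.rho, "z": grid.z, "theta": grid.theta,
        "C1": grid.C1, "C2": grid.C2, "H": grid.H, "K": grid.K,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_texture(path: str | Path, texture: NematicTexture,
                  s_nodes: np.ndarray, phi_nodes: np.ndarray,
                  attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("q0", data=texture.q0)
        f.create_dataset("qm", data=texture.qm)
        f.create_dataset("s_nodes", data=s_nodes)
        f.create_dataset("phi_nodes", data=phi_nodes)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_texture(path: str | Path) -> tuple[NematicTexture, np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        tex = NematicTexture(f["q0"][...], f["qm"][...])
        s = f["s_nodes"][...]
        phi = f["phi_nodes"][...]
        attrs = dict(f.attrs)
    return tex, s, phi, attrs


def write_defects_csv(path: str | Path, defects: DefectSet) -> None:
    df = pd.DataFrame(
        [{"s": d.s, "phi": d.phi, "m": d.m, "kind": d.kind,
          "confident": d.confident} for d in defects]
    )
    df.to_csv(path, index=False, float_format="%.17g")


def export_mesh(profile: ShapeProfile, texture: NematicTexture | None,
                path: str | Path, n_s: int, n_phi: int,
                lam0: float = 0.5) -> None:
    """Triangulated surface of revolution as legacy-ASCII VTK PolyData.

    Vertices are the interior grid rings plus one merged vertex per pole
    ((n_s - 2) * n_phi + 2 points); per-vertex data carry the normalized
    order lambda/lambda0 and the in-plane director as a 3D vector.
    """
    grid = build_surface_grid(profile, n_s, n_phi)
    warn = abs(grid.rho[-1]) > 1e-3
    phi = grid.phi_nodes
    pts = [np.array([0.0, 0.0, grid.z[0]])]
    for i in range(1, n_s - 1):
        ring = np.stack([grid.rho[i] * np.cos(phi), grid.rho[i] * np.sin(phi),
                         np.full(n_phi, grid.z[i])], axis=1)
        pts.append(ring)
    pts.append(np.array([0.0, 0.0, grid.z[-1]]))
    points = np.vstack([p if p.ndim == 2 else p[None, :] for p in pts])

    def vid(i: int, j: int) -> int:
        if i == 0:
            return 0
        if i == n_s - 1:
            return points.shape[0] - 1
        return 1 + (i - 1) * n_phi + (j % n_phi)

    tris = []
    for j in range(n_phi):  # pole fans
        tris.append((vid(0, 0), vid(1, j), vid(1, j + 1)))
        tris.append((vid(n_s - 1, 0), vid(n_s - 2, j + 1), vid(n_s - 2, j)))
    for i in range(1, n_s - 2):  # quad strips
        for j in range(n_phi):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            tris.append((a, b, d))
            tris.append((a, d, c))

    if texture is not None:
        lam, eta = order_and_director(texture)
        eta = np.nan_to_num(eta)
        ct, st = np.cos(grid.theta), np.sin(grid.theta)
        lam_pts = np.empty(points.shape[0])
        dir_pts = np.zeros((points.shape[0], 3))
        lam_pts[0] = lam[0].mean()
        lam_pts[-1] = lam[-1].mean()
        for i in range(1, n_s - 1):
            for j in range(n_phi):
                k = vid(i, j)
                lam_pts[k] = lam[i, j]
                e1 = np.array([ct[i] * np.cos(phi[j]), ct[i] * np.sin(phi[j]), st[i]])
                e2 = np.array([-np.sin(phi[j]), np.cos(phi[j]), 0.0])
                dir_pts[k] = np.cos(eta[i, j]) * e1 + np.sin(eta[i, j]) * e2
    else:
        lam_pts = np.zeros(points.shape[0])
        dir_pts = np.zeros((points.shape[0], 3))

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"nemshell surface{' (non-closed profile!)' if warn else ''}\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {points.shape[0]} double\n")
        for p in points:
            f.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        f.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"POINT_DATA {points.shape[0]}\n")
        f.write("SCALARS lambda_norm double 1\nLOOKUP_TABLE default\n")
        for v in lam_pts / max(lam0, 1e-12):
            f.write(f"{v:.10g}\n")
        f.write("VECTORS director double\n")
        for d in dir_pts:
            f.write(f"{d[0]:.10g} {d[1]:.10g} {d[2]:.10g}\n")


def save_run(out_dir: str | Path, result: RunResult) -> Path:
    """Write a complete run archive; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, params = result.config, result.params
    save_config(out / "config.yaml", cfg, params)
    (out / "shape.json").write_text(json.dumps({
        "theta0": result.profile.theta0,
        "Ls": result.profile.Ls,
        "amplitudes": result.profile.amplitudes.tolist(),
    }))
    write_profile_csv(out / "profile.csv", result.profile, cfg.n_s)
    grid = build_surface_grid(result.profile, cfg.n_s, cfg.n_phi)
    write_texture(out / "texture.h5", result.texture, grid.s_nodes,
                  grid.phi_nodes, {"seed": cfg.seed})
    write_defects_csv(out / "defects.csv", result.defects)
    (out / "energy.json").write_text(json.dumps({
        **result.energy.as_dict(),
        "shape_class": result.shape_class.label,
        "total_charge": float(sum(d.m for d in result.defects)),
        "converged": result.converged,
        "v_residual": result.v_residual,
        "closure": result.closure,
        "seconds": result.seconds,
    }, indent=2))
    pd.DataFrame(result.trace).to_csv(out / "trace.csv", index=False,
                                      float_format="%.17g")
    export_mesh(result.profile, result.texture, out / "mesh.vtk",
                cfg.n_s, cfg.n_phi, lam0=max(params.lam0, 1e-12))
    return out


def load_run(run_dir: str | Path) -> tuple[ShapeProfile, NematicTexture,
                                           RunConfig, ModelParams, dict]:
    run = Path(run_dir)
    cfg, params = load_config(run / "config.yaml")
    shape = json.loads((run / "shape.json").read_text())
    profile = ShapeProfile(shape["theta0"], np.array(shape["amplitudes"]),
                           shape["Ls"])
    texture, *_ = read_texture(run / "texture.h5")
    energy = json.loads((run / "energy.json").read_text())
    return profile, texture, cfg, params, energy


def recompute_energy(run_dir: str | Path) -> float:
    """Ftot recomputed from a stored archive (archive integrity check)."""
    profile, texture, cfg, params, _ = load_run(run_dir)
    grid = build_surface_grid(profile, cfg.n_s, cfg.n_phi)
    return total_free_energy(texture, grid, params, cfg.include_extrinsic).Ftot
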