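# nemshell

Equilibrium shapes of closed flexible shells with in-plane nematic order.

Thin closed membranes — lipid vesicles, liquid-crystal shells — that are
covered by curved rod-like molecules (bent-core mesogens, BAR-domain
proteins) couple two fields: the 3D shape of the shell and the in-plane
orientational order of the molecules on it. `nemshell` finds joint
equilibria of both fields for axisymmetric shells of spherical topology
at fixed area and reduced volume, for people studying vesicle
morphology, membrane-protein organization, or nematic shells.

## Model

The total free energy is the surface integral

F = ∮ [ κ/2 (C₁+C₂−C₀)²  −  α Tr Q² + β/2 (Tr Q²)²
        + k_i/2 |∇ₛQ|²  +  k_e/2 (C−C_p)² ] dA

with principal curvatures C₁, C₂, spontaneous curvature C₀, the 2D
surface order tensor Q (amplitude λ ∈ [0, ½], director n), and
C = H + D cos 2η the normal curvature seen by a molecule at angle η from
the first principal direction (H, D: mean curvature and curvature
deviator; C_p: the molecule's intrinsic curvature). Lengths are in units
of R = √(A/4π), energies in units of k_i; the correlation length
ξ = √(k_i/|α|) fixes |α|. Shapes are surfaces of revolution whose
tangent angle is a Fourier series θ(s) = πs/L_s + Σ aᵢ sin(πis/L_s);
equilibria alternate annealed Metropolis Monte Carlo on the (q₀, q_m)
texture with constrained Powell minimization over the amplitudes at
fixed area and reduced volume v. Closed shells force total director
winding 2 (Poincaré–Hopf), carried by point defects where λ → 0.
Competing branches (oblate, prolate, stomatocyte) are relaxed separately
and compared by energy. See `docs/methods.md` for the numerics.

## Worked example

Relax the prolate branch at reduced volume v = 0.60 with strongly curved
molecules (C_p = 2.0, k_e = k_i/5, κ = k_i/60, R/ξ = 10):

```python
import numpy as np
import nemshell as ns
from nemshell.minimize import RunConfig, alternate_minimize
from nemshell.analysis import mean_tilt

cfg = RunConfig.small(seed=1, branch="prolate", max_alternations=8)
params = ns.ModelParams(Cp=2.0, v_target=0.60)
res = alternate_minimize(cfg, params)

print(res.shape_class.label)                    # prolate
print(f"Ftot = {res.Ftot:.2f} ki")              # Ftot = -141.30 ki
print(ns.total_charge(res.defects))             # 2.0
tilt = mean_tilt(res.texture, res.profile, cfg.n_s, cfg.n_phi)
print(f"tilt = {np.degrees(tilt):.0f} deg")     # tilt = 66 deg
```

The shell stays a tube (the fixed reduced volume pins its radius
r_t ≈ 0.43), the texture is defect-free on the tube wall with one +1
defect at each pole, and the molecules spiral around the tube at the
angle where the curvature they see along their length, sin²η / r_t,
equals C_p — here arcsin √(C_p r_t) ≈ 67°. Raising C_p beyond
1/r_t ≈ 2.3 makes a perfect fit impossible at any tilt and the molecular
bending energy starts to grow as (C_p − 1/r_t)²; whether the shell then
pays that penalty or squeezes out thinner protrusions depends on the
gradient-energy convention (see `docs/methods.md`).

A thin CLI wraps the same calls: `nemshell run --v 0.4 --cp 1.5
--branch stomatocyte --out runs/s15`, `nemshell sweep 0 3 --v 0.4`,
`nemshell report runs/s15`.

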