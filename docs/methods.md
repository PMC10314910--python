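# Methods

## Model

`nemshell` computes equilibrium shapes of closed, axisymmetric, flexible
shells carrying in-plane nematic order, together with the corresponding
ordering textures. The physical picture is a thin membrane (a lipid
vesicle or a liquid-crystal shell) densely and homogeneously covered by
curved rod-like molecules — bent-core mesogens or BAR-family proteins —
that (i) order orientationally in the surface plane and (ii) sense the
local membrane curvature along their own length.

The free energy is a surface integral of four densities:

| term | density | role |
|------|---------|------|
| bending | (κ/2)(C₁+C₂−C₀)² | Helfrich spontaneous-curvature elasticity of the bare shell |
| condensation | −α Tr Q² + (β/2)(Tr Q²)² | Landau potential driving nematic order below the transition |
| intrinsic elastic | (k_i/2)\|∇ₛQ\|² | penalizes spatial variation of the order tensor |
| deviatoric | (k_e/2)(C−C_p)² | mismatch between the curvature C seen by a molecule and its intrinsic curvature C_p |

Here Q is the 2D surface order tensor with amplitude λ ∈ [0, ½] and
director n; in the principal frame {e₁ (meridian), e₂ (parallel)} it is
parameterized by two scalars, Q = q₀(e₁⊗e₁−e₂⊗e₂) + q_m(e₁⊗e₂+e₂⊗e₁),
with λ = √(q₀²+q_m²) and director angle η given by cos 2η = q₀/λ,
sin 2η = q_m/λ. The curvature seen by a molecule at angle η from the
first principal direction is Euler's relation C = H + D cos 2η, with mean
curvature H = (C₁+C₂)/2 and curvature deviator D = (C₁−C₂)/2.

Constraints: fixed surface area A and enclosed volume V, i.e. fixed
reduced volume v = V/V₀ with V₀ the volume of the equal-area sphere.
Closed shells of spherical topology force the director field to carry
total winding number 2 (Poincaré–Hopf), realized as point defects where
λ → 0.

### Units and parameter closure

All lengths are in units of R = √(A/4π) (so A = 4π identically) and all
energies in units of k_i. The correlation length ξ = √(k_i/|α|) fixes
|α| = (R/ξ)² k_i; the default R/ξ = 10 gives α = ±100 (sign: + nematic,
− isotropic phase; a temperature quench is a sign flip of α only).
The quartic coefficient is β = 4|α|. This is the closure under which the
frequently quoted equilibrium amplitude √(α/β) equals ½: written with
Tr Q² = 2λ² the condensation density −2αλ² + 2βλ⁴ is then minimized at
λ₀ = √(α/2β) = ½√2 ≈ 0.354, safely inside the admissible [0, ½], with
depth −α²/2β and equilibrium Tr Q² = ¼ — the same physical energetics as
the λ₀ = ½ state of the Tr Q² = λ² bookkeeping. The choice matters
beyond cosmetics: β sets how much every Q-quadratic energy (elastic,
defect, curvature-coupled) weighs against the λ-independent deviatoric
term, and therefore where the shape branches exchange stability.
Default couplings: k_e = k_i/5, κ = k_i/60, C₀ = 0; C_p and v are the
control parameters of interest.

### Intrinsic vs extrinsic gradients

On a surface of revolution the frame rotates along parallels at the
geodesic-curvature rate κ_g2 = cos θ/ρ, giving tangential covariant
components D_s q₀ = ∂_s q₀, D_φ q₀ = (1/ρ)∂_φ q₀ − 2κ_g2 q_m (and the
q_m pair with +2κ_g2 q₀). The frame derivatives additionally generate
normal (extrinsic) components −C₁ v⊗e₁, −C₂ v⊗e₂, whose squared norm is
(C₁²+C₂²) Tr Q² — an orientation-independent penalty on maintaining
order on curved surface.

Equilibrium runs include the extrinsic components by default
(`include_extrinsic` in the run configuration; the density function's
own default is tangential-only, which is what the embedding oracle in
the tests checks). The physics forced this choice: in a tangential-only
model a meridian-aligned texture costs exactly zero elastic energy on a
cylinder wall, so nothing penalizes arbitrarily narrow tubes when the
bare bending rigidity is as small as κ = k_i/60, and tubular branches
win the branch comparison at every C_p. The extrinsic penalty is what
makes highly curved tubes pay through suppressed order — the mechanism
by which the condensation term disfavors narrow prolates and opens the
low-C_p oblate window.

### Deviatoric term in the disordered regime

Where the local order is well developed the deviatoric density uses the
director angle. Where λ → 0 (defect cores, or the whole surface in the
isotropic phase) all orientations are equally probable and the density is
replaced by its uniform average over η, (k_e/2)[(H−C_p)² + D²/2] — an
effective isotropic spontaneous-curvature preference, which is what makes
the isotropic-phase shapes resemble classical C₀ ≠ 0 Helfrich shapes.
A linear blend over λ/λ₀ ∈ [0.05, 0.15] connects the regimes without an
energy jump. An optional switch weights the ordered-phase density by
λ/λ₀; it is off by default (the plain form already reproduces the
ordered-phase phenomenology, and the λ-weight would make the deviatoric
coupling vanish spuriously inside broad disordered patches).

## Discretization

**Shape.** The profile-curve tangent angle is a truncated Fourier series
θ(s) = θ₀ s/L_s + Σᵢ aᵢ sin(πis/L_s) with θ₀ = π; ρ and z follow by
cumulative Simpson quadrature of cos θ and sin θ on a uniform s grid that
includes both poles. C₁ = θ′(s) is analytic (term-by-term derivative,
never finite-differenced); C₂ = sin θ/ρ, with the umbilic limit C₂ = C₁
assigned at the poles. Line integrals use composite Simpson in s (odd
node count required) and the exact uniform rule in the periodic φ
direction. After every shape update L_s is rescaled so the area is
exactly 4π; the amplitudes are therefore the only shape degrees of
freedom, and L_s is not optimized separately.

**Texture.** (q₀, q_m) live on the same (s, φ) grid. Gradient components
are discretized as the mean of squared forward and backward one-sided
differences (periodic in φ). This is second-order accurate for smooth
fields and deliberately avoids plain central differences, whose decoupled
even/odd sublattices admit checkerboard zero modes that a Monte Carlo
sampler will happily populate. Pole rows carry zero area weight; their
1/ρ azimuthal terms are excluded. Nodes where a trial shape has ρ < 0
(self-intersection) are clamped to zero quadrature weight everywhere —
negative weights would otherwise act as an unbounded energy sink.

**Defect bookkeeping.** The phase 2η = atan2(q_m, q₀) is single-valued,
so its principal-value circulation around every elementary grid cell is
an exact multiple of 2π: each plaquette carries an exact half-integer
charge. The principal frame contributes index +1 at each pole, so the
two pole caps carry 1 ± (first/last regular ring winding). By
telescoping, reported total charge is exactly 2 on any closed texture —
the detector cannot miscount global topology, only attribute positions.
Nonzero plaquettes are clustered (8-connected, φ-periodic) into defect
records; the order-parameter threshold λ < 0.2 λ₀ supports positions and
confidence flags.

## Minimization protocol

Alternating relaxation, as many iterations as needed for the total
energy to stall (relative change < 10⁻³ over 3 consecutive iterations):

1. **Texture, shape frozen**: Metropolis single-site Monte Carlo.
   Proposals mix Gaussian steps in the (q₀, q_m) disc (σ = 0.08, moves
   capped at λ = ½) with pure director rotations (σ = 0.32 rad), the
   latter moving along the soft direction of the stiff Landau potential —
   without them, director relaxation and defect-pair annihilation freeze.
   The starting temperature is calibrated from the mean |ΔE| of probe
   moves (initial acceptance ≈ ½), cooled geometrically, with the final
   20% of sweeps greedy (T = 0). Later alternation stages re-anneal at
   0.3× the calibrated temperature, with sweep counts scaled to the
   number of grid sites, so defects can rearrange as the shape evolves;
   the run ends with a full re-anneal and quench on the final shape.
   Before and after each relaxation an exact collective move is applied:
   a global rotation of (q₀, q_m) leaves the condensation and intrinsic
   elastic energies invariant (gauge equivariance of the covariant
   derivative), so the rotation angle minimizing the deviatoric energy —
   a closed quadratic form in (cos χ, sin χ) — is found by line search
   and applied as pure descent. This move nucleates the uniformly tilted
   (spiral) state on tubes, which single-site proposals cannot reach
   against the gradient barrier; with it, the measured tube tilt follows
   arcsin √(C_p r_t) to a degree.
2. **Shape, texture frozen**: derivative-free (Powell) minimization over
   the Fourier amplitudes in blocks of 10 modes, low frequencies first,
   repeated up to three times until a pass stops improving. Volume and
   closure enter as quadratic penalties whose weights escalate ×10 (up to
   three times) until |v − v_target| ≤ 10⁻³ and |ρ(L_s)| ≤ 10⁻³; area is
   exact by rescaling; ρ ≥ 0 by a stiff quadratic barrier; an optional
   minimal pole-to-pole height h_min (quadratic penalty) models an
   internal stretching rod.

Candidate equilibria are produced from several seed branches (oblate,
prolate/spherocylinder, stomatocyte, dumbbell fixtures), each paired
with the defect arrangement compatible with its geometry: four +½ cores
near the equator for the oblate, a uniform meridian field (+1 at each
pole) for tubular branches, the 2×(+½) outer + invaginated +1 split for
the stomatocyte. Seeding shape and texture together keeps each branch
in its own basin — a meridian start on an oblate, for example, drags the
shape toward the stomatocyte basin before the texture can split its pole
defects. Each branch runs on a grid whose arc-length step matches its
seed length (n_s ∝ L_s, target step 0.07 R), so defect cores are equally
resolved across branches; without this, long tubular branches get their
cores ~2.7× cheaper than compact oblates, a bias of several k_i — the
same size as the physical energy gaps between branches. The equilibrium
is the branch of lowest total energy; candidates within 10⁻³|F| are
reported as coexisting — the signature of a discontinuous morphological
transition.

## Synthetic fixtures

Seed profiles are built from closed-form target curves (spheroids,
spherocylinders with the exact v(r) relation, a three-arc invaginated
family whose inner-cup radius is fixed by closure), least-squares
projected onto the Fourier basis and fine-adjusted on the two lowest
modes to meet v and closure to 10⁻³. Textures with prescribed defects
map the grid to the stereographic plane and superpose planar phase
fields — any half-integer charge set summing to 2 can be realized, with
Gaussian-profile λ dips (core radius 2 cells) marking the cores. These
fixtures emulate idealized initial conditions and reference states; they
do not emulate thermal shape fluctuations, finite molecular density, or
asymmetric (non-axisymmetric) states, so passing tests constrain the
solver, not those physical effects.

## Problem sizes and limitations

The reference protocol is a 101×101 grid with N = 80 modes. Shipped
tests and the acceptance script run a reduced preset (41×41, N = 16,
~10³ annealing sweeps) so that a full branch comparison is minutes, not
hours, on one CPU. Consequences, measured on the desk-scale preset:

- Energy differences between branches of very different profile length
  L_s carry a discretization bias (the s step is L_s/(n_s−1): ~2.7× finer
  for a v = 0.4 oblate than for the prolate tube of the same area), and
  residual Monte Carlo noise of order 0.1–1 k_i; branch orderings with
  gaps of that size are not resolved at this preset.
- Defect cores (size ξ = R/10) are 1–3 cells wide; core energies are
  under-resolved, which penalizes configurations with higher-charge or
  more numerous cores in a resolution-dependent way.
- Annealing is finite: a relaxed texture may retain one or two
  defect–antidefect pairs above the ideal configuration. Total charge is
  still exactly 2 (by construction of the detector), and the
  characteristic configurations (four +½ on oblates, +1 per pole on
  prolates, the stomatocyte 2×(+½) + 1 split) emerge reliably.
- The optimizer is local: each branch relaxes within its basin, which is
  exactly what the multi-seed branch-comparison protocol requires, but
  no global-optimality claim is made.
- Two phenomena sit on the other side of the gradient-convention choice:
  φ-shapes (two tubular protrusions once C_p exceeds the tube-fit
  curvature 1/r_t) and deep necklace pearling after an isotropic quench.
  A protrusion of radius 1/C_p costs (k_i/2) C_p² Tr Q² in extrinsic
  energy, which exceeds its deviatoric gain for k_e = k_i/5 at every C_p,
  so with extrinsic gradients the shell keeps a plain tube (verified from
  both tube and two-neck seeds; the states tie within 0.01 k_i). In the
  isotropic phase the orientation-averaged molecular energy carries a
  neck penalty D²/2, and an explicit two-bead necklace at v = 0.70
  evaluates above the gently undulated cylinder the optimizer reaches.
  Both effects are properties of the energy as implemented, not of the
  optimizer.
- Branch stability windows along C_p are compressed toward the oblate at
  desk scale: at v = 0.40 the oblate is the global minimum through
  C_p ≈ 2.5 and the oblate→prolate exchange sits near C_p ≈ 3 (the
  deviatoric gain on the oblate grows ∝ C_p² against a ~5 k_i baseline
  gap), with no resolvable stomatocyte window between them. Locating
  the exchanges to a 0.1-step resolution in C_p would
  require inter-branch energy differences controlled to ~1 k_i, beyond
  this preset and the surviving convention ambiguities (β, the extrinsic
  weight, the exact annealing protocol). Within each branch, the defect
  configurations, shape classes, tilt law, stretching response and
  quench phenomenology are reproduced.
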