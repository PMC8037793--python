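# Methods

This package re-implements, as a tested analysis pipeline, the chain of
reasoning that links first-coil packing of an intracranial aneurysm to its
late-recanalization risk: geometric packing formulas, a porous-media model
of the coiled dome's hemodynamics, the grid-convergence verification
procedure used to qualify CFD meshes, and the cohort-level statistics that
turn the first-coil volume packing density (1st VPD) into a clinical
predictor.

## Packing morphometry

The aneurysm sac volume is estimated from caliper measurements with a
shape-specific closed form: a sphere `πd³/6` on the largest of the three
dome diameters (H, S, D), an ellipsoid `πd²h/6` with `d = max(S, D)` and
`h = H`, or, for bilobed sacs, the sum of two ellipsoid terms over
explicitly measured lobes.  Each coil is a cylinder of wire,
`πd²L/4`, with the wire diameter converted from inches at exactly
25.4 mm/inch.  Packing density (PD) is total coil volume over sac volume
(as a percent); 1st VPD is the same ratio for the first coil alone.
`first_coil_length_for_vpd` inverts these formulas to give the
intraoperative quantity of interest: the first-coil length that reaches a
target 1st VPD in a measured sac.

Design choices (the measurement protocol leaves them open): "largest
diameter" is `max(H, S, D)`; the ellipsoid diameter is `max(S, D)`;
bilobed lobes must be measured per-lobe rather than approximated.

## Blood rheology

Blood is incompressible (ρ = 1050 kg/m³) and shear-thinning, with a
plateau-capped power-law viscosity:

    η = 0.55471 Pa·s                 γ̇ ≤ 0.001 s⁻¹
    η = η₀ · γ̇^(n−1)                 0.001 ≤ γ̇ < 327 s⁻¹
    η = 0.00345 Pa·s                 γ̇ ≥ 327 s⁻¹

with η₀ = 0.035 (units kg·m⁻¹·s⁻¹·⁴ for n = 0.6).  The plateau values are
exactly the power-law branch evaluated at the breakpoints, so the model is
continuous; the constructor validates this.  The scalar shear rate is
`γ̇ = √(2 D:D)` with `D` the strain-rate tensor.

## Porous coiled dome

The coil mass is not resolved; the dome is a homogeneous porous medium.
A coil packing density CPD (%) sets the porosity κ = 1 − CPD/100, and the
Ergun packed-bed correlation gives the resistance coefficients

    α = 1.75 ρ (1−κ) / (κ³ Dp)          [inertial, kg/m⁴]
    β = 150 μ (1−κ)² / (κ³ Dp²)         [viscous, kg/(m³·s)]

with Dp = 2.54×10⁻⁴ m (0.010″ wire) and μ fixed at the high-shear plateau
0.00345 Pa·s (a single critical value: at the wire scale the local shear
rate is not meaningful in a homogenized model).  The momentum sink is the
standard isotropic Darcy–Forchheimer form on the superficial velocity,
`F = −(β + α|U|) U`, applied only in dome cells.  At CPD = 0 both
coefficients vanish identically, so an uncoiled dome is bit-for-bit an
ordinary fluid region.

## Flow solver

The patient-specific surface behind the published absolute hemodynamic
values is not available, so the solver runs on an idealized 2D geometry: a
straight parent-vessel channel (diameter 3 mm) with a circular side-wall
dome (radius 2.5 mm) attached through a neck opening (3 mm).  Results on
this geometry are interpreted as *trends over packing density*, never as
value-level reproductions of the patient-specific study; the published
sweep table is carried as a reference fixture and compared only through
curve-shape descriptors.

Discretization: staggered (MAC) finite volumes on a uniform Cartesian
grid, ≥ 16 cells across the parent diameter.  Chorin-type projection in
incremental (pressure-correction) form — the increment form matters
because with a stiff implicit sink the non-incremental variant
under-reports the converged pressure by the factor (1 + Δt·K/ρ).
Momentum uses explicit first-order upwind advection, backward-Euler
diffusion with the local viscosity (the simplified scalar-Laplacian
stress, matching the momentum equation the porous model extends), and the
porous sink implicitly (unconditionally stable in β).  Walls are rigid
no-slip; tangential components use a quadratic wall ghost fitted through
the wall zero and two interior points, which is exact for parabolic
profiles — the mirror ghost's O(1/n) wall-shear error (≈ 4 % at 16 cells
per diameter) would otherwise dominate the WSS budget.  The inlet carries
a prescribed parabolic profile; the outlet is zero-gradient with an exact
global mass correction, and the pressure gauge is pinned near the outlet.

The viscosity nonlinearity is Picard-iterated with under-relaxation 0.7;
momentum matrices are refactorized every 20 steps with lagged
coefficients, so a pseudo-time step costs three sparse triangular solves.
Steady states march in pseudo-time until the largest per-step velocity
change, relative to the mean inflow, falls below the tolerance (default
10⁻⁶, capped at 10⁴ iterations); sweep drivers use 2×10⁻⁶, which the
trend observables are insensitive to.  Transient runs are time-accurate
with the advective CFL held below 0.5 at peak inflow.

The pulsatile inflow waveform is a two-harmonic unit-mean pulse
(`1 + a₁cos + a₂cos2·`, a₁ = 3a₂) peaking early in the cycle with
peak-to-mean 2.0, period 0.8 s, 5 cycles with the early cycles discarded
— a generic systolic shape, configurable throughout.  Test and example
transients shorten the period and cycle count; the properties checked
(OSI bounds, cycle periodicity, porous damping) are insensitive to the
Womersley number, and the full cardiac settings remain available via
`--cardiac`.

Verification anchors: plane Poiseuille flow (profile and wall shear within
2 % of the analytic solution at 16 cells per diameter, error falling with
refinement) and a fully porous channel plug (streamwise Δp/L within 5 % of
the one-dimensional `(β + α|U|)|U|` balance at CPD 30 %).

## Hemodynamic observables

Wall shear stress is the tangential viscous traction at each wall face,
from a one-sided second-order gradient (points at h/2 and 3h/2; exact for
quadratics) with viscosity evaluated at the wall shear rate.  TAWSS is the
cycle-averaged |τ| (trapezoid, ≥ 8 samples/cycle).  OSI is
`0.5(1 − |∫τ dt| / ∫|τ| dt)` — 0 for unidirectional, 0.5 for fully
reversing shear; faces with identically zero shear are defined as 0.
"Velocity at the neck" is the area-averaged speed on the dome/lumen
interface plane, including the in-plane sweeping component.  RFV/AV is
the fraction of dome volume with speed above 0.01 m/s (the residual-flow
threshold, configurable), a proxy for persistent intra-aneurysmal
circulation.  Dome pressure is the mean over wall-adjacent dome cells,
reported as gauge pressure relative to the outlet.

The sweep driver repeats the steady solve over a packing-density list
(default 0/5/…/30 %, warm-started case to case) and `characterize_curve`
reduces each observable to shape descriptors: the interval of steepest
slope, monotonicity of the tail (VPD ≥ 10 %), the locations of the global
extrema, and an asymptote flag.  The flag is raised when the last three
slope magnitudes shrink monotonically *or* have all dropped below 5 % of
the curve's peak slope — without the floor, an observable that has already
collapsed to numerical noise would never register as flat.

On the idealized geometry the sweep reproduces the qualitative structure
of the published patient-specific study: the dome-wall WSS falls steepest
over the first packing increment and flattens beyond ~10 % VPD, RFV/AV is
monotone non-increasing in the tail, and the artery-wall WSS is nearly
unaffected.  Absolute magnitudes differ strongly — a 2D side-wall cavity
fed by channel shear carries far less inflow than a basilar-tip sac under
direct impingement, so neck velocities and dome WSS sit one to two orders
of magnitude below the published values.  That gap is inherent to the
stand-in geometry and is why acceptance on this stage is property-based.

## Grid convergence (three-grid verification)

`porocoil.gci` implements the standard three-grid procedure: the apparent
order p solves the sign-aware fixed-point relation

    p = |ln|ε₃₂/ε₂₁| + q(p)| / ln r₂₁,   q(p) = ln((r₂₁ᵖ − s)/(r₃₂ᵖ − s))

with s = sign(ε₃₂/ε₂₁), damped 0.5 on oscillation (oscillatory
convergence, s = −1, occurs in the published fine-grid velocity probe and
is handled without special-casing).  Richardson extrapolation gives the
zero-spacing estimate, and the GCI uses the three-grid safety factor 1.25.
On the published probe triplets the procedure reproduces the printed
orders to ±0.01; the wall-WSS probe's printed order is not recoverable
from its rounded inputs (the printed values 3.82/3.83/3.74 give p ≈ 7.1)
and is excluded from verification.

## Synthetic cohort generator

The generator emulates the two-group structure of the 66-patient registry:
11 late-recanalization vs 55 no-recanalization patients (an 18/48 6-month
split is selectable), with per-variable normal marginals at the published
group means and SDs, truncated at zero for physical positivity.  The
truncation is *moment-corrected*: the underlying (loc, scale) are solved
so the truncated marginal reproduces the configured mean and SD.  A
zero-truncated normal cannot have SD ≥ mean, so for the aneurysm-volume
variable (published SD exceeds the mean — the registry distribution is
right-skewed, which a normal summary cannot encode) the raw parameters
are kept and the realized moments are shifted; every other default
variable is matched.

PD and 1st VPD are drawn jointly through a Gaussian copula with
correlation 0.6 — a plausible, explicitly synthetic choice (the registry's
actual correlation is unpublished) — and the physical ordering
1st VPD ≤ PD is enforced by rejection.  All draws derive from a single
seed; a cohort is byte-reproducible from its config.

What passing tests show, and what they do not: the generator reproduces
configured *marginal moments* and the group separation of the predictor;
it does not model the registry's skewness, outcome-scale correlations, or
any covariance beyond the PD–VPD pair, so pipeline results on synthetic
cohorts validate the statistical machinery, not the clinical effect
sizes.

## Cohort statistics

Welch t-tests (from raw samples or published mean/SD/n summaries) with
Satterthwaite degrees of freedom; Mann–Whitney U (exact for combined
n ≤ 20 without ties, tie-corrected normal approximation otherwise);
Bonferroni correction with m = 19 by default (the published comparison
count), configurable.  ROC analysis is empirical: trapezoidal AUC over
all score thresholds, Youden-optimal cut-off (ties resolve toward the
positive-class mean), and a seeded 2000-resample bootstrap percentile CI
(the published CI's method is unstated; bootstrap is distribution-free).
The predictor's direction (lower 1st VPD ⇒ recanalization) is
auto-detected and logged.  `binormal_auc` provides the closed-form
surrogate `Φ(|Δμ|/√(σ₁²+σ₂²))` for when only group summaries are
published; on the 1st VPD summaries it gives 0.94, matching the published
empirical AUC, and the package's empirical ROC agrees with it within 0.01
on large synthetic draws.  Logistic regression is maximum-likelihood
(IRLS) with Wald odds-ratio CIs and optional backward stepwise
elimination at p > 0.05; quasi-separation falls back to a gradient fit
and is flagged.

## Known limitations

- The flow stage is 2D; three-dimensional secondary flows, the real
  basilar-tip impingement, and patient-specific geometry are out of reach,
  so hemodynamic results are qualitative by construction.
- First-order upwind advection adds numerical diffusion; trends over
  packing density are robust to it but boundary-layer detail is not.
- Homogeneous porosity ignores coil-mass heterogeneity and compaction.
- Normal marginals cannot reproduce the skewed registry variables
  (notably aneurysm volume), and the synthetic PD–VPD correlation is a
  free parameter, not an estimate.
- The published cut-off 10.56 % and its sensitivity/specificity belong to
  the real registry; the package carries them as documentation values and
  recomputes cut-offs only on synthetic cohorts.
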