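# porocoil

Post-coiling aneurysm hemodynamics and late-recanalization prediction.

After endovascular coiling of a ruptured intracranial aneurysm, the sac
can re-open ("recanalize") months later. A candidate intraoperative
predictor of that risk is the **first-coil volume packing density
(1st VPD)** — the fraction of the sac volume filled by the *first* coil:

    PD      = 100 · Σ (π d² L / 4) / V_sac        [%]
    1st VPD = 100 ·   (π d² L₁ / 4) / V_sac       [%]

with the sac volume `V_sac` from a shape-specific closed form (sphere
`πd³/6`, ellipsoid `πd²h/6`, bilobed = sum of two ellipsoids). This
package implements, as a tested pipeline, the three strands that connect
that number to hemodynamics and outcome:

1. **Porous-media CFD of the coiled dome.** The coiled sac is a
   homogeneous porous domain on an idealized 2D parent-vessel + side-dome
   geometry. Blood is shear-thinning (plateau-capped power law,
   η₀ = 0.035, n = 0.6); the coil mass enters as a Darcy–Forchheimer sink
   `F = −(β + α|U|)U` with Ergun coefficients
   `α = 1.75ρ(1−κ)/(κ³Dp)`, `β = 150μ(1−κ)²/(κ³Dp²)`, κ = 1 − CPD/100.
   A staggered-grid projection solver sweeps packing densities 0–30 % and
   post-processes WSS, TAWSS, OSI, neck velocity, dome pressure and the
   residual-flow-volume fraction RFV/AV (dome volume with speed
   > 0.01 m/s).
2. **Grid-convergence verification.** The standard three-grid Richardson
   procedure (sign-aware apparent order, extrapolation, GCI) used to
   qualify CFD meshes, reproducing the published mesh-independence study
   from its printed probe values.
3. **Cohort statistics.** A synthetic-cohort generator with the published
   two-group structure (11 recanalization / 55 without), Welch and
   Mann–Whitney tests with Bonferroni correction, empirical ROC with
   Youden cut-off and bootstrap CI, the closed-form binormal AUC
   surrogate `Φ(|Δμ|/√(σ₁²+σ₂²))`, and logistic regression.

See `docs/methods.md` for the model details and limitations.

## Worked example

```bash
$ python analysis/01_packing_metrics.py
sac volume: 113.1 mm^3 (6-mm spherical dome)
packing density 19.91 %, 1st VPD 6.72 %
first 0.010" coil length for the 10.56 % cut-off: 235.7 mm
```

A 6-mm spherical sac coiled with a 150-mm first coil reaches only
1st VPD = 6.7 %, below the 10.56 % clinical cut-off; the inversion shows
the first 0.010″ coil would need to be ≈ 236 mm long to clear it.

```bash
$ python analysis/05_cohort_statistics.py --replicates 200
1st VPD ROC: AUC 0.914 (95% CI 0.839-0.974), Youden cut-off 13.57 % ...
logistic: OR 0.66 per % (0.52-0.83), p = 5.02e-04
200 replicate cohorts: median AUC 0.942, 99.0 % inside the published CI [0.86, 1.0]
```

Each percentage point of 1st VPD lowers the odds of recanalization
(OR < 1); across replicate synthetic cohorts the AUC concentrates at the
published 0.94.

The other drivers: `02_grid_convergence.py` (mesh-study verification),
`03_vpd_sweep.py` (steady packing-density sweep and curve shapes —
a few minutes), `04_pulsatile_metrics.py` (TAWSS/OSI on a pulsatile run).
All write their tables under `results/`. The same stages are available as
a CLI: `porocoil all --out OUT [--config FILE] [--seed N]`.

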