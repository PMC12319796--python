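# Methods

## The model

`capox` estimates the oxygen extraction fraction (OEF) of brain tissue from
two perfusion quantities measurable with bolus-tracking MRI: the mean
capillary transit time (MTT, s) and the capillary transit time heterogeneity
(CTH, s), the standard deviation of transit times.

**Single capillary.** Blood enters a capillary of normalized length
`x ∈ [0, 1]` with hemoglobin-bound oxygen concentration `C(0) = S_a·B`
(arterial saturation times oxygen-carrying capacity). Oxygen flux to tissue
is proportional to the plasma–tissue tension gradient:

    dC/dx = −k·τ·α_H·( P(C) − P_tO2 ),      P(C) = P50·( C/(B−C) )^(1/h)

where `P(C)` is the inverse Hill relation (the plasma tension in equilibrium
with the bound pool), `P_tO2` the tissue oxygen tension, `τ` the transit
time and `k` the transfer rate constant. The single-capillary extraction is
`Q(τ) = 1 − C(1)/C(0)`.

**Tissue.** Transit times follow a gamma density `h(τ; α, β)` with
`MTT = αβ`, `CTH = √α·β`; tissue OEF is `∫ h(τ) Q(τ) dτ`.

**Fast-exchange ceiling.** As `k → ∞` the outflow equilibrates with tissue
regardless of `h(τ)`, giving the closed-form ceiling
`OEF_max = 1 − S(P_tO2)/S_a`. This inverts analytically, which is how the
tissue tension is fixed (step 1 of calibration).

**PET arm.** For inhaled labeled oxygen the one-tissue-compartment
clearance is `K1(O2) = CBF·OEF`, so `OEF = K1(O2)/CBF` and
`CMRO2 = K1(O2)·[O2]_a`. Labeled-water CBF is biased low by incomplete
water extraction and is divided by `E = 0.84` before use. A minimal
two-parameter (K1, k2) compartment simulator/fitter with the standard
3-minute frame schedule (12×5 s, 6×10 s, 3×20 s) lets the PET arm run end
to end on synthetic time–activity curves; delay/dispersion correction,
blood volume terms and image processing are out of scope.

## Parameters and defaults

| parameter | default | units | role |
|---|---|---|---|
| `alpha_H` | 3.1e-5 | mL O2·mL⁻¹·mmHg⁻¹ | plasma oxygen solubility |
| `P50` | 26 | mmHg | half-saturation tension |
| `B` | 0.1943 | mL O2/mL | oxygen-carrying capacity |
| `h` | 2.8 | – | Hill coefficient |
| `S_a` | 0.95 | – | arterial saturation |
| `PtO2` | 21.8 | mmHg | tissue tension (calibrated) |
| `k` | 68 | 1/s | transfer rate constant (calibrated) |

The binding constants are standard literature values. They are pinned by two
independent operating points that the defaults must reproduce (checked at
import): a ceiling of 0.60 at `PtO2 = 21.8 mmHg` and 0.50 at `25 mmHg`. As
an additional consistency check, the model's original rodent
parameterization (`PtO2 = 25 mmHg`, `k = 118 1/s`, resting MTT 1.4 s / CTH
1.33 s) evaluates to OEF 0.30 with these constants, pinning the kinetic
scale `alpha_H/B` as well. Units are fixed to seconds and 1/s; config files
(YAML/JSON keys `alpha_H, P50_mmHg, B, hill_h, S_a, PtO2_mmHg, k_per_s`)
declare units in their key names.

The inflow pool is bound oxygen only; dissolved plasma oxygen (<1% of
content) enters the model only through the gradient term. Both ceiling
anchors confirm this reading.

## Numerics

- **ODE.** `Q` depends on `(k, τ)` only through `s = k·τ`, so the ODE is
  solved once per parameter set on `s ∈ [0, 1e5]` (implicit Runge–Kutta,
  rtol 1e-10, atol 1e-14, dense output); every later evaluation is an
  interpolant lookup. Beyond `s = 1e5` the state is clamped to the tissue
  equilibrium value (the residual is < 1e-8 in OEF). The state is guarded
  to `[C_eq, B(1−1e-12)]` inside the right-hand side; the exact solution
  never leaves this band. Agreement with an independent fixed-step RK4
  integration (10⁶ steps) is at the 1e-13 level, tested at 1e-6.
- **Quadrature.** Gauss–Legendre with 256 nodes on the gamma support
  truncated at the `1 − 1e-7` quantile. For shape `α < 1` (typical white
  matter: `α ≈ 0.69`) the substitution `u = (τ/β)^α` removes the integrable
  density singularity at `τ = 0`, leaving the smooth integrand
  `e^{−u^{1/α}}/Γ(α+1)`. For `α ≥ 1` the interval is two-sided
  (`[q(1e-7), q(1−1e-7)]`) so that sharply peaked densities stay resolved.
  Truncation changes OEF by < 1e-5; agreement with a 10⁵-step midpoint
  Riemann oracle is ≤ 1e-4 across the observed parameter box. `CTH = 0`
  short-circuits to `Q(MTT)`.
- **Calibration.** `PtO2` from the target ceiling in closed form (inverse
  Hill). `k` by bracketed Brent root-finding on `log10 k ∈ [−3, 6]`
  (calibrated values span an order of magnitude and OEF(k) saturates);
  the root is unique because OEF is strictly increasing in `k`. Converged
  fits satisfy `|OEF − target| ≤ 1e-6`. Subjects whose PET OEF is at or
  above the ceiling are excluded with a recorded reason. The cohort
  summary is the arithmetic mean of per-subject `k` (median reported as a
  robustness diagnostic — see limitations).
- **Maps.** Voxelwise evaluation loops exact scalar calls; an optional
  bilinear lookup grid over log-spaced (MTT, CTH) trades ≤ 1e-3 OEF error
  for constant-time queries. Out-of-mask or invalid voxels yield NaN and
  are counted in the log.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
68 subjects; per-ROI MTT/CTH lognormal with means and central-95% ranges
matched to published cohort summaries (NAWM: MTT 4.52 s [3.14; 6.42], CTH
5.45 s [3.82; 8.31]; gray matter: 3.40 s [2.35; 4.60], 4.08 s
[2.85; 6.07]), truncated to those ranges; within-subject MTT–CTH Gaussian
copula correlation 0.8 (CTH tracks MTT across tissue types); a hidden true
`k` per subject, lognormal with median 68 1/s truncated to [22, 175];
and PET-observed OEF generated by the forward model times multiplicative
Gaussian noise with CV 0.10 (the reported day-to-day reproducibility of
PET OEF), clipped inside (0, ceiling). Lognormal shapes were chosen for
positivity and the right skew typical of transit times; the true joint
distribution of (MTT, CTH, k) is unpublished, so all of these choices are
exposed in `CohortConfig`. The generator draws the tissue tension from its
own `target_max_oef` (default 0.6) so that generation and calibration
share one parameterization.

What synthetic cohorts do **not** emulate: within-ROI voxel heterogeneity
(each subject-ROI is a single (MTT, CTH) pair, whereas real ROI values
average voxelwise model outputs), PET/MRI registration and partial-volume
effects, and any physiological coupling between `k` and hemodynamics.
Passing cohort-level tests therefore demonstrates the estimator's internal
consistency, not field accuracy on images.

## Known limitations and observed gaps

- **Averaging (Jensen) gaps.** OEF is concave in MTT and in `k` over the
  physiological range, so the model evaluated at mean inputs exceeds the
  mean of per-subject (and, more strongly, per-voxel) model values. At the
  cohort-mean NAWM point with `k = 68` the model gives OEF 0.382 (gray
  matter 0.350); cohort-level averaging over the synthetic spread recovers
  only ~0.002 of the difference from published ROI-mean values (0.37/0.33),
  the remainder being attributable to within-ROI voxel averaging that
  cannot be reproduced from summary statistics. Consistently, calibrating
  `k` to OEF 0.37 at the NAWM mean inputs yields `k ≈ 61` and a gray-matter
  OEF of 0.338.
- **Convexity bias of the mean k.** `k(OEF)` is convex, so multiplicative
  observation noise inflates the arithmetic cohort-mean `k`: at CV 0.10 the
  inflation is ~6–8% (σ of log k ≈ 0.34 at the NAWM operating point), and
  the model OEF computed with the mean `k` overshoots the mean observed OEF
  by ~0.015. The cohort median of `k` is free of this bias and is reported
  alongside the mean.
- Constant `PtO2`, `S_a`, `B` and `P50` across subjects compress the
  model-OEF range relative to PET OEF (reproduced as a property on
  synthetic cohorts); no Bohr-effect or disease-specific adjustments.
- The 1TCM fitter is deliberately minimal (no weighting by frame counts,
  no delay/dispersion, no blood volume); it is intended for synthetic
  end-to-end exercises, not measured PET data.
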