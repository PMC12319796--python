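# capox

Biophysical estimation of the cerebral **oxygen extraction fraction (OEF)**
from perfusion-MRI transit-time statistics, with PET-anchored calibration.

Bolus-tracking (DSC) MRI yields two summary statistics of capillary blood
flow in every voxel: the mean transit time (**MTT**) and the capillary
transit time heterogeneity (**CTH**, the standard deviation of transit
times). Because oxygen unloading during a capillary pass depends on how
long blood spends in the exchange bed, these two numbers constrain the
fraction of arterial oxygen the tissue can extract. `capox` implements the
forward model

- single capillary: `dC/dx = −kτ·α_H·(P50·(C/(B−C))^{1/h} − P_tO2)` on
  `x ∈ [0,1]`, `C(0) = S_a·B`, giving the extraction `Q(τ) = 1 − C(1)/C(0)`
  of a capillary with transit time `τ` (Hill-equation hemoglobin binding,
  constant tissue oxygen tension `P_tO2`, transfer rate constant `k`);
- tissue: `OEF = ∫₀^∞ h(τ)·Q(τ) dτ` with a gamma transit-time density
  `h(τ; α, β)` parameterized by `MTT = αβ`, `CTH = √α·β`;

and the two-step calibration of its free parameters against
[¹⁵O]-PET: `P_tO2` from the fast-exchange ceiling
`OEF_max = 1 − S(P_tO2)/S_a` (the `k → ∞` limit, independent of transit
times), and `k` per subject by root-finding so the model matches that
subject's PET OEF (`OEF_PET = K1(O₂)/CBF`) in normal-appearing white
matter. Agreement between the model and PET OEF series is summarized with
Pearson correlation and Bland–Altman statistics. A seeded synthetic-cohort
generator and a minimal one-tissue-compartment PET simulator/fitter make
the whole pipeline runnable with no input data.

Intended users: quantitative-neuroimaging researchers working with DSC-MRI
perfusion maps who want physiologically calibrated OEF estimates, and
anyone studying transit-time-heterogeneity models of oxygen transport.

## Worked example

```python
from capox import (DEFAULT_CONSTANTS, HemodynamicSummary, CohortConfig,
                   limit_extraction, calibrate_pto2, calibrate_k, oef,
                   generate_cohort, run_pipeline)

c = DEFAULT_CONSTANTS                       # PtO2 = 21.8 mmHg, k = 68 1/s

# Step 1: a 0.6 extraction ceiling fixes the tissue oxygen tension
calibrate_pto2(0.6, c)                      # -> 21.83 mmHg
limit_extraction(21.8, c)                   # -> 0.6009

# Forward model at cohort-mean hemodynamics
oef(HemodynamicSummary(mtt=4.52, cth=5.45), c)   # NAWM        -> 0.3816
oef(HemodynamicSummary(mtt=3.40, cth=4.08), c)   # gray matter -> 0.3501

# Step 2: k that reproduces a PET OEF of 0.37 at the NAWM operating point
calibrate_k(0.37, HemodynamicSummary(4.52, 5.45), c)   # -> 61.3 1/s

# End to end on a synthetic 68-subject cohort (10% PET observation noise)
cohort = generate_cohort(CohortConfig(n_subjects=68, seed=1), constants=c)
res = run_pipeline(cohort, c)
res.calibration.k_mean, res.calibration.k_median   # -> 71.7, 56.9 1/s
res.agreement["NAWM"]
# AgreementReport(r=0.551, p_value=1e-06, bias=0.022,
#                 loa_low=-0.095, loa_high=0.139, n=68)
```

Reading the output: the calibrated tissue tension of ~21.8 mmHg caps OEF at
0.60; at that tension the model maps the white-matter transit-time point
(MTT 4.52 s, CTH 5.45 s) to OEF ≈ 0.38 and gray matter to ≈ 0.35 — gray
matter extracts less per pass because its transits are faster. Calibrating
`k` per subject and re-estimating with the single cohort-mean `k`
reproduces PET OEF with a positive correlation, a near-zero bias, and a
narrower model-OEF range than the PET range (the model holds saturation,
carrying capacity and tissue tension fixed across subjects). The
cohort-mean `k` sits above the median because `k(OEF)` is convex, so
noisy high-OEF observations map to disproportionately large rate
constants.

The same steps are available from a shell:

```sh
capox simulate --n 68 --seed 1 --out cohort.csv
capox calibrate --roi-table cohort.csv --target-max-oef 0.6 --out calibration.json
capox run --roi-table cohort.csv --out-dir report/
capox estimate --mtt-nifti mtt.nii --cth-nifti cth.nii --out oef.nii   # map mode
```

Model constants can be overridden with `--config constants.yaml` (keys
`alpha_H, P50_mmHg, B, hill_h, S_a, PtO2_mmHg, k_per_s`).

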