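# adcascade

Data-driven causal modelling of the Alzheimer's disease biomarker cascade:
sparse discovery of a polynomial ODE linking amyloid, tau, neurodegeneration
and cognition, joint calibration of population dynamics with per-subject
disease-progression-score (DPS) time warps, variance-based (Sobol)
sensitivity analysis of the calibrated weights, and sensitivity-guided
personalized models scored by leave-last-visit-out prediction accuracy.

The package is aimed at researchers modelling longitudinal AD biomarker
panels (CSF amyloid-beta 1-42, CSF total tau, hippocampal volume, ADAS-13)
who want a mechanistic, testable alternative to independent per-biomarker
curve fitting.  A synthetic ADNI-like cohort generator with full ground
truth makes every pipeline stage runnable and testable without access to
clinical data.

## The model

Each subject's age t maps onto a common disease-time axis through an affine
warp s_i(t) = α_i t + β_i.  On that axis the normalized biomarkers
x = (A_β, τ, N, C) follow a chained ("cascade") system of ODEs, each
equation quadratic in its own and its upstream variable:

    dA/ds = w_A1 A + w_A2 A²
    dτ/ds = w_T1 τ + w_T2 τ² + w_T3 A + w_T4 A² + w_T5 Aτ
    dN/ds = w_N1 N + w_N2 N² + w_N3 τ + w_N4 τ² + w_N5 τN
    dC/ds = w_C1 C + w_C2 C² + w_C3 N + w_C4 N² + w_C5 NC

with A(−10) = y0 > 0 small and τ = N = C = 0 at s = −10 (constant terms
w_·0 exist in the general model; they calibrate to 0).  The structure is
learned from data by Lasso regression of sigmoid-smoothed trajectory
derivatives on a polynomial library; the weights and warps are estimated by
alternating nonlinear least squares (Levenberg–Marquardt-type steps) with a
final joint refinement; first-, second- and total-order Sobol indices of
C(s) over 90–110% parameter boxes identify the weights worth personalizing.
Two calibrated weight columns ship as fixtures (`full_cohort`, `lmci_ad`).

See `docs/methods.md` for assumptions, parameter meanings, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
from adcascade import GeneratorConfig, generate_cohort, load_fixture_params
from adcascade.sensitivity import make_ranges, sobol_indices, select_personalized

params = load_fixture_params("lmci_ad")
res = sobol_indices(make_ranges(params), output=("C", 0.0), N=2**13, seed=1)
top = np.argsort(-res.S1)[:3]
for i in top:
    print(f"{res.names[i]:6s} S1={res.S1[i]:.3f} +- {res.S1_se[i]:.3f}")
print("personalized set:", select_personalized(res, tol=0.01))
```

prints

    w_A1   S1=0.917 +- 0.013
    w_N1   S1=0.024 +- 0.003
    w_T4   S1=0.012 +- 0.002
    personalized set: ['w_A1', 'w_N1', 'w_T4', 'w_N3', 'w_C3']

meaning: at disease onset (s = 0) about 92% of the variance of the
cognitive outcome under ±10% parameter uncertainty is attributable to the
linear amyloid self-term alone, with small contributions from the
neurodegeneration and tau terms; parameters whose first-order index
exceeds 0.01 form the subset re-estimated per subject in personalization.

The full pipeline (simulate → calibrate → sigmoid fits → structure
discovery → sensitivity → personalize) runs from the shell:

    adcascade run --seed 3 --outdir demo_run

writing per-stage artifacts (cohort CSV, calibrated parameters JSON, DPS
table, discovery report, Sobol index tables, per-subject prediction
accuracies) plus a reproducibility manifest.

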