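# iadtmodels

Comparative ODE modelling and Bayesian model selection for serum PSA
(prostate-specific antigen) dynamics under **intermittent androgen-deprivation
therapy (IADT)**.

Prostate tumours depend on androgens; deprivation therapy suppresses the
androgen-dependent cell population and PSA falls, but resistance emerges under
continuous treatment. Intermittent schedules cycle therapy on and off, and the
resulting saw-tooth PSA series carry information about the underlying
resistance mechanism. Over the years many compartmental ODE models of this
process have been proposed — androgen-driven population models, cell-quota
(Droop) models, Lotka–Volterra competition, stem-cell enrichment,
pharmacodynamic dormancy models. This package puts **13 of these models behind
one uniform interface** and provides the machinery to compare them as
scientific hypotheses on per-patient PSA data:

- `schedule` — patient-specific treatment control `u(t) = Σ_i 1_{τ_i}(t)`
  from recorded on/off cycles τ_i,
- `model_zoo` — the 13 models (`I08A`, `I08B`, `E10`, `H10`, `P12A`, `P12B`,
  `M14`, `B16A`, `B16B`, `E16`, `Z17`, `P19`, `B20`): states, parameters with
  bounds and biological inequality constraints, RHS `f(x, p, u)`, PSA
  observation map,
- `simulator` — piecewise integration across treatment switches (exact
  segment propagation for the linear model), plus the closed-form
  serum-androgen channel for a single on→off step,
- `stability` — analytic + multi-start numeric equilibria per phase,
  complex-step Jacobian spectra, hyperbolicity classification,
- `sensitivity` — forward (direct differential method) sensitivities
  `S_ij(t) = ∂x_i/∂p_j` via the variational ODE,
- `inference` — Gaussian likelihood with per-point assay errors, seeded
  differential-evolution MAP search, Laplace evidence and an in-package
  nested sampler with quantified `logZ` error, uniform/Jeffreys/empirical
  priors,
- `comparison` — Bayes factors `β_ij = Z_i/Z_j`, posterior model
  probabilities `Pr(M_i|D) = O_i / Σ_j O_j`, cohort preference fractions,
  PSA-drop statistics and Ω/¬Ω (relapsing vs responding) phase-space
  densities,
- `cohort_io` / `synthetic_data` — cohort CSV I/O with detection-floor and
  error preprocessing and exclusion filters, and a ground-truth-carrying
  synthetic-trial generator for closed-loop validation.

## Worked example

Generate a small synthetic trial from the linear three-compartment model
(`H10`), fit three candidate models to every patient, and rank them by
Laplace evidence:

```python
import numpy as np
from iadtmodels import GeneratorConfig, generate_cohort, cohort_ranking
from iadtmodels.workflows import compare_models_on_cohort

cohort = generate_cohort(GeneratorConfig(n_patients=20, model_id="H10",
                                         noise_sd=0.1, seed=42))
tables = compare_models_on_cohort(cohort, model_ids=("I08A", "H10", "B20"),
                                  seed=7)
print(cohort_ranking(tables))
```

```
  model_id  preference_fraction  mean_normalized_log_evidence
0     I08A                  0.0                 -1.145697e+05
1      H10                  1.0                  0.000000e+00
2      B20                  0.0                 -2.070382e+06
```

The generative model wins on every patient: its preference fraction (the
share of patients for which it attains the highest posterior probability) is
1.0, and the mean log-evidence of the competing models, normalized to the
per-patient winner, is thousands of nats lower — the evidence strongly
penalizes mechanisms that cannot reproduce the observed cycle-to-cycle
kinetics.

Stability analysis of a single model from the shell:

```bash
iadt stability --model Z17 --phase off
```

reports, for the three-species competition model off-treatment, the
producer-only rest point `(0, K_P, 0, K_P/δ)` (a saddle) and the interior
coexistence point with its four eigenvalues (stable for the reference
parameters) — the "basin of attraction" question that decides whether a
patient's dynamics can be parked at a bounded tumour burden without
treatment.

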