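# Methods

This note records the scientific and numerical choices behind the package:
what each component computes, under which assumptions, and what the
synthetic-data experiments do and do not demonstrate.

## Treatment forcing

Intermittent androgen-deprivation therapy is represented by the binary
control `u(t) = Σ_i 1_{τ_i}(t)` over recorded on-treatment cycles
`τ_i = [start_i, end_i)` inside an observation window `[t_min, t_max]`
(days). The half-open convention makes abutting on/off blocks tile time
without double counting; the trial data themselves do not fix whether a
sample drawn exactly on a switch day is on- or off-treatment, so a draw on a
switch day is attributed to the phase beginning that day. Clinical switch
dates are usually not in the data model; when a schedule is derived from
per-sample on/off flags, boundaries are placed at midpoints between adjacent
samples with differing flags.

## The model catalogue

Thirteen ODE models share one interface: state vector (compartment
concentrations, quotas, androgen, PSA; µg/L-equivalent), parameter vector
with per-parameter bounds and inequality constraints, RHS `f(x, p, u)`, and
a PSA observation map. Default bounds are set by unit class (rates ≤ 10/day,
concentrations ≤ 10³ µg/L, fractions ≤ 1, order-one dimensionless ≤ 10),
stored in a single editable YAML (`default_bounds.yaml`); they are two
orders of magnitude above physiologic scales, i.e. deliberately
uninformative. The linear three-compartment model's per-compartment net
growth rates are signed (bounds ±10/day): its on-treatment diagonal rates
must be negative for PSA to fall, which is the defining clinical feature of
a response.

Model-specific decisions:

- **I08A/I08B.** The constrained variant pins the androgen-independent
  population's net growth to zero (its hormonal death and growth modulation
  cancel); the free variant keeps both rates and is structurally
  non-identifiable through their ratio — the fitting layer therefore exposes
  free-parameter *subsets*, and the PSA weights `w_D, w_I` default to 1 and
  are ordinarily held fixed.
- **E10.** The testosterone influx gated by `(1 − u)` is implemented as a
  single nonnegative constant `υ_S` (µg/L/day): a constant influx preserves
  the on/off modulation while keeping the parameter identifiable from
  PSA-grade data. No state of this receptor-kinetics model is PSA itself;
  the serum testosterone `n_T` acts as the default PSA proxy (configurable).
  Its printed critical points do not annihilate the full vector field, so
  equilibria for E10 are searched numerically only.
- **P12 family.** The quota relaxation term uses each equation's own quota
  `γ_max(q_imin − q_i)`; this is what makes the shared-quota model (`P12A`)
  an exact restriction of the per-population-quota model (`P12B`, with
  `q_D ≡ q_I` and equal minima) and reproduces the quota equilibria
  `q_eq^on = γ_max q_min/(γ_max + δ_q)` used by the stability module.
- **E16.** The non-smooth primitives (min, ramp, the piecewise PSA growth
  switching at `c_tPSA`, the manual bounding hats `(l_max − f)⁺/l_max`) are
  implemented exactly as written; integration uses a stiff solver rather
  than smoothing, and the model is excluded from complex-step
  differentiation (central differences instead). One state drifts at
  constant rate, so the system has no equilibria.
- **Z17.** All competition-matrix constraints are enforced
  (`α_ii = 1`, `α_31 > α_21`, `α_32 > α_12`, `α_13 > α_23`, `α_13 > α_21`,
  `α_32 > α_31`, off-diagonals in ]0,1[). The carrying capacity of the
  dependent population, `n_P(β − u + 1)`, is singular as `n_P → 0`; the RHS
  raises a named singular-state error there rather than returning garbage.
- **B20.** The self-renewal ratio `n_S/(n_S + n_D)` is removably singular at
  total extinction; the guard raises rather than clips.

Ratio terms of the multi-population quota models (`B16B`, `P19`) are
singular when every population vanishes. Their catalogued rest points carry
a *directional* flag: residuals and Jacobians are evaluated along the
nonnegative orthant at an infinitesimal population in the direction noted on
the point (the independent population), which reproduces the analytic quota
equilibria.

## Simulation

The control makes every RHS discontinuous in time, so integration restarts
at each switch with state carried over continuously; within a segment the
RHS is smooth and the solver runs at full order. Defaults: LSODA for the
stiff-leaning models (`E16`, `M14`, `P12B`), RK45 otherwise, rtol 1e-8 /
atol 1e-10. For the linear model the solution is propagated exactly per
segment through the eigendecomposition of the segment matrix (with a
stepwise matrix-exponential fallback if the eigenvector basis is ill
conditioned); this path has no truncation error and is roughly two orders of
magnitude faster than a tolerance-controlled solver, which is what makes
cohort-scale fitting experiments affordable.

States are not clipped at zero. Excursions below −1e-8 raise a warning and
below 1e-3 an error, so model misbehavior is surfaced, not masked; fitting
code may loosen the error threshold explicitly (solver option
`negative_tol`) because loose-tolerance solvers overshoot decaying tails by
amounts on the scale of the absolute tolerance. A per-call RHS-evaluation
budget (`max_rhs_calls`) turns pathological parameter corners — where a
stiff solver would grind indefinitely — into ordinary simulation failures
that the likelihood treats as zero support.

The serum-androgen channel under a single on→off step has the closed form

    c_A(t) = c_A0 exp(−δ_A(t+1)) [exp(δ_A) θ(t) (exp(δ_A t) − 1) + 1],

with treatment released at t = 0 and the homeostatic value attained at
t = −1 on the decaying branch. This is the exact solution of
`dc_A/dt = δ_A(c_A0 − c_A) − δ_A c_A0 u`; it is validated in the test suite
against direct integration and serves as the primary simulator oracle, and
its symbolic δ_A-derivative as the sensitivity oracle.

## Stability

With the control frozen per phase, equilibria are the union of a hard-coded
analytic catalogue (per model and phase) and multi-start numeric roots (64
scrambled-Sobol starts in log-state space, nonnegative-orthant filter,
1e-10 residual contract, 1e-6 deduplication). Equilibrium manifolds (the
line of the androgen-driven model, the plane of the stem-cell model) are
represented by one sampled representative point with the free coordinate
recorded. Jacobians are complex-step derivatives where the RHS is analytic
in the states (exact to machine precision) and central differences for the
non-smooth model; "generalized eigenvalues" of explicit ODE systems reduce
to ordinary Jacobian eigenvalues, and spectra are reported sorted by
descending real part. Classification uses a tolerance of 1e-9/day on real
parts: any |Re λ| inside it is "nonhyperbolic" (center-manifold reduction
for those cases is out of scope), otherwise stable/unstable/saddle by sign
pattern.

## Sensitivities

Forward sensitivities solve the variational system
`dS/dt = (∂f/∂x) S + ∂f/∂p` jointly with the states, piecewise across
switches. S is carried continuously through switches — schedules are data,
not parameters, so no jump terms arise; sensitivity to the switch *times*
themselves is deliberately out of scope. Initial-condition sensitivities
start from canonical basis vectors, dynamical-parameter sensitivities from
zero, and the PSA sensitivity follows by the chain rule through the
observation map (including the direct parameter dependence of weighted
observation maps).

## Likelihood, priors and evidence

The observation model is independent Gaussian with the per-point assigned
PSA errors as standard deviations; the 1-day time error of the data is not
propagated (at biweekly sampling cadence the PSA error dominates). The
detection floor (0.1 µg/L) and error assignment (uniform `e_max = 0.1 µg/L`
or the peak-referenced declining-relevance weights, floored at 0.01 µg/L
because they combine magnitudes on different scales) live in the
preprocessing layer.

Priors are proper and truncated: per-parameter uniform (optionally flat in
log10), tabulated Jeffreys densities ∝ √det F per parameter around a
reference point, or empirical densities smoothed from cohort MAP values —
the empirical mode refuses to build from fewer than ceil(√N_pat) fits, the
Poisson-noise floor on the sample size.

MAP search runs differential evolution in the prior's quantile coordinates
(so log-space priors are explored logarithmically), scaling factor 0.9,
crossover probability 0.1, population 10×dim by default, followed by a
bounded local polish; all seeds are explicit and recorded. The Fisher
information at the MAP is the Gauss–Newton curvature of the Gaussian
likelihood; parameters whose Fisher diagonal falls below 1e-12 are flagged
as practically non-identifiable.

Two evidence estimators are provided. The default Laplace form is

    log Z ≈ log Pr(p̂) + log L(p̂) + (k/2) log 2π − ½ log det A,

with A the curvature of −log posterior at the MAP; a `paper_variant` switch
instead *multiplies* by √det F (log Z ≈ log Pr(p̂) + log L(p̂) + ½ log det F),
so the difference between the two conventions is auditable rather than
silently resolved. The nested sampler is a classic implementation:
likelihood-sorted live points, log-trapezoid prior-mass accumulation,
likelihood-constrained random-walk replacement with adaptive step, dlogz
termination, error √(H/nlive). It samples in the prior's unit-cube
coordinates and surfaces termination diagnostics (plateaus, iteration caps)
instead of swallowing them. On the conjugate-Gaussian toy both estimators
match the analytic log Z (Laplace to 1e-6; nested within its quoted error);
on a well-identified two-parameter ODE fit with a linear-space flat prior
they agree to ~1 nat — with a log-space prior the Laplace estimate, which
assumes a locally flat prior density, is biased by the prior curvature, and
that bias is left visible by design.

## Model comparison

Posterior model probabilities are computed in log space from evidences and
(default equal) model priors; Bayes factors are exposed as a by-product, and
for two models the normalization reduces to the pairwise odds formula.
Cohort ranking credits each patient's winning model with one unit, split
equally on ties (ties are essentially measure-zero for real evidence but the
rule is explicit), and also reports per-model mean log-evidence normalized
to the per-patient winner. Phase-space occupation densities per Ω/¬Ω label
pool re-simulated MAP trajectories on a uniform time grid with uniform
weights and summarize them as Freedman–Diaconis histograms with superlevel
contour masses {0.1, 0.68, 0.95}; the estimator and pooling are package
choices, stated here because no standard exists for them.

## Cohort preprocessing and exclusion

The exclusion filter removes (a) patients whose PSA fluctuation statistic is
below 2.0 µg/L and (b) patients with fewer than ceil(√N) samples, N the
pre-filter cohort size (frozen into the output provenance, which makes the
filter idempotent). The default fluctuation statistic is the series range
(max − min): a patient whose entire excursion stays inside the natural
serum-PSA variability band carries no pathological signal. A literal
max-|ΔPSA|/Δt per-day statistic is available as a config option; at
realistic sampling cadence it would exclude nearly everyone and is therefore
not the default. Every exclusion is logged with its reason.

## Synthetic cohorts

The generator emulates the design of an intermittent-therapy trial: 2–5
on/off cycles per patient, on-phase durations normal around 35.5 weeks
(sd 2.5, truncated at ±3 sd), off-phase durations uniform on [25.6, 53.7]
weeks, visits every ~14 days with ±3-day jitter, additive Gaussian assay
noise of sd 0.1 µg/L, and a 0.1 µg/L detection floor. Ground-truth
parameters, initial states and group labels ride along with the cohort.

The default generative model is the linear three-compartment model: fast,
positivity-preserving, and able to separate relapsing (Ω) from responding
(¬Ω) patients through its irreversibly androgen-independent channel. The
responsive kinetics are calibrated to the drawn schedule — PSA falls 5–7
e-folds over an on-phase and regrows a comparable amount off-treatment, the
clinical picture of a responding cycle — with small mutation couplings
(2e-5–1e-4/day) so they perturb rather than drive the cycle map; Ω patients
additionally carry an irreversible compartment compounding to a few tens of
µg/L over the study. Samplers for the stem-cell model (relapse = elevated
symmetric self-renewal, at percent-level rates) and the shared-quota model
are included for recovery and nesting experiments. The relapse labeling
rule is explicit and serializable: Ω iff some later on-treatment cycle
minimum exceeds 2× the first-cycle minimum (factor configurable).

What the generator does *not* emulate: assay censoring beyond the simple
floor, inter-visit variability structure, serum testosterone or other
covariates, dropout, or model misspecification — synthetic patients are
exact realizations of one catalogue model plus white noise. Passing
recovery tests therefore demonstrates the correctness and calibration of
the pipeline, not that any model describes real patients.

## Problem sizes of the validation experiments

The closed-loop experiments are sized for a single CPU: parameter recovery
uses single zero-noise patients with the identifiable free subset
(3 parameters, initial conditions fixed at truth); model-selection recovery
uses 5 replicate cohorts of 20 patients, screened with per-model 2–4
parameter free subsets and reduced differential-evolution budgets (the
winning margins are 10³–10⁶ nats, orders of magnitude beyond what fit
polish could overturn); the nested-model comparison uses 20 single-patient
replicates. Screening fits use LSODA at rtol 3e-4 — PSA accuracy ~1e-3
µg/L, two orders below the assay error — while oracle-grade comparisons use
rtol 1e-10.

## Known limitations

- The `E10` PSA proxy is a modelling choice, not canon; evidence values for
  E10 depend on it.
- Laplace evidence under strongly curved (log-space) priors omits the prior
  curvature term; use the nested sampler when that matters.
- The nested sampler is single-threaded and walk-based; heavily multimodal
  posteriors would need more walk steps than the default 25.
- Center-manifold analysis of the nonhyperbolic equilibria and sensitivity
  to treatment switch times are out of scope.
- Forecasting (extrapolating PSA beyond the fitted window) is deliberately
  not provided; the machinery ends at comparison and diagnosis.
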