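"""High-level fitting and model-comparison workflows.

These helpers wire the calibration machinery to whole cohorts: a default
free-parameter subset per model (the practically identifiable core of each
model at PSA-only data quality), heuristic initial states derived from the
first PSA draw, MAP fits with Laplace evidence, and per-patient posterior
tables ready for cohort ranking.

The default fit budgets are sized for cohort-scale screening (hundreds of
fits); single-patient studies can raise ``maxiter``/``popsize`` for
publication-quality MAP estimates.
"""

from __future__ import annotations

import numpy as np

from .cohort_io import Cohort, PatientRecord
from .comparison import ModelPosteriorTable, posterior_table
from .inference import (
    FitProblem, FitResult, laplace_log_evidence, map_fit, uniform_prior,
)
from .model_zoo import default_params, get_model

__all__ = ["default_fit_spec", "fit_patient_model", "compare_models_on_cohort"]

# free-parameter subsets used for cohort screening, per model: the dominant
# on/off kinetic rates, with the remaining parameters held at reference values
_SCREEN_FREE = {
    "H10": ("gamma_D_on", "gamma_D_off", "gamma_Irr_on", "gamma_Irr_off"),
    "I08A": ("gamma_D_max", "delta_cA"),
    "B20": ("p_S", "delta_D"),
    "P12A": ("gamma_max", "q_min"),
    "P12B": ("gamma_max", "q_D_min", "q_I_min"),
}

_SCREEN_BOUNDS = {
    "H10": {"gamma_D_on": (-0.08, 0.0), "gamma_D_off": (0.0, 0.06),
            "gamma_Irr_on": (0.0, 0.004), "gamma_Irr_off": (0.0, 0.004)},
    "I08A": {"gamma_D_max": (0.05, 1.0), "delta_cA": (0.005, 0.5)},
    "B20": {"p_S": (1e-4, 0.1), "delta_D": (1e-3, 0.3)},
    "P12A": {"gamma_max": (5e-3, 0.1), "q_min": (0.05, 2.0)},
    "P12B": {"gamma_max": (5e-3, 0.1), "q_D_min": (0.05, 2.0),
             "q_I_min": (0.05, 2.0)},
}

_LOG_SPACE = {"H10": False, "I08A": True, "B20": True, "P12A": True,
              "P12B": True}


def _screen_init_state(model_id: str, record: PatientRecord,
                       fixed: dict) -> np.ndarray:
    """Heuristic initial state anchored to the first PSA draw."""
    c0 = float(record.psa[0])
    if model_id == "H10":
        return np.array([0.90 * c0, 0.07 * c0, 0.03 * c0])
    if model_id == "I08A":
        # treatment usually starts at t0: serum androgen at homeostasis
        return np.array([0.95 * c0, 0.05 * c0, fixed["c_A0"]])
    if model_id == "B20":
        n_D0 = c0 * fixed["delta_PSA"] / fixed["gamma_PSA"]
        return np.array([0.02 * n_D0, n_D0, c0])
    if model_id in ("P12A", "P12B"):
        q0 = 0.7 * fixed["q_max"]
        if model_id == "P12A":
            return np.array([0.9 * c0, 0.1 * c0, q0, c0])
        return np.array([0.9 * c0, 0.1 * c0, q0, q0, c0])
    raise ValueError(f"no screening defaults for model {model_id!r}")


def default_fit_spec(model_id: str, record: PatientRecord,
                     fixed_overrides: dict | None = None):
    """(problem, prior) with the screening free subset for this model."""
    md = get_model(model_id)
    free = _SCREEN_FREE[model_id]
    fixed = {n: v for n, v in zip(md.param_names, default_params(model_id))
             if n not in free}
    fixed.update(fixed_overrides or {})
    # LSODA handles the fast on-treatment decay channels; tolerances are
    # screening-grade (PSA accuracy ~1e-3 µg/L, far below the 0.1 µg/L assay
    # error).  Linear models keep their exact propagator (no method override).
    solver_opts = {"rtol": 3e-4, "atol": 1e-6, "negative_tol": 0.05,
                   "max_rhs_calls": 5_000}
    if md.linear_matrix is None:
        solver_opts["method"] = "LSODA"
    problem = FitProblem(
        model_id=model_id,
        patient=record,
        init_state=_screen_init_state(model_id, record, fixed),
        free=free,
        fixed=fixed,
        solver_opts=solver_opts,
    )
    bounds = [_SCREEN_BOUNDS[model_id][f] for f in free]
    prior = uniform_prior(free, bounds, log_space=_LOG_SPACE[model_id])
    return problem, prior


def fit_patient_model(
    model_id: str,
    record: PatientRecord,
    seed: int = 0,
    maxiter: int | None = None,
    popsize: int = 3,
    fixed_overrides: dict | None = None,
) -> FitResult:
    """Screening MAP fit with Laplace evidence for one model × patient.

    The default generation budget is larger for models with a cheap exact
    propagator; ``maxiter`` overrides it uniformly.
    """
    problem, prior = default_fit_spec(model_id, record, fixed_overrides)
    if maxiter is None:
        maxiter = 8 if get_model(model_id).linear_matrix is not None else 3
    fit = map_fit(problem, prior, seed=seed, popsize=popsize, maxiter=maxiter,
                  tol=0.01, polish_maxfun=20 * prior.ndim)
    fit.log_evidence = None
    try:
        fit.log_evidence = laplace_log_evidence(fit, prior)
    except Exception:
        # screening fallback: clip flat curvature directions at a small
        # positive floor so the Occam factor stays finite (flagged)
        try:
            F = np.asarray(fit.fisher_info, float)
            w, V = np.linalg.eigh(F)
            floor = 1e-8 * max(1.0, float(np.max(np.abs(w))))
            fit.fisher_info = (V * np.maximum(w, floor)) @ V.T
            fit.log_evidence = laplace_log_evidence(fit, prior)
            fit.flags.append(
                "laplace evidence from floor-regularized curvature")
        except Exception:
            pass
    if fit.log_evidence is None or not np.isfinite(fit.log_evidence):
        # last resort: posterior height, no Occam factor (curvature broken
        # at a low-quality MAP — the likelihood term dominates anyway)
        fit.log_evidence = fit.log_likelihood_at_map + fit.log_prior_at_map
        fit.flags.append("curvature unavailable; posterior-height proxy")
    return fit


def compare_models_on_cohort(
    cohort: Cohort,
    model_ids=("I08A", "H10", "B20"),
    seed: int = 0,
    maxiter: int | None = None,
    popsize: int = 3,
) -> list[ModelPosteriorTable]:
    """Per-patient model posterior tables over a cohort (equal model priors)."""
    tables = []
    for i, rec in enumerate(cohort):
        logz, errs = [], []
        for j, mid in enumerate(model_ids):
            fit = fit_patient_model(
                mid, rec, seed=seed + 1000 * j + i, maxiter=maxiter,
                popsize=popsize,
            )
            logz.append(fit.log_evidence)
            errs.append(0.0)
        tables.append(posterior_table(rec.patient_id, model_ids, logz, errs))
    return tables
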