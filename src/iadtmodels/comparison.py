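"""Bayes factors, model posterior probabilities and cohort-level ranking.

For models M_i with evidences Z_i and prior probabilities Pr(M_i), the odds
of M_i over M_j are O_ij = [Pr(M_i)/Pr(M_j)] · β_ij with the Bayes factor
β_ij = Z_i/Z_j, and the posterior probability of each model follows by
normalizing the odds against a common reference.  All arithmetic runs in
log space.  Cohort-level ranking credits each patient's winning model (ties
split fractionally) and reports the preference fraction per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort_io import PatientRecord
from .simulator import simulate

__all__ = [
    "ModelPosteriorTable",
    "model_posteriors",
    "bayes_factor",
    "cohort_ranking",
    "psa_drop_statistic",
    "omega_phase_pdf",
]


@dataclass
class ModelPosteriorTable:
    """Per-patient model comparison: evidences, posteriors, winner(s)."""

    patient_id: str
    model_ids: tuple[str, ...]
    log_evidences: np.ndarray
    log_evidence_errs: np.ndarray | None
    posteriors: np.ndarray
    winners: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.winners:
            best = np.max(self.posteriors)
            self.winners = tuple(
                m for m, p in zip(self.model_ids, self.posteriors)
                if np.isclose(p, best, rtol=0.0, atol=1e-12)
            )

    @property
    def winner(self) -> str:
        return self.winners[0]


def model_posteriors(log_evidences, model_priors=None) -> np.ndarray:
    """Posterior model probabilities from log-evidences (log-space safe).

    NaN or −∞ evidences contribute zero posterior weight (with a warning);
    equal priors are assumed unless ``model_priors`` is given.
    """
    logz = np.asarray(log_evidences, dtype=float)
    if logz.size < 2:
        raise ValueError("need at least two models to compare")
    if model_priors is None:
        logprior = np.zeros(logz.size)
    else:
        pr = np.asarray(model_priors, dtype=float)
        if np.any(pr <= 0):
            raise ValueError("model priors must be positive")
        logprior = np.log(pr / pr.sum())
    score = logz + logprior
    bad = ~np.isfinite(score)
    if bad.any():
        import warnings
        warnings.warn(
            f"{bad.sum()} model(s) with non-finite evidence get zero "
            "posterior weight", RuntimeWarning, stacklevel=2,
        )
        score = np.where(bad, -np.inf, score)
    if not np.any(np.isfinite(score)):
        raise ValueError("no model has finite evidence")
    return np.exp(score - logsumexp(score))


def bayes_factor(log_evidence_i: float, log_evidence_j: float) -> float:
    """β_ij = Z_i / Z_j."""
    return float(np.exp(log_evidence_i - log_evidence_j))


def posterior_table(patient_id, model_ids, log_evidences,
                    log_evidence_errs=None, model_priors=None
                    ) -> ModelPosteriorTable:
    post = model_posteriors(log_evidences, model_priors)
    return ModelPosteriorTable(
        patient_id=patient_id,
        model_ids=tuple(model_ids),
        log_evidences=np.asarray(log_evidences, float),
        log_evidence_errs=(None if log_evidence_errs is None
                           else np.asarray(log_evidence_errs, float)),
        posteriors=post,
    )


def cohort_ranking(tables: list[ModelPosteriorTable]) -> pd.DataFrame:
    """Per-model cohort preference fraction and mean normalized log-evidence.

    Each patient contributes one unit of credit, split equally among tied
    winning models.  Normalized log-evidence subtracts the per-patient
    maximum before averaging, so patients with different data sizes weigh
    comparably.
    """
    if not tables:
        raise ValueError("empty table list")
    model_ids = tables[0].model_ids
    if any(t.model_ids != model_ids for t in tables):
        raise ValueError("all tables must rank the same models")
    wins = dict.fromkeys(model_ids, 0.0)
    norm_logz = dict.fromkeys(model_ids, 0.0)
    for t in tables:
        share = 1.0 / len(t.winners)
        for w in t.winners:
            wins[w] += share
        ref = np.max(t.log_evidences[np.isfinite(t.log_evidences)])
        for m, lz in zip(model_ids, t.log_evidences):
            norm_logz[m] += (lz - ref) if np.isfinite(lz) else -np.inf
    n = len(tables)
    return pd.DataFrame({
        "model_id": list(model_ids),
        "preference_fraction": [wins[m] / n for m in model_ids],
        "mean_normalized_log_evidence": [norm_logz[m] / n for m in model_ids],
    })


# ---------------------------------------------------------------------------
# PSA-drop statistic and phase-space densities
# ---------------------------------------------------------------------------

def psa_drop_statistic(patient: PatientRecord) -> float:
    """PSA at its first-cycle minimum over PSA entering the first cycle.

    A small value means a deep response during the first on-treatment cycle
    (a strong indicator of continued response); a value of 1 means PSA never
    fell below its entry level inside the cycle.
    """
    if patient.schedule.n_cycles < 1:
        raise ValueError(f"{patient.patient_id}: no treatment cycle")
    tau1 = patient.schedule.intervals[0]
    mask = (patient.times >= tau1.start) & (patient.times < tau1.end)
    if mask.sum() < 2:
        raise ValueError(
            f"{patient.patient_id}: fewer than 2 points in the first cycle"
        )
    series = patient.psa[mask]
    return float(series.min() / series[0])


def omega_phase_pdf(
    fits,
    variables,
    labels=None,
    n_grid: int = 120,
    bins="fd",
    contour_masses=(0.1, 0.68, 0.95),
) -> dict:
    """Phase-space occupation densities of fitted trajectories per Ω label.

    Each fit is re-simulated over a uniform time grid spanning its
    patient's window; the requested state variables are pooled per label
    (uniform weight in time) and summarized as a normalized histogram
    (Freedman–Diaconis binning in 1D; per-axis FD bins in 2–3D), together
    with the density levels enclosing the given probability masses.
    """
    model_ids = {f.model_id for f in fits}
    if len(model_ids) != 1:
        raise ValueError(f"fits mix model ids: {sorted(model_ids)}")
    model_id = model_ids.pop()
    from .model_zoo import get_model
    md = get_model(model_id)
    var_idx = [md.state_names.index(v) for v in variables]
    if not 1 <= len(var_idx) <= 3:
        raise ValueError("1 to 3 state variables supported")

    if labels is None:
        labels = [f.patient.label for f in fits]
    pooled: dict[str, list[np.ndarray]] = {}
    for f, lab in zip(fits, labels):
        rec = f.patient
        if rec is None:
            raise ValueError("fit lacks its patient record")
        t_grid = np.linspace(rec.schedule.t_min, rec.schedule.t_max, n_grid)
        _, x0 = f.problem.assemble(f.map_free)
        traj = simulate(model_id, f.map_params, x0, rec.schedule, t_grid,
                        solver_opts={"rtol": 1e-6, "atol": 1e-8})
        pooled.setdefault(lab, []).append(traj.states[var_idx])

    out = {}
    for lab, chunks in pooled.items():
        data = np.concatenate(chunks, axis=1).T  # (samples, n_vars)
        if data.shape[1] == 1:
            hist, edges = np.histogram(data[:, 0], bins=bins, density=True)
            edges = [edges]
        else:
            per_axis = [np.histogram_bin_edges(data[:, j], bins=bins)
                        for j in range(data.shape[1])]
            hist, edges = np.histogramdd(data, bins=per_axis, density=True)
        out[lab] = {
            "density": hist,
            "edges": edges,
            "levels": _contour_levels(hist, edges, contour_masses),
        }
    return out


def _contour_levels(density, edges, masses):
    """Density levels whose superlevel sets enclose the given masses."""
    widths = [np.diff(e) for e in edges]
    cell = widths[0]
    for w in widths[1:]:
        cell = np.multiply.outer(cell, w)
    d = density.ravel()
    vol = np.asarray(cell).ravel()
    order = np.argsort(-d)
    cum = np.cumsum(d[order] * vol[order])
    levels = {}
    for m in masses:
        idx = np.searchsorted(cum, m)
        idx = min(idx, d.size - 1)
        levels[m] = float(d[order][idx])
    return levels
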