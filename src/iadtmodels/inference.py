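"""Bayesian calibration of one model to one patient.

The observation model is an independent-Gaussian likelihood with the
per-point assigned PSA errors as standard deviations,

    log L(p) = −½ Σ_i [(c_obs,i − c_model(t_i; p)) / e_i]²
               − Σ_i log(e_i √(2π)),

with the model PSA obtained by piecewise ODE integration under the
patient's treatment schedule.  The 1-day time error of the data is not
propagated (the PSA error dominates at the sampling cadences involved).

MAP search runs differential evolution in the prior's unit-cube
coordinates (scaling factor 0.9, crossover probability 0.1, population
10 × dim), followed by a local polish.  Model evidence is available two
ways: a Laplace approximation around the MAP using the Gauss–Newton
curvature of the Gaussian likelihood, and nested sampling (quantified
error, log-coordinate exploration through the prior transform).  Both
estimators are deterministic given their seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .cohort_io import PatientRecord
from .model_zoo import get_model
from .nested import NestedResult, nested_sampling
from .simulator import SimulationError, simulate_psa

__all__ = [
    "PriorEntry",
    "PriorSpec",
    "FitProblem",
    "FitResult",
    "NonIdentifiableError",
    "InsufficientSampleError",
    "log_likelihood",
    "map_fit",
    "laplace_log_evidence",
    "nested_log_evidence",
    "build_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)
_FISHER_FLAG_TOL = 1e-12


class NonIdentifiableError(RuntimeError):
    """Curvature at the MAP is not positive definite along named directions."""


class InsufficientSampleError(ValueError):
    """Too few cohort fits to build an empirical prior above Poisson noise."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorEntry:
    """Proper prior for one parameter on a truncated support [lower, upper]."""

    name: str
    kind: str = "uniform"            # uniform | jeffreys | empirical
    lower: float = 0.0
    upper: float = 1.0
    log_space: bool = False          # flat in log10(p) rather than p
    grid: np.ndarray | None = None   # tabulated density support (param values)
    density: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.upper) or self.upper <= self.lower:
            raise ValueError(f"{self.name}: prior support must be finite, "
                             "upper > lower")
        if self.log_space and self.lower <= 0:
            raise ValueError(f"{self.name}: log-space prior needs lower > 0")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            dens = np.clip(np.asarray(self.density, dtype=float), 0.0, None)
            norm = np.trapezoid(dens, self.grid)
            if norm <= 0:
                raise ValueError(f"{self.name}: tabulated density not normalizable")
            self.density = dens / norm
            cdf = np.concatenate(([0.0], np.cumsum(
                0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.grid)
            )))
            self._cdf = cdf / cdf[-1]

    # density ---------------------------------------------------------------

    def logpdf(self, x: float) -> float:
        if not (self.lower <= x <= self.upper):
            return -np.inf
        if self.grid is not None:
            d = float(np.interp(x, self.grid, self.density))
            return math.log(d) if d > 0 else -np.inf
        if self.log_space:
            return -math.log(x * math.log(self.upper / self.lower))
        return -math.log(self.upper - self.lower)

    def ppf(self, u: float) -> float:
        if self.grid is not None:
            return float(np.interp(u, self._cdf, self.grid))
        if self.log_space:
            return float(self.lower * (self.upper / self.lower) ** u)
        return float(self.lower + u * (self.upper - self.lower))


@dataclass
class PriorSpec:
    entries: tuple[PriorEntry, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def ndim(self) -> int:
        return len(self.entries)

    def logpdf(self, theta) -> float:
        return float(sum(e.logpdf(x) for e, x in zip(self.entries, theta)))

    def transform(self, u) -> np.ndarray:
        """Unit-cube quantile coordinates → parameter values."""
        return np.array([e.ppf(v) for e, v in zip(self.entries, u)])

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.transform(rng.random(self.ndim))


def uniform_prior(names, bounds, log_space=False) -> PriorSpec:
    """Flat prior, per-parameter, on the given truncated supports."""
    entries = []
    for name, (lo, hi) in zip(names, bounds):
        if log_space and lo <= 0:
            lo = max(lo, 1e-6 * hi)
        entries.append(PriorEntry(name=name, kind="uniform", lower=lo,
                                  upper=hi, log_space=log_space))
    return PriorSpec(tuple(entries))


# ---------------------------------------------------------------------------
# fitting problems
# ---------------------------------------------------------------------------

@dataclass
class FitProblem:
    """One model × one patient with a chosen free-parameter subset.

    ``free`` names the parameters being calibrated; every other model
    parameter must appear in ``fixed``.  Initial conditions are fixed at
    ``init_state`` unless a free entry is named '<state>0', in which case
    that component of the initial state is calibrated too.
    """

    model_id: str
    patient: PatientRecord
    init_state: np.ndarray
    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    solver_opts: dict | None = None

    def __post_init__(self):
        md = get_model(self.model_id)
        self.init_state = np.asarray(self.init_state, dtype=float)
        self._ic_slots = {}
        names = []
        for f in self.free:
            if f in md.param_names:
                names.append(f)
            elif f.endswith("0") and f[:-1] in md.state_names:
                self._ic_slots[f] = md.state_names.index(f[:-1])
            else:
                raise ValueError(f"{self.model_id}: unknown free entry {f!r}")
        missing = set(md.param_names) - set(names) - set(self.fixed)
        if missing:
            raise ValueError(
                f"{self.model_id}: parameters neither free nor fixed: "
                f"{sorted(missing)}"
            )
        if self.patient.n_points < 1:
            raise ValueError("patient record has no usable points")

    @property
    def ndim(self) -> int:
        return len(self.free)

    def default_bounds(self) -> list[tuple[float, float]]:
        md = get_model(self.model_id)
        out = []
        for f in self.free:
            if f in self._ic_slots:
                out.append((0.0, 1e3))
            else:
                out.append(md.bounds[md.pindex(f)])
        return out

    def assemble(self, theta) -> tuple[np.ndarray, np.ndarray]:
        md = get_model(self.model_id)
        d = dict(self.fixed)
        x0 = self.init_state.copy()
        for f, val in zip(self.free, theta):
            if f in self._ic_slots:
                x0[self._ic_slots[f]] = val
            else:
                d[f] = val
        return md.pvector(d), x0

    def predict(self, theta) -> np.ndarray:
        params, x0 = self.assemble(theta)
        # fitting-grade defaults: mid tolerances plus a work cap so that
        # pathological trial points fail fast instead of stalling the search
        opts = self.solver_opts or {"rtol": 1e-6, "atol": 1e-8,
                                    "max_rhs_calls": 100_000}
        return simulate_psa(
            self.model_id, params, x0, self.patient.schedule,
            self.patient.times, solver_opts=opts, validate=False,
        )

    def loglik(self, theta) -> float:
        try:
            model_psa = self.predict(theta)
        except (SimulationError, ValueError) as exc:
            warnings.warn(f"simulation failed at theta={theta}: {exc}",
                          RuntimeWarning, stacklevel=2)
            return -np.inf
        return gaussian_loglik(self.patient.psa, model_psa, self.patient.errors)


def gaussian_loglik(observed, predicted, errors) -> float:
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    errors = np.asarray(errors, float)
    if np.any(errors <= 0):
        raise ValueError("nonpositive measurement error")
    if not np.all(np.isfinite(predicted)):
        return -np.inf
    z = (observed - predicted) / errors
    return float(-0.5 * np.sum(z * z) - np.sum(np.log(errors))
                 - 0.5 * observed.size * _LOG_2PI)


def log_likelihood(model_id, params, patient: PatientRecord, init_state,
                   solver_opts=None) -> float:
    """Gaussian log-likelihood of a full parameter vector for one patient."""
    if patient.n_points < 1:
        raise ValueError("patient record has no usable points")
    try:
        psa = simulate_psa(model_id, params, init_state, patient.schedule,
                           patient.times, solver_opts=solver_opts)
    except SimulationError as exc:
        warnings.warn(f"simulation failed: {exc}", RuntimeWarning, stacklevel=2)
        return -np.inf
    return gaussian_loglik(patient.psa, psa, patient.errors)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model_id: str
    patient_id: str
    free: tuple[str, ...]
    map_free: np.ndarray
    map_params: np.ndarray | None      # full parameter vector (model order)
    log_likelihood_at_map: float
    log_prior_at_map: float
    fisher_info: np.ndarray | None
    seed: int
    log_evidence: float | None = None
    log_evidence_err: float | None = None
    samples: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    patient: PatientRecord | None = None
    problem: object | None = None

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "patient_id": self.patient_id,
            "free": list(self.free),
            "map_free": np.asarray(self.map_free).tolist(),
            "map_params": (None if self.map_params is None
                           else np.asarray(self.map_params).tolist()),
            "log_likelihood_at_map": self.log_likelihood_at_map,
            "log_prior_at_map": self.log_prior_at_map,
            "fisher_info": (None if self.fisher_info is None
                            else np.asarray(self.fisher_info).tolist()),
            "log_evidence": self.log_evidence,
            "log_evidence_err": self.log_evidence_err,
            "seed": self.seed,
            "flags": self.flags,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# MAP search
# ---------------------------------------------------------------------------

def map_fit(
    problem,
    prior: PriorSpec,
    seed: int = 0,
    popsize: int = 10,
    maxiter: int = 150,
    mutation: float = 0.9,
    recombination: float = 0.1,
    tol: float = 1e-8,
    polish: bool = True,
    polish_maxfun: int | None = None,
    fisher: bool = True,
    workers: int = 1,
) -> FitResult:
    """Maximize the log posterior with seeded differential evolution.

    The search runs in the prior's unit-cube coordinates (so log-space
    priors are explored logarithmically); a local polish refines the best
    member.  The Fisher information at the MAP is the Gauss–Newton
    curvature of the Gaussian likelihood when the problem exposes
    ``predict``, otherwise a central-difference Hessian of −log L.
    """
    k = prior.ndim
    if hasattr(problem, "free") and tuple(prior.names) != tuple(problem.free):
        raise ValueError("prior entries must match the problem's free names")

    def negpost(u):
        theta = prior.transform(u)
        lp = prior.logpdf(theta)
        if not np.isfinite(lp):
            return 1e12
        ll = problem.loglik(theta)
        if not np.isfinite(ll):
            return 1e12
        return -(ll + lp)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = differential_evolution(
            negpost,
            bounds=[(0.0, 1.0)] * k,
            seed=seed,
            popsize=popsize,
            maxiter=maxiter,
            mutation=mutation,
            recombination=recombination,
            tol=tol,
            polish=False,
            init="sobol",
            workers=workers,
        )
        if polish and np.isfinite(res.fun) and res.fun < 1e12:
            # bounded local refinement of the best member
            from scipy.optimize import minimize
            loc = minimize(
                negpost, res.x, method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * k,
                options={"maxfun": polish_maxfun or 60 * k,
                         "ftol": 1e-12, "gtol": 1e-10},
            )
            if loc.fun < res.fun:
                res.x, res.fun = loc.x, loc.fun
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise RuntimeError(
            "no feasible start: every trial point failed to simulate or had "
            "zero prior mass; consider widening the prior support"
        )
    theta_hat = prior.transform(np.clip(res.x, 0.0, 1.0))
    ll_hat = problem.loglik(theta_hat)
    lp_hat = prior.logpdf(theta_hat)

    F = None
    flags = []
    if fisher and k > 0:
        F = _fisher_information(problem, theta_hat)
        for j, name in enumerate(prior.names):
            if F[j, j] < _FISHER_FLAG_TOL:
                flags.append(f"non-identifiable direction: {name} "
                             f"(Fisher diagonal {F[j, j]:.3g})")

    full = None
    if hasattr(problem, "assemble"):
        full, _ = problem.assemble(theta_hat)
    return FitResult(
        model_id=getattr(problem, "model_id", "custom"),
        patient_id=getattr(getattr(problem, "patient", None), "patient_id",
                           "synthetic"),
        free=tuple(prior.names),
        map_free=theta_hat,
        map_params=full,
        log_likelihood_at_map=float(ll_hat),
        log_prior_at_map=float(lp_hat),
        fisher_info=F,
        seed=seed,
        flags=flags,
        patient=getattr(problem, "patient", None),
        problem=problem,
    )


def _fisher_information(problem, theta_hat) -> np.ndarray:
    k = len(theta_hat)
    if hasattr(problem, "predict") and hasattr(problem, "patient"):
        try:
            errors = problem.patient.errors
            J = np.empty((errors.size, k))
            for j in range(k):
                h = 1e-5 * max(abs(theta_hat[j]), 1e-4)
                tp, tm = np.array(theta_hat, float), np.array(theta_hat, float)
                tp[j] += h
                tm[j] -= h
                J[:, j] = (problem.predict(tp) - problem.predict(tm)) / (2 * h)
            if not np.all(np.isfinite(J)):
                raise FloatingPointError("non-finite prediction Jacobian")
            return (J / errors[:, None]).T @ (J / errors[:, None])
        except Exception:
            pass  # fall through to the Hessian of the log-likelihood
    # generic fallback: central-difference Hessian of the negative loglik
    H = np.empty((k, k))
    f0 = problem.loglik(theta_hat)
    hs = [1e-4 * max(abs(t), 1e-4) for t in theta_hat]
    for a in range(k):
        for b in range(a, k):
            tpp = np.array(theta_hat, float)
            tpm = np.array(theta_hat, float)
            tmp = np.array(theta_hat, float)
            tmm = np.array(theta_hat, float)
            tpp[[a, b]] += [hs[a], hs[b]]
            tpm[a] += hs[a]
            tpm[b] -= hs[b]
            tmp[a] -= hs[a]
            tmp[b] += hs[b]
            tmm[[a, b]] -= [hs[a], hs[b]]
            if a == b:
                val = -(problem.loglik(tpp) - 2 * f0 + problem.loglik(tmm)) \
                    / (hs[a] ** 2)
            else:
                val = -(problem.loglik(tpp) - problem.loglik(tpm)
                        - problem.loglik(tmp) + problem.loglik(tmm)) \
                    / (4 * hs[a] * hs[b])
            H[a, b] = H[b, a] = val
    return H


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def laplace_log_evidence(fit: FitResult, prior: PriorSpec,
                         paper_variant: bool = False) -> float:
    """Laplace-approximation log-evidence around the MAP.

    Default: log Pr(p̂) + log L(p̂) + (k/2) log 2π − ½ log det A with A the
    curvature of −log posterior at p̂ (the Gauss–Newton Fisher matrix under
    a flat prior).  ``paper_variant`` instead multiplies by √det F, i.e.
    returns log Pr(p̂) + log L(p̂) + ½ log det F; both conventions are kept
    so the difference is auditable.
    """
    k = len(fit.free)
    if k == 0:
        return fit.log_likelihood_at_map
    F = fit.fisher_info
    if F is None:
        raise ValueError("fit carries no Fisher information")
    eigvals, eigvecs = np.linalg.eigh(np.asarray(F, float))
    if np.min(eigvals) <= 0:
        flat = []
        for idx in np.flatnonzero(eigvals <= 0):
            j = int(np.argmax(np.abs(eigvecs[:, idx])))
            flat.append(fit.free[j])
        raise NonIdentifiableError(
            "curvature at the MAP is not positive definite; flat directions "
            f"dominated by: {sorted(set(flat))}"
        )
    logdet = float(np.sum(np.log(eigvals)))
    base = fit.log_prior_at_map + fit.log_likelihood_at_map
    if paper_variant:
        return base + 0.5 * logdet
    return base + 0.5 * k * _LOG_2PI - 0.5 * logdet


def nested_log_evidence(
    problem,
    prior: PriorSpec,
    nlive: int = 400,
    seed: int = 0,
    dlogz: float = 0.05,
    n_steps: int = 25,
    return_result: bool = False,
):
    """Nested-sampling log-evidence with its statistical error.

    Sampling runs in the prior's quantile coordinates, so log-space priors
    are explored logarithmically.  Termination diagnostics (likelihood
    plateaus, iteration caps) are surfaced on the returned result object.
    """
    res = nested_sampling(
        lambda u: problem.loglik(prior.transform(u)),
        ndim=prior.ndim, nlive=nlive, seed=seed, dlogz=dlogz, n_steps=n_steps,
    )
    if res.termination not in ("dlogz",):
        warnings.warn(f"nested sampling termination: {res.termination}",
                      RuntimeWarning, stacklevel=2)
    if return_result:
        return res
    return res.log_evidence, res.log_evidence_err


# ---------------------------------------------------------------------------
# prior construction
# ---------------------------------------------------------------------------

def build_prior(model_id: str, mode: str = "uniform",
                context: dict | None = None) -> PriorSpec:
    """Construct a prior for a model's (sub)set of free parameters.

    Modes
    -----
    uniform
        Truncated flat prior on [lower, p_max] per parameter; optionally
        flat in log10 (``context['log_space']``).
    jeffreys
        Density ∝ √det F(p), tabulated per parameter on a grid over the
        support while the remaining parameters sit at a reference point;
        requires ``context['fisher']`` (callable p → Fisher matrix) and
        ``context['reference']``.
    empirical
        Per-parameter smoothed histogram of cohort MAP values; requires
        ``context['fits']`` (prior FitResults) and ``context['n_pat']``;
        refuses to build below the Poisson-noise sample size ceil(√N_pat).
    """
    context = dict(context or {})
    md = get_model(model_id)
    free = tuple(context.get("free", md.param_names))
    bounds = []
    for f in free:
        if f in md.param_names:
            bounds.append(md.bounds[md.pindex(f)])
        else:
            bounds.append((0.0, 1e3))
    bounds = [tuple(context.get("bounds", {}).get(f, b))
              for f, b in zip(free, bounds)]

    if mode == "uniform":
        return uniform_prior(free, bounds,
                             log_space=context.get("log_space", False))

    if mode == "jeffreys":
        fisher = context["fisher"]
        ref = np.asarray(context["reference"], dtype=float)
        n_grid = int(context.get("n_grid", 41))
        entries = []
        for j, (name, (lo, hi)) in enumerate(zip(free, bounds)):
            glo = max(lo, 1e-6 * hi)
            grid = np.geomspace(glo, hi, n_grid)
            dens = np.empty(n_grid)
            for g, val in enumerate(grid):
                p = ref.copy()
                p[j] = val
                F = np.atleast_2d(np.asarray(fisher(p), dtype=float))
                det = np.linalg.det(F)
                dens[g] = math.sqrt(max(det, 0.0))
            entries.append(PriorEntry(name=name, kind="jeffreys", lower=glo,
                                      upper=hi, grid=grid, density=dens))
        return PriorSpec(tuple(entries))

    if mode == "empirical":
        fits = context["fits"]
        n_pat = int(context["n_pat"])
        need = math.ceil(math.sqrt(n_pat))
        if len(fits) < need:
            raise InsufficientSampleError(
                f"empirical prior needs >= ceil(sqrt(N_pat)) = {need} fits "
                f"(above the Poisson-noise sample size); got {len(fits)}"
            )
        entries = []
        for j, (name, (lo, hi)) in enumerate(zip(free, bounds)):
            vals = np.array([f.map_free[f.free.index(name)] for f in fits])
            grid = np.linspace(lo, hi, 201)
            width = max(np.std(vals) * len(vals) ** (-1 / 5), 1e-3 * (hi - lo))
            dens = np.exp(
                -0.5 * ((grid[:, None] - vals[None, :]) / width) ** 2
            ).sum(axis=1)
            entries.append(PriorEntry(name=name, kind="empirical", lower=lo,
                                      upper=hi, grid=grid, density=dens))
        return PriorSpec(tuple(entries))

    raise ValueError(f"unknown prior mode {mode!r}")
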