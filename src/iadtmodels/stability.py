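"""Equilibria and local stability of the IADT models, phase by phase.

With the treatment control frozen at u = 0 (off) or u = 1 (on) every model
becomes autonomous, and its rest points can be catalogued analytically for
most systems; the higher-dimensional quota models only admit numerical
root-finding.  ``find_equilibria`` merges a hard-coded analytic catalogue
with quasi-random multi-start root search, ``eigen_analysis`` evaluates the
Jacobian spectrum at a verified rest point, and ``classify`` maps the
spectrum to a hyperbolicity class.

Several models have equilibrium *manifolds* (a line for I08A, a plane for
B20): these are represented by one sampled representative point, with the
free coordinate noted in the equilibrium's ``family`` field.  Ratio terms of
the multi-population quota models are removably singular when all
populations vanish; such rest points carry a ``directional`` flag and are
evaluated along the nonnegative orthant at a tiny positive population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

from .model_zoo import SingularStateError, get_model
from .numdiff import rhs_jacobian_states

__all__ = [
    "EquilibriumPoint",
    "StabilityReport",
    "find_equilibria",
    "eigen_analysis",
    "classify",
]

_RES_TOL = 1e-10       # ‖rhs‖∞ contract for a returned equilibrium
_DEDUP_TOL = 1e-6
_DIR_EPS = 1e-14       # directional-limit population for removable ratios
_CLASSIFY_TOL = 1e-9   # day⁻¹


@dataclass
class EquilibriumPoint:
    """A rest point of one model at fixed treatment phase."""

    model_id: str
    state: np.ndarray
    phase: str                      # "on" | "off"
    source: str                     # "analytic_catalogue" | "numeric_root"
    family: str | None = None       # free coordinate(s) for manifold members
    directional: bool = False       # evaluated via a nonnegative-orthant limit
    dir_states: tuple[str, ...] = ()  # states nudged for the directional limit
    note: str | None = None

    @property
    def u(self) -> int:
        return 1 if self.phase == "on" else 0

    def eval_state(self) -> np.ndarray:
        """State used for RHS/Jacobian evaluation (directional limit if needed)."""
        if not self.directional:
            return self.state
        md = get_model(self.model_id)
        x = self.state.copy()
        for name in self.dir_states:
            x[md.state_names.index(name)] = _DIR_EPS
        return x

    def residual(self, params) -> float:
        md = get_model(self.model_id)
        try:
            r = md.rhs(0.0, self.eval_state(), np.asarray(params, float), self.u)
        except SingularStateError:
            return np.inf
        return float(np.max(np.abs(r)))


@dataclass
class StabilityReport:
    equilibrium: EquilibriumPoint
    eigenvalues: np.ndarray         # sorted by descending real part, day⁻¹
    classification: str             # stable | unstable | saddle | nonhyperbolic
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.equilibrium.model_id,
            "phase": self.equilibrium.phase,
            "state": self.equilibrium.state.tolist(),
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "classification": self.classification,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# analytic catalogue
# ---------------------------------------------------------------------------

def _quota_equilibrium_p12(d, q_min, u):
    if u == 1:
        return d["gamma_max"] * q_min / (d["gamma_max"] + d["delta_q"])
    B = (d["q_max"] - q_min) * (d["k_q2"] + 1.0)
    den = d["v_max"] + (d["gamma_max"] + d["delta_q"]) * B
    return (d["v_max"] * d["q_max"] + d["gamma_max"] * q_min * B) / den


def _quota_equilibrium_b16(d, q_min, u):
    gamma = d["gamma_1"] * u + d["gamma_2"]
    den = d["gamma_max"] + gamma
    return d["q_max"] + d["gamma_max"] * (q_min - d["q_max"]) / den


def _catalogue(model_id: str, params: np.ndarray, phase: str,
               rep_population: float) -> list[EquilibriumPoint]:
    md = get_model(model_id)
    d = md.pdict(params)
    u = 1 if phase == "on" else 0
    P = lambda *a, **k: EquilibriumPoint(model_id, np.array(a[0], float),
                                         phase, "analytic_catalogue", **k)
    pts: list[EquilibriumPoint] = []

    if model_id == "I08A":
        # line of equilibria: n_D = 0, c_A pinned, n_I free
        pts.append(P([0.0, rep_population, d["c_A0"] * (1 - u)],
                     family="n_I free (equilibrium line)"))
    elif model_id == "I08B":
        pts.append(P([0.0, 0.0, d["c_A0"] * (1 - u)]))
    elif model_id == "H10":
        pts.append(P([0.0, 0.0, 0.0]))
    elif model_id == "P12A":
        q = _quota_equilibrium_p12(d, d["q_min"], u)
        pts.append(P([0.0, 0.0, q, 0.0]))
    elif model_id in ("P12B", "M14"):
        qD = _quota_equilibrium_p12(d, d["q_D_min"], u)
        qI = _quota_equilibrium_p12(d, d["q_I_min"], u)
        pts.append(P([0.0, 0.0, qD, qI, 0.0]))
    elif model_id == "B16A":
        q = _quota_equilibrium_b16(d, d["q_min"], u)
        if d["delta_PSA"] == 0:
            pts.append(P([np.nan] * 4, note="delta_PSA = 0: c_PSA level undefined"))
        else:
            pts.append(P([0.0, 0.0, d["gamma_PSA0"] * q / d["delta_PSA"], q]))
            if d["delta"] > 0 and q > 0:
                n2 = d["gamma_max"] * (q - d["q_min"]) / (q * d["delta"])
                c2 = (
                    d["delta"] * d["gamma_PSA0"] * q
                    + d["gamma_max"] * d["gamma_PSA1"] * (q - d["q_min"])
                ) / (d["delta_PSA"] * d["delta"])
                pts.append(P([n2, 0.0, c2, q]))
    elif model_id == "B16B":
        q = _quota_equilibrium_b16(d, d["q_I_min"], u)
        if d["delta_PSA"] > 0:
            pts.append(P([0.0, 0.0, q, d["gamma_PSA0"] * q / d["delta_PSA"]],
                         directional=True, dir_states=("n_I",),
                         note="n_D = 0 branch; ratio term taken along n_I > 0"))
    elif model_id == "Z17":
        if d["delta"] > 0:
            pts.append(P([0.0, d["K_P"], 0.0, d["K_P"] / d["delta"]]))
            b = d["beta"] - d["alpha_12"] - u + 1.0
            dd = d["alpha_21"] * b + 1.0
            if dd != 0 and b >= 0:
                pts.append(P([
                    d["K_P"] * b / dd,
                    d["K_P"] / dd,
                    0.0,
                    d["K_P"] * (b + 1.0) / (dd * d["delta"]),
                ]))
    elif model_id == "P19":
        if phase == "off" and d["delta_PSA"] > 0:
            den = d["gamma_2"] + d["gamma_max"]
            if den > 0:
                q = (d["gamma_max"] * d["q_I_min"] + d["gamma_2"] * d["q_max"]) / den
                pts.append(P([0.0, 0.0, 0.0, q,
                              d["gamma_PSA0"] * q / d["delta_PSA"]],
                             directional=True, dir_states=("n_I",),
                             note="all-population limit along n_I > 0"))
    elif model_id == "B20":
        if phase == "off" and d["delta_PSA"] > 0:
            nD = rep_population
            pts.append(P([0.0, nD, d["gamma_PSA"] * nD / d["delta_PSA"]],
                         family="n_D free (equilibrium plane)"))
    # E16: no equilibria (one state drifts at constant rate); E10: the
    # printed critical points do not zero the full RHS, numeric search only.
    return pts


# ---------------------------------------------------------------------------
# numeric multi-start root finding
# ---------------------------------------------------------------------------

def _numeric_roots(model_id: str, params: np.ndarray, phase: str,
                   n_starts: int, seed: int,
                   state_range: tuple[float, float]) -> list[EquilibriumPoint]:
    md = get_model(model_id)
    u = 1 if phase == "on" else 0
    lo, hi = np.log10(state_range[0]), np.log10(state_range[1])
    sampler = qmc.Sobol(d=md.n_states, scramble=True, rng=np.random.default_rng(seed))
    m = max(1, int(np.ceil(np.log2(n_starts))))
    starts = 10.0 ** (lo + (hi - lo) * sampler.random_base2(m=m)[:n_starts])

    def f(x):
        try:
            return md.rhs(0.0, x, params, u)
        except (SingularStateError, FloatingPointError):
            return np.full(md.n_states, 1e6)

    found = []
    for x0 in starts:
        sol = root(f, x0, method="hybr", options={"xtol": 1e-12})
        if not sol.success:
            continue
        x = sol.x
        if np.any(x < -1e-8):
            continue
        x = np.where(np.abs(x) < 1e-12, 0.0, x)
        try:
            res = np.max(np.abs(md.rhs(0.0, x, params, u)))
        except SingularStateError:
            continue
        if res > _RES_TOL:
            continue
        found.append(EquilibriumPoint(model_id, x, phase, "numeric_root"))
    return found


def _dedup(points: list[EquilibriumPoint]) -> list[EquilibriumPoint]:
    kept: list[EquilibriumPoint] = []
    for p in points:
        if any(
            np.max(np.abs(p.state - q.state)) < _DEDUP_TOL
            and not np.any(np.isnan(p.state))
            for q in kept
        ):
            continue
        kept.append(p)
    return kept


def find_equilibria(
    model_id: str,
    params,
    phase: str,
    include_numeric: bool = True,
    n_starts: int = 64,
    seed: int = 0,
    rep_population: float = 1.0,
    state_range: tuple[float, float] = (1e-6, 1e3),
) -> list[EquilibriumPoint]:
    """Rest points of ``model_id`` at fixed phase ("on" or "off").

    Returns the union of the analytic catalogue and multi-start numeric
    roots (64 scrambled-Sobol starts in log-state-space by default),
    deduplicated at 1e-6 and restricted to the nonnegative orthant.
    Catalogue members whose defining expression is undefined for the given
    parameters are returned with a note instead of being silently dropped.
    """
    if phase not in ("on", "off"):
        raise ValueError("phase must be 'on' or 'off'")
    md = get_model(model_id)
    params = np.asarray(params, dtype=float)
    bad = md.validate(params)
    if bad:
        raise ValueError(f"{model_id}: invalid parameters: {bad}")

    pts = _catalogue(model_id, params, phase, rep_population)
    verified = []
    for p in pts:
        if np.any(np.isnan(p.state)):
            verified.append(p)  # undefined expression, reported with note
            continue
        if p.residual(params) <= max(_RES_TOL, 1e-9 * np.max(np.abs(p.state) + 1)):
            verified.append(p)
    if include_numeric:
        verified.extend(
            _numeric_roots(model_id, params, phase, n_starts, seed, state_range)
        )
    return _dedup(verified)


# ---------------------------------------------------------------------------
# spectrum and classification
# ---------------------------------------------------------------------------

def classify(eigenvalues, tol: float = _CLASSIFY_TOL) -> str:
    """Hyperbolicity class from the real parts of the spectrum.

    any |Re λ| ≤ tol → "nonhyperbolic"; otherwise all Re < 0 → "stable",
    all Re > 0 → "unstable", mixed signs → "saddle".
    """
    re = np.real(np.asarray(eigenvalues, dtype=complex))
    if re.size == 0:
        raise ValueError("empty spectrum")
    if not np.all(np.isfinite(re)):
        raise ValueError("non-finite eigenvalues")
    if np.any(np.abs(re) <= tol):
        return "nonhyperbolic"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def eigen_analysis(model_id: str, params, eq: EquilibriumPoint,
                   tol: float = _CLASSIFY_TOL) -> StabilityReport:
    """Jacobian spectrum at a verified rest point, sorted by Re λ descending.

    The Jacobian is taken by complex-step differentiation where the RHS is
    analytic in the states and by central differences otherwise; removable
    ratio singularities are handled through the equilibrium's directional
    evaluation state (flagged in the report).
    """
    params = np.asarray(params, dtype=float)
    res = eq.residual(params)
    if not res <= max(_RES_TOL, 1e-8):
        raise ValueError(
            f"{model_id}: point is not an equilibrium (‖rhs‖∞ = {res:.3g})"
        )
    flags = []
    if eq.directional:
        flags.append("jacobian evaluated via directional limit in the "
                     "nonnegative orthant")
    J = rhs_jacobian_states(model_id, 0.0, eq.eval_state(), params, eq.u)
    eigvals = np.linalg.eigvals(J)
    order = np.argsort(-eigvals.real)
    eigvals = eigvals[order]
    return StabilityReport(
        equilibrium=eq,
        eigenvalues=eigvals,
        classification=classify(eigvals, tol=tol),
        flags=flags,
    )
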