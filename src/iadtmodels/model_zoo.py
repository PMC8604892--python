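"""Catalogue of 13 intermittent androgen-deprivation therapy (IADT) ODE models.

Every model is exposed behind one uniform interface: an ordered state vector
``x`` (cell-compartment concentrations, androgen/cell quotas, PSA — all in
µg/L-equivalent units), an ordered parameter vector ``p`` with per-parameter
bounds and optional inequality constraints, a right-hand side
``f(t, x, p, u)`` forced by the binary treatment control ``u``, and an
observation map returning the serum PSA concentration ``c_PSA`` in µg/L.

Model identifiers follow the field's convention of first-author initial plus
publication year:

========  ===========================================================
id        resistance mechanism / structure
========  ===========================================================
I08A/B    androgen-dependent + independent cells driven by a
          decoupled serum-androgen channel (B keeps the independent
          compartment's net growth free; A pins it to zero)
E10       testosterone / DHT / androgen-receptor binding kinetics
H10       linear three-compartment model with an irreversibly
          androgen-independent population
P12A/B    Droop cell-quota models (A: one shared quota; B: one quota
          per population — A is nested in B)
M14       P12B plus quota-dependent apoptosis
B16A/B    quota models with quadratic (crowding) death terms
          (A: one population; B: two populations)
E16       pharmacodynamic PSA model with dormancy switch and manual
          bounding of diverging channels
Z17       three-species Lotka–Volterra competition with an
          androgen-producing population
P19       B16B plus a weakly androgen-dependent population
B20       stem / differentiated-cell model with PSA relaxation
========  ===========================================================

Right-hand sides of the smooth models accept complex state/parameter values
so Jacobians can be taken by complex-step differentiation; E16 contains
genuine non-smooth primitives (min, ramp) and is flagged ``smooth=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "ModelDefinition",
    "SingularStateError",
    "MODEL_IDS",
    "get_model",
    "rhs",
    "observe",
    "validate_params",
    "default_params",
]

LOG2 = np.log(2.0)


class SingularStateError(ValueError):
    """A model RHS hit a vanishing denominator; carries the offending term."""


def _pos(x):
    """Real part of a possibly complex-step-perturbed number (for guards)."""
    return x.real if np.iscomplexobj(x) else x


# ---------------------------------------------------------------------------
# bounds by unit class, from the editable YAML shipped with the package
# ---------------------------------------------------------------------------

def _load_bound_classes() -> dict[str, tuple[float, float]]:
    text = resources.files(__package__).joinpath("default_bounds.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for cls, spec in raw.items():
        out[cls] = (float(spec["lower"]), float(spec["upper"]))
    return out


_BOUND_CLASSES = _load_bound_classes()


@dataclass(frozen=True)
class ModelDefinition:
    """One IADT model behind the uniform state/parameter/RHS interface."""

    id: str
    state_names: tuple[str, ...]
    state_units: tuple[str, ...]
    params: tuple[tuple[str, str], ...]  # (name, unit-class)
    rhs: Callable  # f(t, x, p, u) -> dx/dt
    observe: Callable  # g(x, p) -> c_PSA
    constraints: tuple[tuple[str, Callable], ...] = ()
    nesting: str | None = None
    smooth: bool = True  # complex-step-safe RHS
    stiff: bool = False  # prefer an implicit solver
    linear_matrix: Callable | None = None  # A(p, u) for linear models
    equations: str = ""
    bound_overrides: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.params)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for name, cls in self.params:
            out.append(self.bound_overrides.get(name, _BOUND_CLASSES[cls]))
        return out

    def pindex(self, name: str) -> int:
        return self.param_names.index(name)

    def pdict(self, p: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.param_names, p))

    def pvector(self, d: dict[str, float]) -> np.ndarray:
        return np.array([d[n] for n in self.param_names], dtype=float)

    def validate(self, p: Sequence[float]) -> list[str]:
        """Return the list of violated bounds/constraints (empty = valid)."""
        p = np.asarray(p, dtype=float)
        if p.shape != (self.n_params,):
            raise ValueError(
                f"{self.id}: expected {self.n_params} parameters, got {p.shape}"
            )
        bad = []
        for val, (name, _), (lo, hi) in zip(p, self.params, self.bounds):
            if not (lo <= val <= hi):
                bad.append(f"{name} outside [{lo}, {hi}]")
        d = self.pdict(p)
        for label, pred in self.constraints:
            if not pred(d):
                bad.append(label)
        return bad

    def manifest(self) -> dict:
        """Machine-readable description for documentation/CLI introspection."""
        return {
            "id": self.id,
            "states": [
                {"name": n, "unit": u}
                for n, u in zip(self.state_names, self.state_units)
            ],
            "parameters": [
                {"name": n, "unit_class": c, "bounds": list(b)}
                for (n, c), b in zip(self.params, self.bounds)
            ],
            "constraints": [label for label, _ in self.constraints],
            "nested_in": self.nesting,
            "smooth": self.smooth,
            "stiff": self.stiff,
            "equations": self.equations,
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=1)


# ---------------------------------------------------------------------------
# I08A / I08B — androgen-driven two-population model
# ---------------------------------------------------------------------------

def _i08_rates(c_A, d, model_b: bool):
    c_A0 = d["c_A0"]
    gamma_D = d["gamma_D_max"] * (
        d["gamma_DA"] + (1.0 - d["gamma_DA"]) * c_A / (c_A + d["k_DA_gamma"])
    )
    delta_D = d["delta_D_max"] * (
        d["delta_DA"] + (1.0 - d["delta_DA"]) * c_A / (c_A + d["k_DA_delta"])
    )
    if model_b:
        gamma_I = 1.0 - (1.0 - d["delta_IA"] / d["gamma_IA"]) * c_A / c_A0
    else:
        gamma_I = 1.0  # delta_IA == gamma_IA pins the AI net growth to zero
    delta_I = 1.0
    mu_DI = d["mu_DI_max"] * (1.0 - c_A / c_A0)
    return gamma_D, delta_D, gamma_I, delta_I, mu_DI


def _rhs_i08(t, x, p, u, names, model_b):
    n_D, n_I, c_A = x
    d = dict(zip(names, p))
    if _pos(d["c_A0"]) == 0:
        raise SingularStateError("I08: homeostatic androgen level c_A0 = 0")
    if model_b and _pos(d["gamma_IA"]) == 0:
        raise SingularStateError("I08B: gamma_IA = 0 in the AI growth ratio")
    for k in ("k_DA_gamma", "k_DA_delta"):
        if _pos(c_A + d[k]) == 0:
            raise SingularStateError(f"I08: vanishing denominator c_A + {k}")
    gamma_D, delta_D, gamma_I, delta_I, mu_DI = _i08_rates(c_A, d, model_b)
    return np.array(
        [
            (gamma_D - delta_D - mu_DI) * n_D,
            mu_DI * n_D + (gamma_I - delta_I) * n_I,
            d["delta_cA"] * (d["c_A0"] - c_A) - d["delta_cA"] * d["c_A0"] * u,
        ]
    )


def _observe_weighted(x, p, names, weights_of):
    d = dict(zip(names, p))
    return sum(d[w] * x[i] for i, w in enumerate(weights_of))


_I08A_PARAMS = (
    ("gamma_D_max", "rate"),
    ("delta_D_max", "rate"),
    ("gamma_DA", "fraction"),
    ("delta_DA", "dimensionless"),
    ("k_DA_gamma", "concentration"),
    ("k_DA_delta", "concentration"),
    ("mu_DI_max", "rate"),
    ("c_A0", "concentration"),
    ("delta_cA", "rate"),
    ("w_D", "dimensionless"),
    ("w_I", "dimensionless"),
)

_I08B_PARAMS = _I08A_PARAMS + (("delta_IA", "rate"), ("gamma_IA", "rate"))


# ---------------------------------------------------------------------------
# E10 — testosterone / DHT / androgen-receptor kinetics
# ---------------------------------------------------------------------------

_E10_PARAMS = (
    ("delta_T", "rate"),
    ("mu_cat", "rate"),
    ("n_5alpha", "concentration"),
    ("k_M", "concentration"),
    ("kappa_TR", "rate"),
    ("delta_TR", "rate"),
    ("gamma_R", "rate"),
    ("delta_R", "rate"),
    ("kappa_DHT", "rate"),
    ("delta_DHT", "rate"),
    ("delta_DHTR", "rate"),
    ("upsilon_S", "flux"),
)


def _rhs_e10(t, x, p, u, names):
    n_T, n_R, n_DHT, q_TR, q_DHTR = x
    d = dict(zip(names, p))
    if _pos(d["k_M"] + n_T) == 0:
        raise SingularStateError("E10: Michaelis denominator k_M + n_T = 0")
    mm = d["mu_cat"] * d["n_5alpha"] / (d["k_M"] + n_T)
    # constant serum-testosterone influx gated off by treatment
    influx = -(u - 1.0) * d["upsilon_S"]
    return np.array(
        [
            n_T * (d["delta_T"] - mm - d["kappa_TR"] * n_R)
            + d["delta_TR"] * q_TR
            + influx,
            n_R * (d["gamma_R"] - d["delta_R"] - d["kappa_DHT"] * n_DHT
                   - d["kappa_TR"] * n_T)
            + d["delta_DHTR"] * q_DHTR
            + d["delta_TR"] * q_TR,
            mm * n_T - n_DHT * (d["delta_DHT"] + d["kappa_DHT"] * n_R)
            + d["delta_DHTR"] * q_DHTR,
            d["kappa_TR"] * n_R * n_T - d["delta_TR"] * q_TR,
            d["kappa_DHT"] * n_DHT * n_R - d["delta_DHTR"] * q_DHTR,
        ]
    )


# ---------------------------------------------------------------------------
# H10 — linear three-compartment model (AD, AI, irreversibly AI)
# ---------------------------------------------------------------------------

_H10_PARAMS = (
    ("gamma_D_on", "signed_rate"),
    ("gamma_D_off", "signed_rate"),
    ("gamma_I_on", "signed_rate"),
    ("gamma_I_off", "signed_rate"),
    ("gamma_Irr_on", "signed_rate"),
    ("gamma_Irr_off", "signed_rate"),
    ("mu_ID", "rate"),
    ("mu_DI", "rate"),
    ("mu_DIrr", "rate"),
    ("mu_IIrr", "rate"),
    ("w_D", "dimensionless"),
    ("w_I", "dimensionless"),
    ("w_Irr", "dimensionless"),
)


def h10_matrix(p: Sequence[float], u: float) -> np.ndarray:
    """System matrix A(u) of the linear H10 model, dx/dt = A(u) x."""
    d = dict(zip([n for n, _ in _H10_PARAMS], p))
    gD = d["gamma_D_off"] + u * (d["gamma_D_on"] - d["gamma_D_off"])
    gI = d["gamma_I_off"] + u * (d["gamma_I_on"] - d["gamma_I_off"])
    gR = d["gamma_Irr_off"] + u * (d["gamma_Irr_on"] - d["gamma_Irr_off"])
    return np.array(
        [
            [gD, d["mu_ID"] * (1.0 - u), 0.0],
            [d["mu_DI"] * u, gI, 0.0],
            [d["mu_DIrr"] * u, d["mu_IIrr"] * u, gR],
        ]
    )


def _rhs_h10(t, x, p, u, names):
    return h10_matrix(p, u) @ np.asarray(x)


# ---------------------------------------------------------------------------
# P12A / P12B — Droop cell-quota models
# ---------------------------------------------------------------------------

def _quota_rhs(q, q_min_i, d, u):
    """Quota dynamics shared by the P12/M14 family (uptake, decay, demand)."""
    denom = (d["q_max"] - q_min_i) * (d["k_q2"] - u + 1.0)
    if _pos(denom) == 0:
        raise SingularStateError("quota uptake denominator (q_max - q_min)(k_q2 + 1 - u) = 0")
    uptake = d["v_max"] * (d["q_max"] - q) * (1.0 - u) / denom
    return uptake - d["delta_q"] * q + d["gamma_max"] * (q_min_i - q)


def _hill2_up(q, k):
    return q * q / (q * q + k * k)


def _hill2_down(q, k):
    return k * k / (q * q + k * k)


def _p12_populations(n_D, n_I, q_D, q_I, q_D_min, q_I_min, d):
    if _pos(q_D) == 0 or _pos(q_I) == 0:
        raise SingularStateError("P12: cell quota q = 0 in Droop growth term")
    mu_DI = d["mu_DI_max"] * _hill2_down(q_D, d["k_DI2"])
    mu_ID = d["mu_ID_max"] * _hill2_up(q_I, d["k_ID2"])
    dn_D = (
        n_D * (-d["delta_D"] - mu_DI + d["gamma_max"] * (1.0 - q_D_min / q_D))
        + mu_ID * n_I
    )
    dn_I = (
        n_I * (-d["delta_I"] - mu_ID + d["gamma_max"] * (1.0 - q_I_min / q_I))
        + mu_DI * n_D
    )
    return dn_D, dn_I


def _p12_psa(n_D, n_I, q_D, q_I, c_PSA, d):
    prod_D = d["gamma_PSA0"] + d["gamma_PSA_D"] * _hill2_up(q_D, d["k_PSA_D2"])
    prod_I = d["gamma_PSA0"] + d["gamma_PSA_I"] * _hill2_up(q_I, d["k_PSA_I2"])
    return n_D * prod_D + n_I * prod_I - d["delta_PSA"] * c_PSA


_P12_COMMON = (
    ("v_max", "concentration"),
    ("q_max", "concentration"),
    ("k_q2", "dimensionless"),
    ("delta_q", "rate"),
    ("gamma_max", "rate"),
    ("mu_DI_max", "rate"),
    ("mu_ID_max", "rate"),
    ("k_DI2", "concentration"),
    ("k_ID2", "concentration"),
    ("delta_D", "rate"),
    ("delta_I", "rate"),
    ("gamma_PSA0", "rate"),
    ("gamma_PSA_D", "rate"),
    ("gamma_PSA_I", "rate"),
    ("k_PSA_D2", "concentration"),
    ("k_PSA_I2", "concentration"),
    ("delta_PSA", "rate"),
)

_P12A_PARAMS = _P12_COMMON + (("q_min", "concentration"),)
_P12B_PARAMS = _P12_COMMON + (
    ("q_D_min", "concentration"),
    ("q_I_min", "concentration"),
)


def _rhs_p12a(t, x, p, u, names):
    n_D, n_I, q, c_PSA = x
    d = dict(zip(names, p))
    dn_D, dn_I = _p12_populations(n_D, n_I, q, q, d["q_min"], d["q_min"], d)
    dq = _quota_rhs(q, d["q_min"], d, u)
    dc = _p12_psa(n_D, n_I, q, q, c_PSA, d)
    return np.array([dn_D, dn_I, dq, dc])


def _rhs_p12b(t, x, p, u, names):
    n_D, n_I, q_D, q_I, c_PSA = x
    d = dict(zip(names, p))
    dn_D, dn_I = _p12_populations(n_D, n_I, q_D, q_I, d["q_D_min"], d["q_I_min"], d)
    dq_D = _quota_rhs(q_D, d["q_D_min"], d, u)
    dq_I = _quota_rhs(q_I, d["q_I_min"], d, u)
    dc = _p12_psa(n_D, n_I, q_D, q_I, c_PSA, d)
    return np.array([dn_D, dn_I, dq_D, dq_I, dc])


# ---------------------------------------------------------------------------
# M14 — P12B plus quota-dependent apoptosis
# ---------------------------------------------------------------------------

_M14_PARAMS = _P12B_PARAMS + (
    ("delta_D_max", "rate"),
    ("delta_I_max", "rate"),
    ("k_D_delta2", "concentration"),
    ("k_I_delta2", "concentration"),
)


def _rhs_m14(t, x, p, u, names):
    n_D, n_I, q_D, q_I, c_PSA = x
    d = dict(zip(names, p))
    dn_D, dn_I = _p12_populations(n_D, n_I, q_D, q_I, d["q_D_min"], d["q_I_min"], d)
    dn_D -= n_D * d["delta_D_max"] * _hill2_down(q_D, d["k_D_delta2"])
    dn_I -= n_I * d["delta_I_max"] * _hill2_down(q_I, d["k_I_delta2"])
    dq_D = _quota_rhs(q_D, d["q_D_min"], d, u)
    dq_I = _quota_rhs(q_I, d["q_I_min"], d, u)
    dc = _p12_psa(n_D, n_I, q_D, q_I, c_PSA, d)
    return np.array([dn_D, dn_I, dq_D, dq_I, dc])


# ---------------------------------------------------------------------------
# B16A / B16B — quota models with crowding death
# ---------------------------------------------------------------------------

_B16A_PARAMS = (
    ("delta", "rate"),
    ("k_n2", "concentration"),
    ("gamma_max", "rate"),
    ("q_min", "concentration"),
    ("q_max", "concentration"),
    ("gamma_1", "rate"),
    ("gamma_2", "rate"),
    ("tau_delta", "rate"),
    ("gamma_PSA0", "rate"),
    ("gamma_PSA1", "rate"),
    ("delta_PSA", "rate"),
)


def _rhs_b16a(t, x, p, u, names):
    n, delta_max, c_PSA, q = x
    d = dict(zip(names, p))
    if _pos(q) == 0:
        raise SingularStateError("B16A: cell quota q = 0 in Droop growth term")
    gamma = d["gamma_1"] * u + d["gamma_2"]
    dn = n * (
        -n * d["delta"]
        - d["k_n2"] * delta_max / (q + d["k_n2"])
        - d["gamma_max"] * d["q_min"] / q
        + d["gamma_max"]
    )
    ddelta = -d["tau_delta"] * delta_max
    dc = q * (d["gamma_PSA1"] * n + d["gamma_PSA0"]) - d["delta_PSA"] * c_PSA
    dq = gamma * (d["q_max"] - q) - d["gamma_max"] * (q - d["q_min"])
    return np.array([dn, ddelta, dc, dq])


_B16B_PARAMS = (
    ("delta_D_max", "rate"),
    ("delta_I_max", "rate"),
    ("k_D2", "concentration"),
    ("k_I2", "concentration"),
    ("k_DI2", "concentration"),
    ("mu_DI_max", "rate"),
    ("gamma_max", "rate"),
    ("q_D_min", "concentration"),
    ("q_I_min", "concentration"),
    ("q_max", "concentration"),
    ("gamma_1", "rate"),
    ("gamma_2", "rate"),
    ("delta_D", "rate"),
    ("delta_I", "rate"),
    ("gamma_PSA0", "rate"),
    ("gamma_PSA1", "rate"),
    ("delta_PSA", "rate"),
)


def _rhs_b16b(t, x, p, u, names):
    n_D, n_I, q, c_PSA = x
    d = dict(zip(names, p))
    if _pos(q) == 0:
        raise SingularStateError("B16B: cell quota q = 0 in Droop growth term")
    tot = n_D + n_I
    if _pos(tot) == 0:
        raise SingularStateError("B16B: population ratio term with n_D + n_I = 0")
    mut = d["k_DI2"] * d["mu_DI_max"] / (q + d["k_DI2"])
    dn_D = (
        n_D * (
            -d["delta_D_max"] * d["k_D2"] / (q + d["k_D2"])
            - mut
            + d["gamma_max"] * (1.0 - d["q_D_min"] / q)
        )
        - d["delta_D"] * n_D * n_D
    )
    dn_I = (
        mut * n_D
        + n_I * (
            d["gamma_max"] * (1.0 - d["q_I_min"] / q)
            - d["delta_I_max"] * d["k_I2"] / (q + d["k_I2"])
        )
        - d["delta_I"] * n_I * n_I
    )
    gamma_in = d["gamma_2"] + d["gamma_1"] * u
    dq = (
        -q * (gamma_in + d["gamma_max"])
        + d["gamma_max"] * (d["q_D_min"] * n_D + d["q_I_min"] * n_I) / tot
        + d["q_max"] * gamma_in
    )
    dc = q * (d["gamma_PSA0"] + d["gamma_PSA1"] * tot) - d["delta_PSA"] * c_PSA
    return np.array([dn_D, dn_I, dq, dc])


# ---------------------------------------------------------------------------
# E16 — pharmacodynamic PSA model with dormancy switch
# ---------------------------------------------------------------------------

_E16_PARAMS = (
    ("gamma_tPSA", "rate"),
    ("gamma_PSA_max", "dimensionless"),
    ("eta_T_PSA", "rate"),
    ("eta_I_T", "dimensionless"),
    ("eta_H_T", "dimensionless"),
    ("gamma_T", "rate"),
    ("delta_T", "rate"),
    ("gamma_TAR", "rate"),
    ("gamma_I", "rate"),
    ("rho_K", "rate"),
    ("sigma_PSA", "fraction"),
    ("c_tPSA", "concentration"),
    ("l_PSA_max", "concentration"),
    ("l_H_max", "concentration"),
    ("l_TAR_max", "concentration"),
    ("l_I_max", "concentration"),
)


def _ramp(x):
    return x * (x > 0.0)


def _bound_hat(f, l_max):
    """Manual bounding (l_max - f)+ / l_max keeping channels from diverging."""
    return _ramp(l_max - f) / l_max


def _rhs_e16(t, x, p, u, names):
    c_PSA, n_T, H, R_TAR, R_I, K, T = x
    d = dict(zip(names, p))
    for nm in ("gamma_PSA_max", "c_tPSA", "l_PSA_max", "l_H_max",
               "l_TAR_max", "l_I_max"):
        if _pos(d[nm]) == 0:
            raise SingularStateError(f"E16: parameter {nm} = 0 in a denominator")
    hat_PSA = _bound_hat(c_PSA, d["l_PSA_max"])
    hat_TAR = _bound_hat(R_TAR, d["l_TAR_max"])
    hat_I = _bound_hat(R_I, d["l_I_max"])
    if c_PSA > d["c_tPSA"]:
        gamma_PSA = 1.0
    else:
        gamma_PSA = d["sigma_PSA"] + (1.0 - d["sigma_PSA"]) * c_PSA / d["c_tPSA"]
    growth = min(gamma_PSA * np.abs(c_PSA) ** K, LOG2 / d["gamma_PSA_max"])
    dc = (
        hat_PSA * d["gamma_tPSA"] * growth
        + d["eta_T_PSA"] * _ramp(c_PSA - d["c_tPSA"] / 2.0)
        * (d["eta_I_T"] * R_I * hat_PSA + n_T - 1.0)
    )
    dn_T = d["gamma_T"] * (1.0 - u) / (d["eta_H_T"] * H + 1.0) - d["gamma_T"] * n_T
    e_TAR = np.exp(R_TAR)
    dH = T - d["delta_T"] * d["l_H_max"] * H * e_TAR / (e_TAR + d["l_H_max"])
    dR_TAR = d["gamma_TAR"] * T * hat_TAR
    dR_I = d["gamma_I"] * T * hat_I
    dK = -d["rho_K"]
    dT = -d["delta_T"] * T
    return np.array([dc, dn_T, dH, dR_TAR, dR_I, dK, dT])


# ---------------------------------------------------------------------------
# Z17 — Lotka–Volterra competition with androgen-producing cells
# ---------------------------------------------------------------------------

_Z17_PARAMS = (
    ("gamma_D", "rate"),
    ("gamma_P", "rate"),
    ("gamma_I", "rate"),
    ("K_P", "concentration"),
    ("K_I", "concentration"),
    ("beta", "dimensionless"),
    ("delta", "rate"),
    ("alpha_12", "fraction"),
    ("alpha_13", "fraction"),
    ("alpha_21", "fraction"),
    ("alpha_23", "fraction"),
    ("alpha_31", "fraction"),
    ("alpha_32", "fraction"),
)

_Z17_CONSTRAINTS = (
    ("alpha_31 > alpha_21", lambda d: d["alpha_31"] > d["alpha_21"]),
    ("alpha_32 > alpha_12", lambda d: d["alpha_32"] > d["alpha_12"]),
    ("alpha_13 > alpha_23", lambda d: d["alpha_13"] > d["alpha_23"]),
    ("alpha_13 > alpha_21", lambda d: d["alpha_13"] > d["alpha_21"]),
    ("alpha_32 > alpha_31", lambda d: d["alpha_32"] > d["alpha_31"]),
    (
        "off-diagonal alpha_ij in ]0,1[",
        lambda d: all(
            0.0 < d[k] < 1.0
            for k in ("alpha_12", "alpha_13", "alpha_21",
                      "alpha_23", "alpha_31", "alpha_32")
        ),
    ),
)


def _rhs_z17(t, x, p, u, names):
    n_D, n_P, n_I, c_PSA = x
    d = dict(zip(names, p))
    cap_D = n_P * (d["beta"] - u + 1.0)
    if _pos(cap_D) == 0:
        raise SingularStateError("Z17: carrying capacity n_P (beta - u + 1) = 0")
    if _pos(d["K_P"]) == 0 or _pos(d["K_I"]) == 0:
        raise SingularStateError("Z17: carrying capacity K_P or K_I = 0")
    dn_D = d["gamma_D"] * n_D * (
        1.0 - (n_D + d["alpha_12"] * n_P + d["alpha_13"] * n_I) / cap_D
    )
    dn_P = d["gamma_P"] * n_P * (
        1.0 - (d["alpha_21"] * n_D + n_P + d["alpha_23"] * n_I) / d["K_P"]
    )
    dn_I = d["gamma_I"] * n_I * (
        1.0 - (d["alpha_31"] * n_D + d["alpha_32"] * n_P + n_I) / d["K_I"]
    )
    dc = n_D + n_P + n_I - d["delta"] * c_PSA
    return np.array([dn_D, dn_P, dn_I, dc])


# ---------------------------------------------------------------------------
# P19 — three-population quota model
# ---------------------------------------------------------------------------

_P19_PARAMS = (
    ("delta_D_max", "rate"),
    ("delta_wD_max", "rate"),
    ("delta_I_max", "rate"),
    ("k_D2", "concentration"),
    ("k_wD2", "concentration"),
    ("k_I2", "concentration"),
    ("k_DI2", "concentration"),
    ("mu_DI_max", "rate"),
    ("gamma_max", "rate"),
    ("q_D_min", "concentration"),
    ("q_wD_min", "concentration"),
    ("q_I_min", "concentration"),
    ("q_max", "concentration"),
    ("gamma_1", "rate"),
    ("gamma_2", "rate"),
    ("delta_D", "rate"),
    ("delta_wD", "rate"),
    ("delta_I", "rate"),
    ("gamma_PSA0", "rate"),
    ("gamma_PSA1", "rate"),
    ("delta_PSA", "rate"),
)


def _rhs_p19(t, x, p, u, names):
    n_D, n_wD, n_I, q, c_PSA = x
    d = dict(zip(names, p))
    if _pos(q) == 0:
        raise SingularStateError("P19: cell quota q = 0 in Droop growth term")
    tot = n_D + n_wD + n_I
    if _pos(tot) == 0:
        raise SingularStateError("P19: population ratio term with n_D + n_wD + n_I = 0")
    mut = d["k_DI2"] * d["mu_DI_max"] / (q + d["k_DI2"])
    dn_D = (
        n_D * (
            -d["delta_D_max"] * d["k_D2"] / (q + d["k_D2"])
            - 2.0 * mut
            + d["gamma_max"] * (1.0 - d["q_D_min"] / q)
        )
        + mut * n_wD
        - d["delta_D"] * n_D * n_D
    )
    dn_wD = (
        n_wD * (
            -2.0 * mut
            - d["delta_wD_max"] * d["k_wD2"] / (q + d["k_wD2"])
            + d["gamma_max"] * (1.0 - d["q_wD_min"] / q)
        )
        + mut * n_D
        - d["delta_wD"] * n_wD * n_wD
    )
    dn_I = (
        mut * (n_D + n_wD)
        + n_I * (
            d["gamma_max"] * (1.0 - d["q_I_min"] / q)
            - d["delta_I_max"] * d["k_I2"] / (q + d["k_I2"])
        )
        - d["delta_I"] * n_I * n_I
    )
    gamma_in = d["gamma_2"] + d["gamma_1"] * u
    dq = (
        -q * (gamma_in + d["gamma_max"])
        + d["gamma_max"]
        * (d["q_D_min"] * n_D + d["q_I_min"] * n_I + d["q_wD_min"] * n_wD) / tot
        + d["q_max"] * gamma_in
    )
    dc = q * (d["gamma_PSA0"] + d["gamma_PSA1"] * tot) - d["delta_PSA"] * c_PSA
    return np.array([dn_D, dn_wD, dn_I, dq, dc])


# ---------------------------------------------------------------------------
# B20 — stem-cell / differentiated-cell model
# ---------------------------------------------------------------------------

_B20_PARAMS = (
    ("p_S", "fraction"),
    ("delta_D", "rate"),
    ("gamma_PSA", "rate"),
    ("delta_PSA", "rate"),
)


def _rhs_b20(t, x, p, u, names):
    n_S, n_D, c_PSA = x
    d = dict(zip(names, p))
    tot = n_D + n_S
    if _pos(tot) == 0:
        raise SingularStateError("B20: self-renewal ratio with n_D + n_S = 0")
    frac = n_S / tot
    return np.array(
        [
            d["p_S"] * LOG2 * n_S * frac,
            LOG2 * n_S * (1.0 - d["p_S"] * frac) - d["delta_D"] * u * n_D,
            d["gamma_PSA"] * n_D - d["delta_PSA"] * c_PSA,
        ]
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _state_obs(index):
    def _obs(x, p):
        return x[index]
    return _obs


_REGISTRY: dict[str, ModelDefinition] = {}


def _register(md: ModelDefinition) -> None:
    _REGISTRY[md.id] = md


_register(ModelDefinition(
    id="I08A",
    state_names=("n_D", "n_I", "c_A"),
    state_units=("ug/L", "ug/L", "ug/L"),
    params=_I08A_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _I08A_PARAMS]:
        _rhs_i08(t, x, p, u, _n, model_b=False),
    observe=lambda x, p, _n=[n for n, _ in _I08A_PARAMS]:
        _observe_weighted(x, p, _n, ("w_D", "w_I")),
    equations="androgen-driven two-population model, constrained variant",
))

_register(ModelDefinition(
    id="I08B",
    state_names=("n_D", "n_I", "c_A"),
    state_units=("ug/L", "ug/L", "ug/L"),
    params=_I08B_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _I08B_PARAMS]:
        _rhs_i08(t, x, p, u, _n, model_b=True),
    observe=lambda x, p, _n=[n for n, _ in _I08B_PARAMS]:
        _observe_weighted(x, p, _n, ("w_D", "w_I")),
    equations="androgen-driven two-population model, free AI net growth",
))

_register(ModelDefinition(
    id="E10",
    state_names=("n_T", "n_R", "n_DHT", "q_TR", "q_DHTR"),
    state_units=("ug/L",) * 5,
    params=_E10_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _E10_PARAMS]:
        _rhs_e10(t, x, p, u, _n),
    # PSA proxy: no state is PSA itself; testosterone n_T is the default
    # proxy, overridable via observe_state in higher-level configs.
    observe=_state_obs(0),
    equations="testosterone/DHT/androgen-receptor binding kinetics",
))

_register(ModelDefinition(
    id="H10",
    state_names=("n_D", "n_I", "n_Irr"),
    state_units=("ug/L",) * 3,
    params=_H10_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _H10_PARAMS]:
        _rhs_h10(t, x, p, u, _n),
    observe=lambda x, p, _n=[n for n, _ in _H10_PARAMS]:
        _observe_weighted(x, p, _n, ("w_D", "w_I", "w_Irr")),
    linear_matrix=h10_matrix,
    equations="linear three-compartment model with irreversible AI pool",
))

_register(ModelDefinition(
    id="P12A",
    state_names=("n_D", "n_I", "q", "c_PSA"),
    state_units=("ug/L",) * 4,
    params=_P12A_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _P12A_PARAMS]:
        _rhs_p12a(t, x, p, u, _n),
    observe=_state_obs(3),
    constraints=(
        ("q_min < q_max", lambda d: d["q_min"] < d["q_max"]),
    ),
    stiff=False,
    equations="shared-quota Droop model",
))

_register(ModelDefinition(
    id="P12B",
    state_names=("n_D", "n_I", "q_D", "q_I", "c_PSA"),
    state_units=("ug/L",) * 5,
    params=_P12B_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _P12B_PARAMS]:
        _rhs_p12b(t, x, p, u, _n),
    observe=_state_obs(4),
    constraints=(
        ("q_I_min < q_D_min", lambda d: d["q_I_min"] < d["q_D_min"]),
        ("q_D_min < q_max", lambda d: d["q_D_min"] < d["q_max"]),
    ),
    nesting=None,  # parent of P12A (P12A arises from q_D ≡ q_I, shared minima)
    stiff=True,
    equations="per-population-quota Droop model; P12A nested inside",
))

_register(ModelDefinition(
    id="M14",
    state_names=("n_D", "n_I", "q_D", "q_I", "c_PSA"),
    state_units=("ug/L",) * 5,
    params=_M14_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _M14_PARAMS]:
        _rhs_m14(t, x, p, u, _n),
    observe=_state_obs(4),
    constraints=(
        ("q_I_min < q_D_min", lambda d: d["q_I_min"] < d["q_D_min"]),
        ("q_D_min < q_max", lambda d: d["q_D_min"] < d["q_max"]),
    ),
    nesting="P12B",
    stiff=True,
    equations="P12B plus quota-dependent ADT-induced apoptosis",
))

_register(ModelDefinition(
    id="B16A",
    state_names=("n", "delta_max", "c_PSA", "q"),
    state_units=("ug/L", "1/day", "ug/L", "ug/L"),
    params=_B16A_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _B16A_PARAMS]:
        _rhs_b16a(t, x, p, u, _n),
    observe=_state_obs(2),
    constraints=(
        ("q_min < q_max", lambda d: d["q_min"] < d["q_max"]),
    ),
    equations="single-population quota model with decaying max death rate",
))

_register(ModelDefinition(
    id="B16B",
    state_names=("n_D", "n_I", "q", "c_PSA"),
    state_units=("ug/L",) * 4,
    params=_B16B_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _B16B_PARAMS]:
        _rhs_b16b(t, x, p, u, _n),
    observe=_state_obs(3),
    constraints=(
        ("q_I_min < q_D_min", lambda d: d["q_I_min"] < d["q_D_min"]),
        ("delta_D_max > delta_I_max", lambda d: d["delta_D_max"] > d["delta_I_max"]),
        ("q_D_min < q_max", lambda d: d["q_D_min"] < d["q_max"]),
    ),
    equations="two-population quota model with crowding death terms",
))

_register(ModelDefinition(
    id="E16",
    state_names=("c_PSA", "n_T", "H", "R_TAR", "R_I", "K", "T"),
    state_units=("ug/L", "-", "ug/L", "-", "-", "-", "ug/L"),
    params=_E16_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _E16_PARAMS]:
        _rhs_e16(t, x, p, u, _n),
    observe=_state_obs(0),
    smooth=False,
    stiff=True,
    equations="pharmacodynamic PSA model with dormancy switch and bounded channels",
))

_register(ModelDefinition(
    id="Z17",
    state_names=("n_D", "n_P", "n_I", "c_PSA"),
    state_units=("ug/L",) * 4,
    params=_Z17_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _Z17_PARAMS]:
        _rhs_z17(t, x, p, u, _n),
    observe=_state_obs(3),
    constraints=_Z17_CONSTRAINTS,
    equations="three-species Lotka-Volterra competition with androgen producers",
))

_register(ModelDefinition(
    id="P19",
    state_names=("n_D", "n_wD", "n_I", "q", "c_PSA"),
    state_units=("ug/L",) * 5,
    params=_P19_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _P19_PARAMS]:
        _rhs_p19(t, x, p, u, _n),
    observe=_state_obs(4),
    constraints=(
        ("q_D_min > q_wD_min", lambda d: d["q_D_min"] > d["q_wD_min"]),
        ("q_D_min > q_I_min", lambda d: d["q_D_min"] > d["q_I_min"]),
        ("q_D_min < q_max", lambda d: d["q_D_min"] < d["q_max"]),
    ),
    equations="three-population quota model with weakly dependent cells",
))

_register(ModelDefinition(
    id="B20",
    state_names=("n_S", "n_D", "c_PSA"),
    state_units=("ug/L",) * 3,
    params=_B20_PARAMS,
    rhs=lambda t, x, p, u, _n=[n for n, _ in _B20_PARAMS]:
        _rhs_b20(t, x, p, u, _n),
    observe=_state_obs(2),
    equations="stem/differentiated-cell model with PSA relaxation",
))


MODEL_IDS: tuple[str, ...] = tuple(_REGISTRY)


def get_model(model_id: str) -> ModelDefinition:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; known: {', '.join(MODEL_IDS)}"
        ) from None


# functional facade ---------------------------------------------------------

def rhs(model_id: str, t: float, state, params, u) -> np.ndarray:
    """Time derivative of every state of ``model_id`` at control value ``u``."""
    return get_model(model_id).rhs(t, np.asarray(state), np.asarray(params), u)


def observe(model_id: str, state, params):
    """PSA observation map: c_PSA (µg/L) as a function of the state."""
    return get_model(model_id).observe(np.asarray(state), np.asarray(params))


def validate_params(model_id: str, params) -> list[str]:
    """List of violated bounds/inequality constraints; empty means valid."""
    return get_model(model_id).validate(params)


# ---------------------------------------------------------------------------
# reference parameter values — physiologically plausible defaults used by
# examples, the synthetic-data generator and the test fixtures
# ---------------------------------------------------------------------------

_DEFAULTS: dict[str, dict[str, float]] = {
    "I08A": dict(
        gamma_D_max=0.35, delta_D_max=0.45, gamma_DA=0.2, delta_DA=1.8,
        k_DA_gamma=2.0, k_DA_delta=0.5, mu_DI_max=0.005, c_A0=12.0,
        delta_cA=0.08, w_D=1.0, w_I=1.0,
    ),
    "E10": dict(
        delta_T=0.05, mu_cat=1.0, n_5alpha=1.0, k_M=10.0, kappa_TR=0.02,
        delta_TR=0.05, gamma_R=0.1, delta_R=0.08, kappa_DHT=0.02,
        delta_DHT=0.06, delta_DHTR=0.05, upsilon_S=1.0,
    ),
    "H10": dict(
        gamma_D_on=-0.024, gamma_D_off=0.021, gamma_I_on=-0.0025,
        gamma_I_off=0.0, gamma_Irr_on=0.001, gamma_Irr_off=0.001,
        mu_ID=6e-5, mu_DI=6e-5, mu_DIrr=5e-5, mu_IIrr=5e-5,
        w_D=1.0, w_I=1.0, w_Irr=1.0,
    ),
    "P12A": dict(
        v_max=0.275, q_max=5.0, k_q2=0.6, delta_q=0.02, gamma_max=0.025,
        mu_DI_max=0.0001, mu_ID_max=0.00015, k_DI2=1.7, k_ID2=1.7,
        delta_D=0.008, delta_I=0.008, gamma_PSA0=0.004, gamma_PSA_D=0.05,
        gamma_PSA_I=0.05, k_PSA_D2=1.7, k_PSA_I2=1.7, delta_PSA=0.08,
        q_min=0.4,
    ),
    "B16A": dict(
        delta=0.009, k_n2=0.8, gamma_max=0.035, q_min=0.4, q_max=5.0,
        gamma_1=0.5, gamma_2=0.02, tau_delta=0.01, gamma_PSA0=0.005,
        gamma_PSA1=0.06, delta_PSA=0.08,
    ),
    "B16B": dict(
        delta_D_max=0.04, delta_I_max=0.01, k_D2=0.8, k_I2=0.8, k_DI2=1.0,
        mu_DI_max=0.0002, gamma_max=0.035, q_D_min=0.6, q_I_min=0.2,
        q_max=5.0, gamma_1=0.5, gamma_2=0.02, delta_D=0.002, delta_I=0.002,
        gamma_PSA0=0.005, gamma_PSA1=0.06, delta_PSA=0.08,
    ),
    "E16": dict(
        gamma_tPSA=0.03, gamma_PSA_max=1.0, eta_T_PSA=0.02, eta_I_T=0.5,
        eta_H_T=1.0, gamma_T=0.08, delta_T=0.05, gamma_TAR=0.002,
        gamma_I=0.002, rho_K=0.0005, sigma_PSA=0.3, c_tPSA=4.0,
        l_PSA_max=200.0, l_H_max=50.0, l_TAR_max=20.0, l_I_max=20.0,
    ),
    "Z17": dict(
        gamma_D=0.03, gamma_P=0.03, gamma_I=0.02, K_P=10.0, K_I=8.0,
        beta=0.9, delta=0.08, alpha_12=0.4, alpha_13=0.8, alpha_21=0.3,
        alpha_23=0.5, alpha_31=0.5, alpha_32=0.7,
    ),
    "B20": dict(p_S=0.2, delta_D=0.06, gamma_PSA=0.1, delta_PSA=0.12),
}
_DEFAULTS["I08B"] = {**_DEFAULTS["I08A"], "delta_IA": 0.9, "gamma_IA": 1.0}
_DEFAULTS["P12B"] = {
    **{k: v for k, v in _DEFAULTS["P12A"].items() if k != "q_min"},
    "q_D_min": 0.6, "q_I_min": 0.2,
}
_DEFAULTS["M14"] = {
    **_DEFAULTS["P12B"], "delta_D_max": 0.03, "delta_I_max": 0.01,
    "k_D_delta2": 0.8, "k_I_delta2": 0.8,
}
_DEFAULTS["P19"] = dict(
    delta_D_max=0.04, delta_wD_max=0.025, delta_I_max=0.01,
    k_D2=0.8, k_wD2=0.8, k_I2=0.8, k_DI2=1.0, mu_DI_max=0.0002,
    gamma_max=0.035, q_D_min=0.6, q_wD_min=0.4, q_I_min=0.2, q_max=5.0,
    gamma_1=0.5, gamma_2=0.02, delta_D=0.002, delta_wD=0.002,
    delta_I=0.002, gamma_PSA0=0.005, gamma_PSA1=0.06, delta_PSA=0.08,
)


def default_params(model_id: str) -> np.ndarray:
    """Reference parameter vector (plausible magnitudes, all constraints met)."""
    md = get_model(model_id)
    vec = md.pvector(_DEFAULTS[model_id])
    bad = md.validate(vec)
    if bad:  # pragma: no cover - guards the shipped defaults
        raise AssertionError(f"default parameters for {model_id} invalid: {bad}")
    return vec
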