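"""Forward (direct differential method) parameter sensitivities.

The sensitivity S_ij(t) = ∂x_i(t; p̂)/∂p_j of a model trajectory obeys the
variational ODE

    dS_ij/dt = Σ_k (∂f_i/∂x_k) S_kj + ∂f_i/∂p_j,

integrated together with the states.  Sensitivities with respect to an
initial condition use the same equation with ∂f/∂p ≡ 0 and a canonical-basis
initial S; dynamical parameters start from S = 0.  The PSA sensitivity
follows by the chain rule through the observation map.

Across treatment switches S is carried continuously: the switch times are
data, not parameters, so no jump terms arise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_zoo import get_model
from .numdiff import _jac, rhs_jacobian_params, rhs_jacobian_states
from .schedule import TreatmentSchedule
from .simulator import SimulationError, _default_method

__all__ = ["SensitivityTrajectory", "ddm"]


@dataclass
class SensitivityTrajectory:
    model_id: str
    times: np.ndarray            # days
    states: np.ndarray           # (n_states, T)
    S: np.ndarray                # (n_states, n_wrt, T), state-units / param-unit
    psa_S: np.ndarray            # (n_wrt, T): ∂c_PSA/∂p_j
    wrt: tuple[str, ...]
    params_hat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        md = get_model(self.model_id)
        rows = []
        for j, pname in enumerate(self.wrt):
            for i, sname in enumerate(md.state_names):
                rows.append(pd.DataFrame({
                    "time_days": self.times, "state": sname,
                    "parameter": pname, "S": self.S[i, j],
                }))
            rows.append(pd.DataFrame({
                "time_days": self.times, "state": "c_PSA_obs",
                "parameter": pname, "S": self.psa_S[j],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _split_wrt(md, wrt):
    """Partition requested names into dynamical parameters and i.c. entries."""
    dyn_idx, ic_idx, order = [], [], []
    for name in wrt:
        if name in md.param_names:
            order.append(("p", len(dyn_idx)))
            dyn_idx.append(md.pindex(name))
        elif name.endswith("0") and name[:-1] in md.state_names:
            order.append(("x0", len(ic_idx)))
            ic_idx.append(md.state_names.index(name[:-1]))
        else:
            raise ValueError(
                f"{md.id}: {name!r} is neither a parameter nor an initial "
                f"condition ('<state>0')"
            )
    return dyn_idx, ic_idx, order


def ddm(
    model_id: str,
    params_hat,
    init_state,
    schedule: TreatmentSchedule,
    t_eval,
    wrt=None,
    solver_opts: dict | None = None,
) -> SensitivityTrajectory:
    """Integrate the augmented state+sensitivity system piecewise.

    ``wrt`` lists parameter names and/or initial-condition names (state name
    suffixed with "0"); by default all model parameters.
    """
    md = get_model(model_id)
    params = np.asarray(params_hat, dtype=float)
    bad = md.validate(params)
    if bad:
        raise ValueError(f"{model_id}: invalid parameters: {bad}")
    if wrt is None:
        wrt = md.param_names
    wrt = tuple(wrt)
    dyn_idx, ic_idx, order = _split_wrt(md, wrt)
    n, m = md.n_states, len(wrt)

    x0 = np.asarray(init_state, dtype=float)
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")

    # flag parameters the RHS provably ignores (zero column at the start)
    if dyn_idx:
        Jp0 = rhs_jacobian_params(model_id, t_eval[0], x0, params, 1, wrt=dyn_idx)
        for col, pi in enumerate(dyn_idx):
            if np.allclose(Jp0[:, col], 0.0):
                warnings.warn(
                    f"{model_id}: RHS may not reference parameter "
                    f"{md.param_names[pi]!r}; its state sensitivity can be "
                    "identically zero",
                    RuntimeWarning, stacklevel=2,
                )

    S0 = np.zeros((n, m))
    for j, (kind, local) in enumerate(order):
        if kind == "x0":
            S0[ic_idx[local], j] = 1.0

    opts = dict(solver_opts or {})
    method = opts.pop("method", _default_method(model_id))
    rtol = opts.pop("rtol", 1e-8)
    atol = opts.pop("atol", 1e-10)

    dyn_cols = [j for j, (kind, _) in enumerate(order) if kind == "p"]

    def aug(t, y, u):
        x = y[:n]
        S = y[n:].reshape(n, m)
        fx = md.rhs(t, x, params, u)
        Jx = rhs_jacobian_states(model_id, t, x, params, u)
        dS = Jx @ S
        if dyn_cols:
            dS[:, dyn_cols] += rhs_jacobian_params(
                model_id, t, x, params, u, wrt=dyn_idx
            )
        return np.concatenate((fx, dS.ravel()))

    t0, t_end = float(t_eval[0]), float(t_eval[-1])
    switches = schedule.switch_times()
    switches = switches[(switches > t0) & (switches < t_end)]
    knots = np.concatenate(([t0], switches, [t_end]))

    y = np.concatenate((x0, S0.ravel()))
    out = np.empty((n + n * m, t_eval.size))
    filled = 0
    for a, b in zip(knots[:-1], knots[1:]):
        u = schedule.indicator(a)
        mask = (t_eval >= a) & ((t_eval < b) if b != t_end else (t_eval <= b))
        seg_eval = t_eval[mask]
        pts = seg_eval if seg_eval.size and seg_eval[-1] == b else np.concatenate(
            (seg_eval, [b]))
        sol = solve_ivp(aug, (a, b), y, method=method, t_eval=pts,
                        rtol=rtol, atol=atol, args=(u,), **opts)
        if not sol.success:
            raise SimulationError(
                f"{model_id}: sensitivity integration failed in [{a}, {b}]: "
                f"{sol.message}",
                last_good_time=float(sol.t[-1]) if sol.t.size else a,
            )
        if seg_eval.size:
            out[:, filled:filled + seg_eval.size] = sol.y[:, :seg_eval.size]
            filled += seg_eval.size
        y = sol.y[:, -1]

    states = out[:n]
    S = out[n:].reshape(n, m, t_eval.size)

    # chain rule through the observation map: dc/dp = g_x·S + g_p
    psa_S = np.empty((m, t_eval.size))
    for k in range(t_eval.size):
        xk = states[:, k]
        g_x = _jac(lambda x: np.atleast_1d(md.observe(x, params)), xk, md.smooth)[0]
        psa_S[:, k] = g_x @ S[:, :, k]
        if dyn_cols:
            g_p = _jac(lambda p: np.atleast_1d(md.observe(xk, p)), params,
                       md.smooth)[0]
            psa_S[dyn_cols, k] += g_p[dyn_idx]

    return SensitivityTrajectory(
        model_id=model_id, times=t_eval, states=states, S=S, psa_S=psa_S,
        wrt=wrt, params_hat=params,
    )
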