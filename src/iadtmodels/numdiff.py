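"""High-accuracy Jacobians of model right-hand sides.

Smooth (complex-analytic) RHS functions get complex-step differentiation,
which is exact to machine precision; models with non-smooth primitives
(min, ramp, piecewise switches) fall back to central differences.
"""

from __future__ import annotations

import numpy as np

from .model_zoo import get_model

__all__ = ["rhs_jacobian_states", "rhs_jacobian_params"]

_CSTEP = 1e-30
_FDSTEP = 1e-7


def _jac(f, z0, smooth: bool) -> np.ndarray:
    """d f / d z at z0 for vector-valued f, columns over components of z0."""
    z0 = np.asarray(z0, dtype=float)
    n_out = np.asarray(f(z0)).size
    J = np.empty((n_out, z0.size))
    if smooth:
        for k in range(z0.size):
            z = z0.astype(complex)
            z[k] += 1j * _CSTEP
            J[:, k] = np.imag(f(z)) / _CSTEP
    else:
        for k in range(z0.size):
            h = _FDSTEP * max(1.0, abs(z0[k]))
            zp, zm = z0.copy(), z0.copy()
            zp[k] += h
            zm[k] -= h
            J[:, k] = (np.asarray(f(zp)) - np.asarray(f(zm))) / (2.0 * h)
    return J


def rhs_jacobian_states(model_id: str, t, state, params, u) -> np.ndarray:
    """∂f/∂x of the model RHS at fixed parameters and control."""
    md = get_model(model_id)
    params = np.asarray(params, dtype=float)
    return _jac(lambda x: md.rhs(t, x, params, u), state, md.smooth)


def rhs_jacobian_params(model_id: str, t, state, params, u,
                        wrt: list[int] | None = None) -> np.ndarray:
    """∂f/∂p of the model RHS; columns restricted to indices ``wrt``."""
    md = get_model(model_id)
    state = np.asarray(state, dtype=float)
    full = _jac(lambda p: md.rhs(t, state, p, u), params, md.smooth)
    return full if wrt is None else full[:, wrt]
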