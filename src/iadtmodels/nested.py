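"""Nested sampling for Bayesian evidence with a quantified error.

A classic single-ellipsoid-free implementation of the nested-sampling
scheme: ``nlive`` live points are drawn from the prior (through its
unit-cube transform), the worst point is repeatedly retired — contributing
prior mass × likelihood to the evidence accumulator — and replaced by a
likelihood-constrained random walk started from a surviving live point.

The evidence estimate is logZ = logsumexp(log w_i + log L_i) over retired
points plus the final live set; its statistical uncertainty is the standard
information-based estimate sqrt(H / nlive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["NestedResult", "nested_sampling"]


@dataclass
class NestedResult:
    log_evidence: float
    log_evidence_err: float
    information: float            # H, nats
    n_iterations: int
    n_calls: int
    samples: np.ndarray           # retired + final live points (parameter space)
    log_weights: np.ndarray       # normalized posterior log-weights
    log_likelihoods: np.ndarray
    termination: str


def _walk(u0, logl0, loglstar, loglik_unit, rng, scale, n_steps):
    """Metropolis random walk within the hard-likelihood constraint L > L*."""
    u, logl = u0.copy(), logl0
    n_accept = 0
    for _ in range(n_steps):
        prop = u + scale * rng.standard_normal(u.size)
        # reflect into the unit cube
        prop = np.abs(prop)
        prop = np.where(prop > 1.0, 2.0 - prop, prop)
        if np.any((prop <= 0.0) | (prop >= 1.0)):
            continue
        logl_prop = loglik_unit(prop)
        if logl_prop > loglstar:
            u, logl = prop, logl_prop
            n_accept += 1
    return u, logl, n_accept


def nested_sampling(
    loglik_unit,
    ndim: int,
    nlive: int = 400,
    seed: int = 0,
    dlogz: float = 0.05,
    n_steps: int = 25,
    max_iter: int = 200_000,
) -> NestedResult:
    """Estimate log ∫ L dU over the unit cube (U = prior measure).

    ``loglik_unit`` maps a point of the unit cube (the prior's quantile
    coordinates) to the log-likelihood.  Reproducible for a fixed seed.
    Termination: the remaining prior volume's maximal possible contribution
    drops below ``dlogz`` nats, or a likelihood plateau stalls the walker
    (reported, not swallowed).
    """
    if nlive < 50:
        raise ValueError("nlive must be >= 50 for a usable error estimate")
    rng = np.random.default_rng(seed)
    u_live = rng.random((nlive, ndim))
    logl_live = np.array([loglik_unit(u) for u in u_live])
    n_calls = nlive

    log_dead_w: list[float] = []    # log prior-mass widths of retired shells
    logl_dead: list[float] = []
    dead_points: list[np.ndarray] = []

    logz = -np.inf
    log_x = 0.0                      # log of remaining prior volume
    shrink = 1.0 / nlive             # E[log shrinkage] per iteration
    scale = 0.1
    termination = "dlogz"
    stalls = 0

    it = 0
    for it in range(1, max_iter + 1):
        worst = int(np.argmin(logl_live))
        loglstar = logl_live[worst]
        log_w = log_x + np.log1p(-np.exp(-shrink))
        log_dead_w.append(log_w)
        logl_dead.append(loglstar)
        dead_points.append(u_live[worst].copy())
        logz = np.logaddexp(logz, log_w + loglstar)
        log_x -= shrink

        # replacement: walk from a random surviving live point
        choices = [i for i in range(nlive) if i != worst]
        start = int(rng.choice(choices))
        u_new, logl_new, n_acc = _walk(
            u_live[start], logl_live[start], loglstar, loglik_unit, rng,
            scale, n_steps,
        )
        n_calls += n_steps
        # adapt the step size toward ~50% acceptance
        frac = n_acc / n_steps
        scale *= np.exp((frac - 0.5) / 10.0)
        scale = float(np.clip(scale, 1e-5, 1.0))
        if n_acc == 0:
            stalls += 1
            if stalls > 50:
                termination = (
                    "likelihood plateau: constrained walker stalled for 50 "
                    "consecutive iterations"
                )
                break
        else:
            stalls = 0
        u_live[worst] = u_new
        logl_live[worst] = logl_new

        if np.max(logl_live) + log_x - logz < dlogz:
            break
    else:
        termination = f"max_iter = {max_iter} reached"

    # final live points: each carries an equal share of the leftover volume
    log_w_live = log_x - np.log(nlive)
    for i in range(nlive):
        log_dead_w.append(log_w_live)
        logl_dead.append(logl_live[i])
        dead_points.append(u_live[i].copy())
        logz = np.logaddexp(logz, log_w_live + logl_live[i])

    log_w = np.asarray(log_dead_w)
    logl = np.asarray(logl_dead)
    log_post = log_w + logl - logz
    with np.errstate(under="ignore"):
        post = np.exp(log_post)
    finite = logl > -np.inf
    h = float(np.sum(post[finite] * logl[finite]) - logz)
    h = max(h, 0.0)
    err = float(np.sqrt(h / nlive))
    return NestedResult(
        log_evidence=float(logz),
        log_evidence_err=err,
        information=h,
        n_iterations=it,
        n_calls=n_calls,
        samples=np.asarray(dead_points),
        log_weights=log_post,
        log_likelihoods=logl,
        termination=termination,
    )
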