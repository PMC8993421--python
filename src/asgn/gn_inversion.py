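"""Gauss-Newton direction and the fixed-packet stochastic GN loop.

The (stochastic) Gauss-Newton direction delta solves the regularized
normal equations

    (J^T Gamma_e^{-1} J + Gamma_mu^{-1}) delta
        = J^T Gamma_e^{-1} (H_data - H_pred - eta_e)
          - Gamma_mu^{-1} (mu_a - eta_mu),

where J and H_pred come from a Monte Carlo simulation with P photon
packets.  Updates use a unit step, mu <- mu + delta.  The S-SGN loop
re-simulates with a fresh RNG stream and a fixed P on every iteration;
the adaptive variant lives in :mod:`asgn.adaptive_norm_test`.

The prior precision makes the system symmetric positive definite, so a
dense Cholesky factorization is used (meshes at desk scale keep N below
a few thousand).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .forward import DataModel
from .prior_bayes import PriorModel, objective

__all__ = [
    "GnIterate",
    "gn_direction",
    "run_ssgn",
    "convergence_check",
    "history_to_frame",
]

logger = logging.getLogger("asgn")


@dataclass
class GnIterate:
    """One recorded Gauss-Newton iteration (unit step, alpha = 1)."""

    i: int
    mu_a: np.ndarray  # estimate AFTER this iteration's step
    P_i: int
    delta: np.ndarray
    u_value: float
    alpha: float = 1.0
    rel_error: float | None = None
    cumulative_packets: int = 0
    wall_time_s: float = 0.0
    extra: dict = field(default_factory=dict)


def gn_direction(
    J: np.ndarray,
    H_pred: np.ndarray,
    data_model: DataModel,
    prior: PriorModel,
    mu_a: np.ndarray,
) -> np.ndarray:
    """Solve the SPD Gauss-Newton system for the search direction.

    With scalar noise covariance, J^T Gamma_e^{-1} J = J^T J / sigma_e^2.
    """
    J = np.asarray(J, dtype=float)
    if J.shape[0] != data_model.M or J.shape[1] != mu_a.shape[0]:
        raise ValueError("Jacobian shape does not match data/parameter sizes")
    inv_var = data_model.L_e**2
    A = inv_var * (J.T @ J) + prior.precision
    residual = data_model.H_data - H_pred - data_model.eta_e
    rhs = inv_var * (J.T @ residual) - prior.precision @ (mu_a - prior.eta_mu)
    try:
        c, low = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as err:  # pragma: no cover - prior guarantees SPD
        raise np.linalg.LinAlgError(
            "Gauss-Newton system not SPD despite prior regularization"
        ) from err
    return linalg.cho_solve((c, low), rhs)


def convergence_check(history, tol: float = 0.10, window: int = 3) -> bool:
    """True when the last estimate differs from each of the ``window``
    previous estimates by less than ``tol`` in relative Euclidean norm,

        ||mu^(i) - mu^(i-k)|| / ||mu^(i)|| < tol,   k = 1..window.

    Histories shorter than ``window + 1`` estimates return False.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mus = [it.mu_a if isinstance(it, GnIterate) else np.asarray(it) for it in history]
    if len(mus) < window + 1:
        return False
    cur = mus[-1]
    denom = np.linalg.norm(cur)
    if denom == 0.0:
        return False
    for k in range(1, window + 1):
        if np.linalg.norm(cur - mus[-1 - k]) / denom >= tol:
            return False
    return True


def _safe_objective(data_model, prior, H_pred, mu_a) -> float:
    try:
        return objective(data_model, prior, H_pred, mu_a)
    except ValueError:  # degenerate (noise-free) data model
        return float("nan")


def _warn_negative(mu_a: np.ndarray, i: int) -> None:
    if np.any(mu_a < 0):
        logger.warning(
            "iteration %d: %d negative absorption entries (no clipping applied)",
            i,
            int((mu_a < 0).sum()),
        )


def run_ssgn(
    forward,
    data_model: DataModel,
    prior: PriorModel,
    mu0: np.ndarray | None = None,
    P: int | None = None,
    mode: str = "convergence",
    budget: int | None = None,
    n_budget_iters: int = 10,
    tol: float = 0.10,
    window: int = 3,
    max_iter: int = 50,
    truth_fn=None,
    log_path=None,
) -> list[GnIterate]:
    """Stochastic Gauss-Newton with a fixed packet count per iteration.

    ``forward`` is a callable ``(mu_a, P) -> (H, J)`` (e.g.
    :class:`asgn.forward.MonteCarloForward`); each call must use a fresh
    stochastic realization.  Modes:

    ``"convergence"``
        iterate at fixed ``P`` until :func:`convergence_check` (or
        ``max_iter``);
    ``"budget"``
        split a total photon budget equally over ``n_budget_iters``
        iterations, ``P_i = budget // n_budget_iters``;
    ``"fixed"``
        run exactly ``max_iter`` iterations at fixed ``P``.

    The objective is evaluated by reusing each iteration's simulation
    (no extra forward run).  ``truth_fn(mu_a)`` may supply a relative
    error in percent for logging.
    """
    if mode == "budget":
        if budget is None or budget < n_budget_iters:
            raise ValueError("budget mode needs budget >= n_budget_iters")
        P = budget // n_budget_iters
        n_iters = n_budget_iters
    else:
        if P is None or P < 1:
            raise ValueError("P must be >= 1")
        n_iters = max_iter
    mu = prior.eta_mu.copy() if mu0 is None else np.asarray(mu0, dtype=float).copy()
    history: list[GnIterate] = []
    booked = 0
    for i in range(1, n_iters + 1):
        t0 = time.perf_counter()
        H, J = forward(mu, P)
        delta = gn_direction(J, H, data_model, prior, mu)
        u = _safe_objective(data_model, prior, H, mu)
        mu = mu + delta
        _warn_negative(mu, i)
        booked += P
        history.append(
            GnIterate(
                i=i,
                mu_a=mu.copy(),
                P_i=P,
                delta=delta,
                u_value=u,
                rel_error=None if truth_fn is None else float(truth_fn(mu)),
                cumulative_packets=booked,
                wall_time_s=time.perf_counter() - t0,
            )
        )
        if mode == "convergence" and convergence_check(history, tol=tol, window=window):
            break
    if log_path is not None:
        history_to_frame(history).to_csv(log_path, index=False)
    return history


def history_to_frame(history: list[GnIterate]) -> pd.DataFrame:
    """Per-iteration log as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "iteration": [it.i for it in history],
            "P_i": [it.P_i for it in history],
            "cumulative_packets": [it.cumulative_packets for it in history],
            "u": [it.u_value for it in history],
            "delta_norm": [float(np.linalg.norm(it.delta)) for it in history],
            "rel_error_pct": [it.rel_error for it in history],
            "wall_time_s": [it.wall_time_s for it in history],
        }
    )
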