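"""Adaptive stochastic Gauss-Newton: norm test and packet-count update.

Per iteration, L independent Monte Carlo realizations at the current
packet count P_i yield L sample directions {delta^(l)} and, from the
elementwise means of {H^(l)} and {J^(l)}, a proxy for the accurate
direction delta_bar (the means aggregate L * P_i packets).  The norm
test controls the expected squared relative direction error

    V^2 = (1/L) sum_l ||delta^(l) - delta_bar||^2 / ||delta_bar||^2
        <= gamma^2;

when it fails the packet count grows by the measured ratio,
P <- ceil((V^2 / gamma^2) P).  If the ratio also exceeds L, the mean
direction itself (equivalent to L * P_i packets) is no longer accurate
enough and one fresh simulation at the updated P supplies the step.
Steps use alpha = 1.

Stopping is either a convergence criterion on the iterates (relative
change below tol for each of the last ``window`` estimates) or an
exhausted photon budget; in budget mode a remainder too small for a
norm test is added to the last iteration by pooling the extra packets
into that iteration's direction estimate.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np

from .forward import DataModel
from .gn_inversion import (
    GnIterate,
    _safe_objective,
    _warn_negative,
    convergence_check,
    gn_direction,
    history_to_frame,
)
from .prior_bayes import PriorModel

__all__ = ["NormTestOutcome", "AsgnConfig", "norm_test", "update_packet_count", "run_asgn"]

logger = logging.getLogger("asgn")


@dataclass
class NormTestOutcome:
    """Result of one L-sample norm test at packet count P_i."""

    V_sq: float
    passed: bool
    ratio: float  # V_sq / gamma^2
    delta_bar: np.ndarray
    deltas: np.ndarray  # (L, N) per-sample directions
    P_next: int
    H_bar: np.ndarray
    J_bar: np.ndarray
    packets_booked: int


@dataclass
class AsgnConfig:
    """Parameters of the A-SGN loop.

    Defaults follow the reference configuration: start from P1 = 10
    packets, L = 10 norm-test samples, threshold gamma = 0.6, and (in
    convergence mode) stop when the estimate changes by less than 10%
    relative to each of the previous three iterates.
    """

    P1: int = 10
    L: int = 10
    gamma: float = 0.6
    mode: str = "convergence"  # "convergence" | "budget"
    Pb: int | None = None
    tol: float = 0.10
    window: int = 3
    max_iter: int = 60

    def __post_init__(self):
        if self.P1 < 1:
            raise ValueError("P1 must be >= 1")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.mode not in ("convergence", "budget"):
            raise ValueError("mode must be 'convergence' or 'budget'")
        if self.mode == "budget" and (self.Pb is None or self.Pb < 1):
            raise ValueError("budget mode requires a positive photon budget Pb")


def norm_test(
    forward,
    data_model: DataModel,
    prior: PriorModel,
    mu_a: np.ndarray,
    P: int,
    L: int,
    gamma: float,
) -> NormTestOutcome:
    """Run L independent simulations at P packets and test the direction.

    ``forward`` is a callable ``(mu_a, P) -> (H, J)`` drawing a fresh
    stochastic realization per call.  ``delta_bar`` is computed from the
    means of {H^(l)} and {J^(l)} (not the mean of the L directions).
    A vanishing ``delta_bar`` defines V^2 = 0 (converged) and is logged.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    Hs = []
    Js = []
    deltas = []
    for _ in range(L):
        H, J = forward(mu_a, P)
        Hs.append(H)
        Js.append(J)
        deltas.append(gn_direction(J, H, data_model, prior, mu_a))
    H_bar = np.mean(Hs, axis=0)
    J_bar = np.mean(Js, axis=0)
    delta_bar = gn_direction(J_bar, H_bar, data_model, prior, mu_a)
    deltas = np.asarray(deltas)
    denom = float(delta_bar @ delta_bar)
    if denom == 0.0:
        logger.info("norm test: ||delta_bar|| = 0, treating as converged (V^2 = 0)")
        V_sq = 0.0
    else:
        V_sq = float(np.mean(np.sum((deltas - delta_bar) ** 2, axis=1))) / denom
    passed = V_sq <= gamma**2
    return NormTestOutcome(
        V_sq=V_sq,
        passed=passed,
        ratio=V_sq / gamma**2,
        delta_bar=delta_bar,
        deltas=deltas,
        P_next=update_packet_count(V_sq, gamma, P),
        H_bar=H_bar,
        J_bar=J_bar,
        packets_booked=L * P,
    )


def update_packet_count(V_sq: float, gamma: float, P_i: int) -> int:
    """Packet-count update: unchanged on pass, otherwise grown by the
    measured error ratio, ``P <- ceil((V^2 / gamma^2) P)``."""
    if V_sq < 0 or gamma <= 0 or P_i < 1:
        raise ValueError("require V_sq >= 0, gamma > 0, P_i >= 1")
    if V_sq <= gamma**2:
        return P_i
    return math.ceil((V_sq / gamma**2) * P_i)


def run_asgn(
    config: AsgnConfig,
    forward,
    data_model: DataModel,
    prior: PriorModel,
    mu0: np.ndarray | None = None,
    truth_fn=None,
    log_path=None,
) -> list[GnIterate]:
    """The adaptive stochastic Gauss-Newton loop.

    Per iteration: run the norm test; on pass, step with delta_bar; on
    failure with ratio <= L, grow P and still step with delta_bar (the
    mean already aggregates L * P_i packets); on failure with ratio > L,
    grow P and step with one fresh simulation at the updated P.  The
    packet count is non-decreasing and carried to the next iteration.

    Budget mode books L * P_i per norm test and P per extra simulation
    against ``config.Pb``.  When the leftover budget no longer covers a
    norm test, it is added to the last iteration: the remainder is
    simulated at the current iterate and pooled (packet-weighted) with
    that iteration's samples before the final step, so the booked total
    reaches Pb exactly and the final direction never comes from a
    low-packet fresh simulation.  Budgets smaller than one norm test
    degenerate to a single plain GN iteration.  Relative errors
    (percent) are logged through ``truth_fn`` when given.
    """
    logger.info(
        "A-SGN run: P1=%d L=%d gamma=%g mode=%s Pb=%s tol=%g window=%d",
        config.P1,
        config.L,
        config.gamma,
        config.mode,
        config.Pb,
        config.tol,
        config.window,
    )
    mu = prior.eta_mu.copy() if mu0 is None else np.asarray(mu0, dtype=float).copy()
    P = config.P1
    booked = 0
    history: list[GnIterate] = []
    budget_mode = config.mode == "budget"

    def final_plain_iteration(P_final: int, i: int, t0: float):
        nonlocal mu, booked
        H, J = forward(mu, P_final)
        delta = gn_direction(J, H, data_model, prior, mu)
        u = _safe_objective(data_model, prior, H, mu)
        mu = mu + delta
        booked += P_final
        history.append(
            GnIterate(
                i=i,
                mu_a=mu.copy(),
                P_i=P_final,
                delta=delta,
                u_value=u,
                rel_error=None if truth_fn is None else float(truth_fn(mu)),
                cumulative_packets=booked,
                wall_time_s=time.perf_counter() - t0,
                extra={"branch": "final", "V_sq": np.nan},
            )
        )

    if budget_mode and config.Pb < config.L * config.P1:
        logger.warning(
            "photon budget %d smaller than one norm test (L*P1 = %d); "
            "spending it on a single plain GN iteration",
            config.Pb,
            config.L * config.P1,
        )
        final_plain_iteration(config.Pb, 1, time.perf_counter())
        if log_path is not None:
            history_to_frame(history).to_csv(log_path, index=False)
        return history

    i = 0
    while True:
        i += 1
        t0 = time.perf_counter()
        if budget_mode:
            remaining = config.Pb - booked
            if remaining < config.L * P:
                if remaining >= 1:
                    final_plain_iteration(remaining, i, t0)
                break
        outcome = norm_test(forward, data_model, prior, mu, P, config.L, config.gamma)
        booked += outcome.packets_booked
        branch = "pass"
        delta = outcome.delta_bar
        u = _safe_objective(data_model, prior, outcome.H_bar, mu)
        folded = 0
        if not outcome.passed:
            P = outcome.P_next
            if outcome.ratio > config.L:
                branch = "recompute"
                P_sim = P
                if budget_mode:
                    remaining = config.Pb - booked
                    if remaining - P_sim < config.L * P:
                        # next norm test unaffordable: fold the whole
                        # remainder into this last simulation
                        folded = max(remaining - P_sim, 0)
                        P_sim = remaining
                if P_sim >= 1:
                    H, J = forward(mu, P_sim)
                    delta = gn_direction(J, H, data_model, prior, mu)
                    u = _safe_objective(data_model, prior, H, mu)
                    booked += P_sim
                else:
                    branch = "mean"  # budget exhausted; fall back to delta_bar
            else:
                branch = "mean"
        if budget_mode and branch in ("pass", "mean"):
            remaining = config.Pb - booked
            if 1 <= remaining < config.L * P:
                # remainder added to this (last) iteration: pool the extra
                # simulation with the norm-test samples, packet-weighted
                H_extra, J_extra = forward(mu, remaining)
                w_mean = outcome.packets_booked / (outcome.packets_booked + remaining)
                H_pool = w_mean * outcome.H_bar + (1 - w_mean) * H_extra
                J_pool = w_mean * outcome.J_bar + (1 - w_mean) * J_extra
                delta = gn_direction(J_pool, H_pool, data_model, prior, mu)
                u = _safe_objective(data_model, prior, H_pool, mu)
                booked += remaining
                folded = remaining
        mu = mu + delta
        _warn_negative(mu, i)
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
                extra={
                    "branch": branch,
                    "V_sq": outcome.V_sq,
                    "ratio": outcome.ratio,
                    "folded_remainder": folded,
                },
            )
        )
        if not budget_mode:
            if convergence_check(history, tol=config.tol, window=config.window):
                break
            if i >= config.max_iter:
                logger.warning("A-SGN reached max_iter=%d without convergence", config.max_iter)
                break
        elif booked >= config.Pb:
            break
    if log_path is not None:
        history_to_frame(history).to_csv(log_path, index=False)
    return history
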