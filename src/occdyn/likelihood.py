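"""Exact likelihood for the dynamic correlated-detection occupancy model.

The observation model is hierarchical: a route is occupied or not in
each season (a two-state Markov chain over years driven by colonization
``gamma`` and extinction ``epsilon``); given occupancy, availability at
successive stops follows a two-state Markov chain along the route
(``theta0`` at the first stop, then ``theta`` / ``theta_prime``
depending on the previous stop); given availability, a detection is
Bernoulli with a stop-specific probability drawn from one of two
route-level detection classes mixed with weight ``pi_mix``. There are
no false positives: a detection implies availability implies occupancy.

All public functions operate on probabilities; the vectorized
log-domain machinery used by fitting lives in :func:`stack_logliks`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histories import MISSING, DetectionHistory, HistoryStack

__all__ = [
    "ParameterPoint",
    "ParameterArrays",
    "stop_forward",
    "year_emission",
    "route_likelihood",
    "annual_occupancy",
    "equilibrium_occupancy",
    "route_detection_prob",
    "stack_logliks",
    "stack_neg2_loglik",
    "stationary_theta0",
]

_LOG_ZERO = -np.inf


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got {value!r}")


def stationary_theta0(theta, theta_prime):
    """Stationary availability of the along-route chain, theta/(theta + 1 - theta')."""
    theta = np.asarray(theta, dtype=float)
    theta_prime = np.asarray(theta_prime, dtype=float)
    denom = theta + 1.0 - theta_prime
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, theta / np.where(denom > 0, denom, 1.0), 0.5)
    return out if out.ndim else float(out)


@dataclass
class ParameterPoint:
    """Natural-scale parameters for a single route.

    ``p1`` and ``p2`` are ``(n_years, n_stops)`` detection probabilities
    for the low- and high-detection classes; ``gamma`` and ``epsilon``
    have one entry per year-to-year transition. ``theta0`` defaults to
    ``theta`` when not given (first-stop availability is not separately
    identified by the standard formulation).
    """

    psi: float
    theta: float
    theta_prime: float
    p1: np.ndarray
    p2: np.ndarray
    pi_mix: float
    gamma: np.ndarray
    epsilon: np.ndarray
    theta0: float | None = None

    def __post_init__(self) -> None:
        self.p1 = np.atleast_2d(np.asarray(self.p1, dtype=float))
        self.p2 = np.atleast_2d(np.asarray(self.p2, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        if self.theta0 is None:
            self.theta0 = self.theta
        for name in ("psi", "theta", "theta_prime", "pi_mix", "theta0"):
            _check_prob(name, getattr(self, name))
        for name in ("p1", "p2", "gamma", "epsilon"):
            _check_prob(name, getattr(self, name))


def stop_forward(
    y_row: np.ndarray,
    theta0: float,
    theta: float,
    theta_prime: float,
    p_row: np.ndarray,
) -> float:
    """Pr(stop observations | route occupied, detection class fixed).

    Two-state (unavailable/available) forward recursion along the
    stops. Availability at the first stop is Bernoulli(``theta0``);
    thereafter the chain moves with ``theta`` (from unavailable) or
    ``theta_prime`` (from available). An available stop emits a
    detection with its entry of ``p_row``; an unavailable stop never
    does. Missing stops emit probability one while the chain advances.
    """
    for name, v in (("theta0", theta0), ("theta", theta), ("theta_prime", theta_prime)):
        _check_prob(name, v)
    y_row = np.asarray(y_row)
    p_row = np.asarray(p_row, dtype=float)
    _check_prob("p_row", p_row)
    if y_row.shape != p_row.shape:
        raise ValueError("y_row and p_row must have the same length")

    a_unavail = 1.0 - theta0
    a_avail = theta0
    first = True
    for y, p in zip(y_row, p_row):
        if not first:
            nxt_unavail = a_unavail * (1.0 - theta) + a_avail * (1.0 - theta_prime)
            nxt_avail = a_unavail * theta + a_avail * theta_prime
            a_unavail, a_avail = nxt_unavail, nxt_avail
        first = False
        if y == MISSING:
            continue
        if y == 1:
            a_unavail = 0.0
            a_avail *= p
        else:
            a_avail *= 1.0 - p
    return float(a_unavail + a_avail)


def year_emission(
    y_row: np.ndarray,
    z: int,
    theta0: float,
    theta: float,
    theta_prime: float,
    p_row: np.ndarray,
) -> float:
    """Pr(one season's stop observations | occupancy state ``z``).

    An unoccupied route cannot produce detections (no false positives),
    so ``z = 0`` emits 1 when the row is detection-free and 0 otherwise.
    """
    if z not in (0, 1):
        raise ValueError(f"z must be 0 or 1, got {z}")
    if z == 0:
        return 0.0 if np.any(np.asarray(y_row) == 1) else 1.0
    return stop_forward(y_row, theta0, theta, theta_prime, p_row)


def route_likelihood(history: DetectionHistory, params: ParameterPoint) -> float:
    """Exact likelihood of one route's full detection history.

    Marginalizes the route-level detection class (drawn once, shared by
    all years) and the occupancy chain over years.
    """
    T = history.n_years
    if params.p1.shape != (T, history.n_stops) or params.p2.shape != params.p1.shape:
        raise ValueError(
            f"detection probability arrays must be (n_years, n_stops) = "
            f"({T}, {history.n_stops})"
        )
    if params.gamma.shape != (T - 1,) or params.epsilon.shape != (T - 1,):
        raise ValueError("gamma/epsilon need one entry per transition")

    total = 0.0
    for weight, p_mat in ((params.pi_mix, params.p1), (1.0 - params.pi_mix, params.p2)):
        f0, f1 = 1.0 - params.psi, params.psi
        for t in range(T):
            e1 = year_emission(
                history.obs[t], 1, params.theta0, params.theta,
                params.theta_prime, p_mat[t],
            )
            e0 = year_emission(
                history.obs[t], 0, params.theta0, params.theta,
                params.theta_prime, p_mat[t],
            )
            f0, f1 = f0 * e0, f1 * e1
            if t < T - 1:
                g, e = params.gamma[t], params.epsilon[t]
                f0, f1 = f0 * (1.0 - g) + f1 * e, f0 * g + f1 * (1.0 - e)
        total += weight * (f0 + f1)
    return float(total)


def annual_occupancy(psi1: float, gamma_series, epsilon_series) -> np.ndarray:
    """Occupancy trajectory psi_{t+1} = psi_t (1 - eps_t) + (1 - psi_t) gamma_t."""
    gamma_series = np.atleast_1d(np.asarray(gamma_series, dtype=float))
    epsilon_series = np.atleast_1d(np.asarray(epsilon_series, dtype=float))
    if gamma_series.shape != epsilon_series.shape:
        raise ValueError("gamma and epsilon series must have equal length")
    _check_prob("psi1", psi1)
    _check_prob("gamma", gamma_series)
    _check_prob("epsilon", epsilon_series)
    out = np.empty(gamma_series.size + 1)
    out[0] = psi1
    for t, (g, e) in enumerate(zip(gamma_series, epsilon_series)):
        out[t + 1] = out[t] * (1.0 - e) + (1.0 - out[t]) * g
    return out


def equilibrium_occupancy(gamma: float, epsilon: float) -> float:
    """Stationary occupancy gamma / (gamma + epsilon) under constant rates."""
    _check_prob("gamma", gamma)
    _check_prob("epsilon", epsilon)
    if gamma + epsilon == 0.0:
        raise ValueError("equilibrium occupancy undefined when gamma = epsilon = 0")
    return gamma / (gamma + epsilon)


def route_detection_prob(
    theta0: float,
    theta: float,
    theta_prime: float,
    p_rows,
    weights=None,
) -> float:
    """Pr(at least one detection on the route | route occupied).

    ``p_rows`` is one per-stop detection vector per mixture class;
    ``weights`` the class weights (default: single class / uniform).
    """
    p_rows = [np.atleast_1d(np.asarray(p, dtype=float)) for p in np.atleast_2d(p_rows)]
    if weights is None:
        weights = np.full(len(p_rows), 1.0 / len(p_rows))
    weights = np.asarray(weights, dtype=float)
    pr_none = 0.0
    for w, p_row in zip(weights, p_rows):
        zeros = np.zeros(p_row.size, dtype=np.int8)
        pr_none += w * stop_forward(zeros, theta0, theta, theta_prime, p_row)
    return float(1.0 - pr_none)


# ---------------------------------------------------------------------------
# Vectorized machinery (routes share the year/stop grid).
# ---------------------------------------------------------------------------


@dataclass
class ParameterArrays:
    """Natural-scale parameters for a whole :class:`HistoryStack`.

    Shapes (R routes, T years, S stops): ``psi``, ``theta0``, ``theta``,
    ``theta_prime``: ``(R,)``; ``p`` : ``(2, R or 1, T, S)`` with class 0
    = low-detection; ``gamma``, ``epsilon``: ``(R, T - 1)``; ``pi_mix``
    scalar.
    """

    psi: np.ndarray
    theta0: np.ndarray
    theta: np.ndarray
    theta_prime: np.ndarray
    p: np.ndarray
    pi_mix: float
    gamma: np.ndarray
    epsilon: np.ndarray

    def for_route(self, r: int) -> ParameterPoint:
        """Slice out a single route's :class:`ParameterPoint`."""
        idx = r if self.p.shape[1] > 1 else 0
        return ParameterPoint(
            psi=float(self.psi[r]),
            theta0=float(self.theta0[r]),
            theta=float(self.theta[r]),
            theta_prime=float(self.theta_prime[r]),
            p1=self.p[0, idx],
            p2=self.p[1, idx],
            pi_mix=self.pi_mix,
            gamma=self.gamma[r],
            epsilon=self.epsilon[r],
        )


def _stop_forward_batch(
    obs: np.ndarray,
    theta0: np.ndarray,
    theta: np.ndarray,
    theta_prime: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """Vectorized stop_forward: obs (R,T,S), p (2,R|1,T,S) -> (2,R,T)."""
    R, T, S = obs.shape
    th0 = theta0[None, :, None]
    th = theta[None, :, None]
    thp = theta_prime[None, :, None]
    a_u = np.broadcast_to(1.0 - th0, (2, R, T)).copy()
    a_a = np.broadcast_to(th0, (2, R, T)).copy()
    for s in range(S):
        if s > 0:
            nxt_u = a_u * (1.0 - th) + a_a * (1.0 - thp)
            nxt_a = a_u * th + a_a * thp
            a_u, a_a = nxt_u, nxt_a
        y = obs[None, :, :, s]
        ps = p[:, :, :, s]
        det = y == 1
        nondet = y == 0
        a_u = np.where(det, 0.0, a_u)
        a_a = np.where(det, a_a * ps, np.where(nondet, a_a * (1.0 - ps), a_a))
    return a_u + a_a


def stack_logliks(stack_obs: np.ndarray, params: ParameterArrays) -> np.ndarray:
    """Per-route log-likelihoods for stacked observations ``(R, T, S)``.

    Runs the year-level forward filter in a scaled (log-stable) form and
    marginalizes the two detection classes with log-sum-exp; routes with
    probability-zero histories get ``-inf``.
    """
    R, T, S = stack_obs.shape
    e1 = _stop_forward_batch(
        stack_obs, params.theta0, params.theta, params.theta_prime, params.p
    )  # (2, R, T)
    e0 = (~(stack_obs == 1).any(axis=2)).astype(float)[None, :, :]  # (1, R, T)

    f0 = np.broadcast_to(1.0 - params.psi, (2, R)).copy()
    f1 = np.broadcast_to(params.psi, (2, R)).copy()
    logscale = np.zeros((2, R))
    for t in range(T):
        f0 = f0 * e0[:, :, t]
        f1 = f1 * e1[:, :, t]
        c = f0 + f1
        with np.errstate(divide="ignore", invalid="ignore"):
            logscale += np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), _LOG_ZERO)
        safe = np.where(c > 0, c, 1.0)
        f0, f1 = f0 / safe, f1 / safe
        if t < T - 1:
            g = params.gamma[:, t][None, :]
            e = params.epsilon[:, t][None, :]
            f0, f1 = f0 * (1.0 - g) + f1 * e, f0 * g + f1 * (1.0 - e)
    # mixture over classes: log(pi * L0 + (1 - pi) * L1), log-sum-exp form
    with np.errstate(divide="ignore"):
        logw = np.log(np.array([params.pi_mix, 1.0 - params.pi_mix])[:, None])
    with np.errstate(invalid="ignore"):
        terms = logw + logscale
    m = np.max(terms, axis=0)
    finite = np.isfinite(m)
    out = np.full(R, _LOG_ZERO)
    if finite.any():
        t0 = terms[:, finite]
        out[finite] = m[finite] + np.log(np.exp(t0 - m[finite]).sum(axis=0))
    return out


def stack_neg2_loglik(stack: HistoryStack | np.ndarray, params: ParameterArrays) -> float:
    """-2 * sum of per-route log-likelihoods; +inf if any route has zero likelihood."""
    obs = stack.obs if isinstance(stack, HistoryStack) else stack
    ll = stack_logliks(obs, params)
    if not np.all(np.isfinite(ll)):
        return np.inf
    return float(-2.0 * ll.sum())
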