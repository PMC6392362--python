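"""Calibration diagnostics on naïve colonization/extinction rates.

The model cannot be checked against latent occupancy directly, so the
check targets observable quantities: transitions of routes between
detection and nondetection states across consecutive surveyed years. A
route-transition is a naïve *colonization* candidate when year ``t``
was surveyed without detections, and a naïve *extinction* candidate
when year ``t`` had at least one detection; both years must be
surveyed. Expected probabilities come from forward-filtering the fitted
model over each route's full observation history through year ``t``
(marginalizing the detection-class mixture), propagating one
transition, and pushing through the route-level detection probability.
Observed and expected event counts are then compared bin-wise with a
Hosmer–Lemeshow chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .histories import HistoryStack
from .likelihood import ParameterArrays, _stop_forward_batch

__all__ = [
    "TransitionEvent",
    "naive_transition_events",
    "expected_naive_rates",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
]

COLONIZATION = "naive_colonization_candidate"
EXTINCTION = "naive_extinction_candidate"


@dataclass
class TransitionEvent:
    route_id: str
    year_from: int
    year_to: int
    kind: str  # COLONIZATION | EXTINCTION
    observed: int
    expected_prob: float | None = None


def naive_transition_events(stack: HistoryStack) -> list[TransitionEvent]:
    """Candidate route-transitions and their observed outcomes.

    Transitions with an unsurveyed endpoint are excluded. For a
    colonization candidate the event is a detection in year ``t + 1``;
    for an extinction candidate, the absence of any detection there.
    """
    events = []
    for h in stack:
        surveyed = h.surveyed()
        detected = h.detected()
        for t in range(h.n_years - 1):
            if not (surveyed[t] and surveyed[t + 1]):
                continue
            if detected[t]:
                events.append(
                    TransitionEvent(
                        route_id=h.route_id,
                        year_from=int(h.years[t]),
                        year_to=int(h.years[t + 1]),
                        kind=EXTINCTION,
                        observed=int(not detected[t + 1]),
                    )
                )
            else:
                events.append(
                    TransitionEvent(
                        route_id=h.route_id,
                        year_from=int(h.years[t]),
                        year_to=int(h.years[t + 1]),
                        kind=COLONIZATION,
                        observed=int(detected[t + 1]),
                    )
                )
    return events


def _filtered_joint(stack: HistoryStack, params: ParameterArrays) -> np.ndarray:
    """Joint filtering distribution over (class, occupancy) after each year.

    Returns ``post`` of shape ``(R, T, 2, 2)`` where
    ``post[r, t, c, z]`` is Pr(class = c, z_t = z | observations of
    route r through year t) — the distribution *before* the t -> t+1
    transition is applied.
    """
    obs = stack.obs
    R, T, S = obs.shape
    e1 = _stop_forward_batch(
        obs, params.theta0, params.theta, params.theta_prime, params.p
    )  # (2, R, T)
    e0 = (~(obs == 1).any(axis=2)).astype(float)[None, :, :]

    w = np.array([params.pi_mix, 1.0 - params.pi_mix])
    f = np.empty((R, 2, 2))  # (route, class, z)
    f[:, :, 0] = w[None, :] * (1.0 - params.psi[:, None])
    f[:, :, 1] = w[None, :] * params.psi[:, None]

    post = np.empty((R, T, 2, 2))
    for t in range(T):
        em = np.stack(
            [np.broadcast_to(e0[:, :, t], (2, R)), e1[:, :, t]], axis=-1
        )  # (class, route, z)
        f = f * em.transpose(1, 0, 2)
        norm = f.sum(axis=(1, 2), keepdims=True)
        if np.any(norm == 0):
            raise FloatingPointError(
                "zero filtering probability: data impossible under parameters"
            )
        f = f / norm
        post[:, t] = f
        if t < T - 1:
            g = params.gamma[:, t][:, None]
            e = params.epsilon[:, t][:, None]
            f = np.stack(
                [f[:, :, 0] * (1.0 - g) + f[:, :, 1] * e,
                 f[:, :, 0] * g + f[:, :, 1] * (1.0 - e)],
                axis=-1,
            )
    return post


def _route_det_prob(stack: HistoryStack, params: ParameterArrays) -> np.ndarray:
    """Pr(>=1 detection | occupied, class), per (class, route, year)."""
    zeros = np.zeros_like(stack.obs)
    pr_none = _stop_forward_batch(
        zeros, params.theta0, params.theta, params.theta_prime, params.p
    )
    return 1.0 - pr_none  # (2, R, T)


def expected_naive_rates(
    stack: HistoryStack,
    params: ParameterArrays,
    events: list[TransitionEvent],
    conditioning: str = "history",
) -> list[TransitionEvent]:
    """Fill ``expected_prob`` on each transition event, in place.

    ``conditioning="history"`` (default) conditions on the full
    observation record through the origin year; ``"year"`` conditions
    on the origin year's observations only.
    """
    if conditioning not in ("history", "year"):
        raise ValueError("conditioning must be 'history' or 'year'")
    if conditioning == "history":
        post = _filtered_joint(stack, params)
    else:
        post = _single_year_joint(stack, params)
    det = _route_det_prob(stack, params)  # (2, R, T)
    ridx = {rid: i for i, rid in enumerate(stack.route_ids)}
    yidx = {int(y): t for t, y in enumerate(stack.years)}

    for ev in events:
        r, t = ridx[ev.route_id], yidx[ev.year_from]
        t1 = yidx[ev.year_to]
        g = params.gamma[r, t]
        e = params.epsilon[r, t]
        f = post[r, t]  # (class, z)
        # propagate one transition: Pr(class, z_{t+1} | data through t)
        occ_next = f[:, 0] * g + f[:, 1] * (1.0 - e)  # per class
        pr_detect = float((occ_next * det[:, r, t1]).sum())
        if ev.kind == COLONIZATION:
            ev.expected_prob = pr_detect
        else:
            ev.expected_prob = 1.0 - pr_detect
    return events


def _single_year_joint(stack: HistoryStack, params: ParameterArrays) -> np.ndarray:
    """Like :func:`_filtered_joint` but conditioning on one year at a time.

    The prior over occupancy in year t is the unconditional chain
    marginal; only year t's observations are filtered in.
    """
    obs = stack.obs
    R, T, _ = obs.shape
    e1 = _stop_forward_batch(
        obs, params.theta0, params.theta, params.theta_prime, params.p
    )
    e0 = (~(obs == 1).any(axis=2)).astype(float)[None, :, :]
    w = np.array([params.pi_mix, 1.0 - params.pi_mix])

    # unconditional occupancy marginal per route-year
    psi_t = np.empty((R, T))
    psi_t[:, 0] = params.psi
    for t in range(T - 1):
        psi_t[:, t + 1] = psi_t[:, t] * (1.0 - params.epsilon[:, t]) + (
            1.0 - psi_t[:, t]
        ) * params.gamma[:, t]

    post = np.empty((R, T, 2, 2))
    for t in range(T):
        f = np.empty((R, 2, 2))
        f[:, :, 0] = w[None, :] * (1.0 - psi_t[:, t][:, None]) * e0[:, :, t].T
        f[:, :, 1] = w[None, :] * psi_t[:, t][:, None] * e1[:, :, t].T
        norm = f.sum(axis=(1, 2), keepdims=True)
        if np.any(norm == 0):
            raise FloatingPointError(
                "zero single-year probability: data impossible under parameters"
            )
        post[:, t] = f / norm
    return post


@dataclass
class HosmerLemeshowResult:
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame


def hosmer_lemeshow(
    events: list[TransitionEvent],
    n_bins: int = 10,
    min_expected: float = 4.0,
) -> HosmerLemeshowResult:
    """Binned calibration chi-square on transition events.

    Events are binned by deciles of expected probability; bins are
    merged from the sparse (low-expectation) end until each bin's
    summed expected event count exceeds ``min_expected``. The statistic
    sums ``(O - E)^2 / E`` over both the event and non-event sides of
    each bin; degrees of freedom are ``bins - 2``.
    """
    if any(ev.expected_prob is None for ev in events):
        raise ValueError("events must carry expected probabilities; run "
                         "expected_naive_rates first")
    probs = np.array([ev.expected_prob for ev in events], dtype=float)
    obs = np.array([ev.observed for ev in events], dtype=float)
    if probs.size == 0:
        raise ValueError("no transition events to test")

    edges = np.quantile(probs, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 2:
        raise ValueError("all expected probabilities identical: only one bin")
    assign = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, edges.size - 2)

    bins = []
    for b in range(edges.size - 1):
        sel = assign == b
        if sel.sum() == 0:
            continue
        bins.append(
            {"n": int(sel.sum()), "observed": float(obs[sel].sum()),
             "expected": float(probs[sel].sum())}
        )
    # merge from the sparse (lowest-expectation) end until E > min_expected
    merged: list[dict] = []
    for b in bins:
        if merged and merged[-1]["expected"] <= min_expected:
            merged[-1] = {k: merged[-1][k] + b[k] for k in b}
        else:
            merged.append(dict(b))
    if len(merged) >= 2 and merged[-1]["expected"] <= min_expected:
        last = merged.pop()
        merged[-1] = {k: merged[-1][k] + last[k] for k in last}
    if len(merged) < 2:
        raise ValueError("fewer than two bins after pooling; test undefined")

    chi2 = 0.0
    for b in merged:
        e, o, n = b["expected"], b["observed"], b["n"]
        if e > 0:
            chi2 += (o - e) ** 2 / e
        if n - e > 0:
            chi2 += ((n - o) - (n - e)) ** 2 / (n - e)
    df = len(merged) - 2
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else np.nan
    table = pd.DataFrame(merged)
    table.insert(0, "bin", np.arange(1, len(merged) + 1))
    return HosmerLemeshowResult(chi2=float(chi2), df=df, p_value=p, table=table)
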