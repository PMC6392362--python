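"""Design matrices linking coefficients to natural-scale parameters.

Every parameter family is modeled on the log-odds scale as a linear
combination of design columns declared by its :class:`~occdyn.modelspec.Term`
list. Covariate columns are resolved from a route-by-year covariate
table that carries, for each covariate base name ``n``, the standardized
spatial-mean component ``n_mean`` (constant within a route) and the
temporal-deviation component ``n_dev`` (summing to zero within a route).
The ``first_year`` component is their sum evaluated at the first survey
year.

Conventions:

* ``psi``, ``theta``, ``theta_prime`` designs are per-route ``(R, k)``.
* ``gamma``/``epsilon`` designs are per route and transition
  ``(R, T-1, k)``; a year dummy for calendar year ``y`` marks the
  transition *into* ``y``; deviation covariates are taken at the origin
  year of the transition by default (configurable to destination).
* ``p1``/``p2`` designs are ``(T, S, k)`` (year dummies mark the survey
  year, baseline = first year; stop polynomials use the standardized
  stop index) or ``(R, T, S, k)`` when route-level covariates enter.
* ``pi_mix`` is intercept-only (a scalar logit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .histories import HistoryStack
from .likelihood import ParameterArrays, stationary_theta0
from .modelspec import FAMILIES, ModelSpec, Term

__all__ = ["DesignSet", "build_designs", "parameter_arrays", "expit", "split_coefficients"]


def expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass
class DesignSet:
    """Pre-built design arrays for one (dataset, spec, covariates) triple."""

    spec: ModelSpec
    route_ids: list[str]
    years: np.ndarray
    n_stops: int
    psi: np.ndarray           # (R, k_psi)
    theta: np.ndarray         # (R, k_theta)
    theta_prime: np.ndarray   # (R, k_theta_prime)
    gamma: np.ndarray         # (R, T-1, k_gamma)
    epsilon: np.ndarray       # (R, T-1, k_epsilon)
    p1: np.ndarray            # (T, S, k) or (R, T, S, k)
    p2: np.ndarray
    theta0_mode: str = "theta"

    @property
    def n_params(self) -> int:
        return sum(len(self.spec.terms(f)) for f in FAMILIES)

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for fam in FAMILIES:
            k = len(self.spec.terms(fam))
            out[fam] = slice(start, start + k)
            start += k
        return out


def _covariate_frame(covariates: pd.DataFrame) -> pd.DataFrame:
    df = covariates
    if not isinstance(df.index, pd.MultiIndex):
        if not {"route_id", "year"}.issubset(df.columns):
            raise ValueError("covariate table needs route_id and year columns")
        df = df.set_index(["route_id", "year"])
    return df.sort_index()


def _resolve(
    df: pd.DataFrame,
    term: Term,
    route_ids: list[str],
    years: np.ndarray,
) -> np.ndarray:
    """Return the covariate term's value per (route, year), shape (R, T)."""
    base = term.name
    try:
        if term.component == "mean":
            col = df[f"{base}_mean"]
            vals = col.groupby(level=0).first().reindex(route_ids).to_numpy()
            return np.repeat(vals[:, None], years.size, axis=1)
        if term.component == "deviation":
            sub = df[f"{base}_dev"].unstack(level=1)
            return sub.reindex(index=route_ids, columns=years).to_numpy()
        if term.component == "first_year":
            y0 = int(years[0])
            m = df[f"{base}_mean"].groupby(level=0).first().reindex(route_ids)
            d = df[f"{base}_dev"].unstack(level=1).reindex(
                index=route_ids, columns=[y0]
            )[y0]
            vals = (m + d).to_numpy()
            return np.repeat(vals[:, None], years.size, axis=1)
        # raw: standardized annual value = mean + deviation
        m = df[f"{base}_mean"].unstack(level=1).reindex(index=route_ids, columns=years)
        d = df[f"{base}_dev"].unstack(level=1).reindex(index=route_ids, columns=years)
        return (m + d).to_numpy()
    except KeyError as err:
        raise ValueError(
            f"covariate component {base}_{term.component} not resolvable: {err}"
        ) from err


def _check_filled(arr: np.ndarray, what: str) -> np.ndarray:
    if np.any(np.isnan(arr)):
        raise ValueError(f"missing covariate values while building {what} design")
    return arr


def _standardized_stops(n_stops: int) -> np.ndarray:
    s = np.arange(1, n_stops + 1, dtype=float)
    sd = s.std()
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


def build_designs(
    stack: HistoryStack,
    spec: ModelSpec,
    covariates: pd.DataFrame | None = None,
    deviation_timing: str = "origin",
    theta0_mode: str = "theta",
) -> DesignSet:
    """Assemble all family design arrays for a stacked dataset."""
    if deviation_timing not in ("origin", "destination"):
        raise ValueError("deviation_timing must be 'origin' or 'destination'")
    if theta0_mode not in ("theta", "stationary"):
        raise ValueError("theta0_mode must be 'theta' or 'stationary'")
    if tuple(t.kind for t in spec.terms("pi_mix")) != ("intercept",):
        raise ValueError("pi_mix must be intercept-only (a scalar logit)")

    R, T, S = stack.obs.shape
    years = stack.years
    df = _covariate_frame(covariates) if covariates is not None else None

    def route_design(family: str) -> np.ndarray:
        terms = spec.terms(family)
        X = np.empty((R, len(terms)))
        for j, term in enumerate(terms):
            if term.kind == "intercept":
                X[:, j] = 1.0
            elif term.kind == "covariate":
                if df is None:
                    raise ValueError(f"family {family} needs a covariate table")
                X[:, j] = _resolve(df, term, stack.route_ids, years)[:, 0]
            else:
                raise ValueError(
                    f"term {term.label} not allowed in family {family}"
                )
        return _check_filled(X, family)

    def vital_design(family: str) -> np.ndarray:
        terms = spec.terms(family)
        X = np.zeros((R, T - 1, len(terms)))
        for j, term in enumerate(terms):
            if term.kind == "intercept":
                X[:, :, j] = 1.0
            elif term.kind == "year_dummy":
                # dummy marks the transition whose destination year is `year`
                dest = years[1:]
                X[:, :, j] = (dest == term.year).astype(float)[None, :]
            elif term.kind == "covariate":
                if df is None:
                    raise ValueError(f"family {family} needs a covariate table")
                vals = _resolve(df, term, stack.route_ids, years)
                if term.component == "deviation":
                    idx = slice(0, T - 1) if deviation_timing == "origin" else slice(1, T)
                    X[:, :, j] = vals[:, idx]
                else:
                    X[:, :, j] = vals[:, : T - 1]
            else:
                raise ValueError(f"term {term.label} not allowed in family {family}")
        return _check_filled(X, family)

    def detection_design(family: str) -> np.ndarray:
        terms = spec.terms(family)
        has_route = any(t.kind == "covariate" for t in terms)
        shape = (R, T, S, len(terms)) if has_route else (T, S, len(terms))
        X = np.zeros(shape)
        stops = _standardized_stops(S)
        for j, term in enumerate(terms):
            if term.kind == "intercept":
                X[..., j] = 1.0
            elif term.kind == "year_dummy":
                marks = (years == term.year).astype(float)
                X[..., j] = marks[:, None] if not has_route else marks[None, :, None]
            elif term.kind == "stop_poly":
                X[..., j] = stops[None, :] ** term.degree if not has_route else (
                    stops[None, None, :] ** term.degree
                )
            elif term.kind == "covariate":
                if df is None:
                    raise ValueError(f"family {family} needs a covariate table")
                vals = _resolve(df, term, stack.route_ids, years)  # (R, T)
                X[..., j] = vals[:, :, None]
            else:
                raise ValueError(f"term {term.label} not allowed in family {family}")
        return _check_filled(X, family)

    return DesignSet(
        spec=spec,
        route_ids=list(stack.route_ids),
        years=years.copy(),
        n_stops=S,
        psi=route_design("psi"),
        theta=route_design("theta"),
        theta_prime=route_design("theta_prime"),
        gamma=vital_design("gamma"),
        epsilon=vital_design("epsilon"),
        p1=detection_design("p1"),
        p2=detection_design("p2"),
        theta0_mode=theta0_mode,
    )


def split_coefficients(designs: DesignSet, beta: np.ndarray) -> dict[str, np.ndarray]:
    beta = np.asarray(beta, dtype=float)
    if beta.size != designs.n_params:
        raise ValueError(
            f"coefficient vector has {beta.size} entries, spec needs {designs.n_params}"
        )
    return {fam: beta[sl] for fam, sl in designs.slices().items()}


def parameter_arrays(designs: DesignSet, beta: np.ndarray) -> ParameterArrays:
    """Map a flat coefficient vector to natural-scale parameter arrays."""
    b = split_coefficients(designs, beta)
    psi = expit(designs.psi @ b["psi"])
    theta = expit(designs.theta @ b["theta"])
    theta_prime = expit(designs.theta_prime @ b["theta_prime"])
    if designs.theta0_mode == "stationary":
        theta0 = np.asarray(stationary_theta0(theta, theta_prime))
    else:
        theta0 = theta
    gamma = expit(designs.gamma @ b["gamma"])
    epsilon = expit(designs.epsilon @ b["epsilon"])
    p1 = expit(designs.p1 @ b["p1"])
    p2 = expit(designs.p2 @ b["p2"])
    if p1.ndim == 2:  # (T, S) shared across routes
        p = np.stack([p1[None], p2[None]])
    else:
        p = np.stack([p1, p2])
    pi_mix = float(expit(b["pi_mix"][0]))
    return ParameterArrays(
        psi=psi,
        theta0=theta0,
        theta=theta,
        theta_prime=theta_prime,
        p=p,
        pi_mix=pi_mix,
        gamma=gamma,
        epsilon=epsilon,
    )
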