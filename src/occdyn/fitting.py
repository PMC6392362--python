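"""Maximum-likelihood estimation and sequential covariate reduction.

Coefficients for all parameter families live in a single flat vector on
the log-odds scale and are optimized jointly with a quasi-Newton
(L-BFGS-B) search, optionally from several seeded random starts because
the finite-mixture detection likelihood can be multimodal. Standard
errors come from a numerically differentiated Hessian of the negative
log-likelihood at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess1

from .design import DesignSet, build_designs, parameter_arrays
from .histories import HistoryStack
from .likelihood import stack_neg2_loglik
from .modelspec import FAMILIES, ModelSpec, Term, count_parameters

__all__ = ["FitOptions", "FittedModel", "neg2_loglik", "fit", "reduce_structure"]

log = logging.getLogger(__name__)

#: |logit| beyond which an estimate is flagged as on the boundary.
BOUNDARY_LOGIT = 15.0


@dataclass(frozen=True)
class FitOptions:
    starts: int = 5
    tol: float = 1e-8
    max_iter: int = 2000
    seed: int | None = None
    start_scale: float = 0.5  # sd of random perturbations around the default start
    deviation_timing: str = "origin"
    theta0_mode: str = "theta"
    compute_se: bool = True


@dataclass
class FittedModel:
    """A fitted :class:`ModelSpec`: estimates, uncertainty and fit metrics."""

    spec: ModelSpec
    estimates: np.ndarray
    std_errors: np.ndarray
    neg2ll: float
    n_params: int
    converged: bool
    relabeled: bool = False
    boundary: np.ndarray | None = None
    message: str = ""
    designs: DesignSet | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return self.neg2ll + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        # small-sample correction; n = number of routes in the fitted stack
        n = len(self.designs.route_ids) if self.designs is not None else np.nan
        k = self.n_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def coefficients(self) -> pd.DataFrame:
        """Tidy per-term table: family, term, estimate, se, boundary flag."""
        rows = []
        i = 0
        for fam in FAMILIES:
            for term in self.spec.terms(fam):
                rows.append(
                    {
                        "family": fam,
                        "term": term.label,
                        "estimate": self.estimates[i],
                        "se": self.std_errors[i],
                        "boundary": bool(self.boundary[i])
                        if self.boundary is not None
                        else False,
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def parameters(self):
        """Natural-scale parameter arrays at the estimates."""
        if self.designs is None:
            raise ValueError("fitted model carries no design set")
        return parameter_arrays(self.designs, self.estimates)


def neg2_loglik(
    stack: HistoryStack,
    beta: np.ndarray,
    spec: ModelSpec,
    covariates: pd.DataFrame | None = None,
    deviation_timing: str = "origin",
    theta0_mode: str = "theta",
) -> float:
    """-2 log-likelihood of the dataset at coefficients ``beta``.

    Convenience wrapper that rebuilds the design set per call; the
    optimizer uses a cached design set instead.
    """
    designs = build_designs(
        stack, spec, covariates, deviation_timing=deviation_timing,
        theta0_mode=theta0_mode,
    )
    return stack_neg2_loglik(stack, parameter_arrays(designs, beta))


def _objective(designs: DesignSet, obs: np.ndarray):
    def f(beta: np.ndarray) -> float:
        val = stack_neg2_loglik(obs, parameter_arrays(designs, beta))
        return val if np.isfinite(val) else 1e12

    return f


def _default_start(designs: DesignSet) -> np.ndarray:
    """Heuristic start: mild intercepts, zero covariate effects."""
    start = np.zeros(designs.n_params)
    sls = designs.slices()
    start[sls["psi"].start] = 0.5
    start[sls["epsilon"].start] = -1.0
    start[sls["gamma"].start] = -1.0
    start[sls["p1"].start] = -1.0
    start[sls["p2"].start] = 0.5
    return start


def _relabel_if_needed(designs: DesignSet, beta: np.ndarray, se: np.ndarray):
    """Order mixture classes so class 1 has the smaller detection intercept."""
    spec = designs.spec
    if spec.terms("p1") != spec.terms("p2"):
        return beta, se, False
    sls = designs.slices()
    b1, b2 = beta[sls["p1"]], beta[sls["p2"]]
    if b1[0] <= b2[0]:
        return beta, se, False
    beta = beta.copy()
    se = se.copy()
    beta[sls["p1"]], beta[sls["p2"]] = b2.copy(), b1.copy()
    se[sls["p1"]], se[sls["p2"]] = se[sls["p2"]].copy(), se[sls["p1"]].copy()
    beta[sls["pi_mix"]] = -beta[sls["pi_mix"]]
    return beta, se, True


def fit(
    stack: HistoryStack,
    spec: ModelSpec,
    covariates: pd.DataFrame | None = None,
    options: FitOptions | None = None,
    start: np.ndarray | None = None,
) -> FittedModel:
    """Maximize the likelihood of ``spec`` on ``stack``.

    Runs ``options.starts`` L-BFGS-B searches (the default start plus
    seeded random perturbations) and keeps the best optimum. Standard
    errors are ``sqrt(diag(2 * inv(H)))`` with ``H`` the numerical
    Hessian of -2LL; entries where the Hessian is not invertible are
    reported as NaN, never fabricated.
    """
    options = options or FitOptions()
    designs = build_designs(
        stack,
        spec,
        covariates,
        deviation_timing=options.deviation_timing,
        theta0_mode=options.theta0_mode,
    )
    obj = _objective(designs, stack.obs)
    rng = np.random.default_rng(options.seed)

    x0 = start if start is not None else _default_start(designs)
    if not np.isfinite(obj(x0)) or obj(x0) >= 1e12:
        log.warning("supplied start is infeasible; falling back to default start")
        x0 = _default_start(designs)
    starts = [x0]
    while len(starts) < max(1, options.starts):
        starts.append(starts[0] + options.start_scale * rng.standard_normal(designs.n_params))

    best = None
    for x0 in starts:
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            options={
                "maxiter": options.max_iter,
                "ftol": options.tol,
                "gtol": 1e-6,
                "maxfun": 10 * options.max_iter * max(designs.n_params, 1),
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    beta = np.asarray(best.x, dtype=float)
    neg2ll = float(best.fun)
    converged = bool(best.success) and neg2ll < 1e11

    se = np.full(designs.n_params, np.nan)
    if options.compute_se and converged:
        try:
            hess = approx_hess1(beta, obj)
            hess = 0.5 * (hess + hess.T)
            cov = 2.0 * np.linalg.inv(hess)
            diag = np.diag(cov)
            se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        except np.linalg.LinAlgError:
            log.warning("singular Hessian: standard errors unavailable")

    beta, se, relabeled = _relabel_if_needed(designs, beta, se)
    boundary = np.abs(beta) > BOUNDARY_LOGIT
    if not converged:
        log.warning("fit did not converge: %s", best.message)
    return FittedModel(
        spec=spec,
        estimates=beta,
        std_errors=se,
        neg2ll=neg2ll,
        n_params=count_parameters(spec),
        converged=converged,
        relabeled=relabeled,
        boundary=boundary,
        message=str(best.message),
        designs=designs,
    )


class ReductionError(RuntimeError):
    """Raised when a refit during covariate reduction fails to converge."""

    def __init__(self, message: str, path: list[tuple[str, str]]):
        super().__init__(message)
        self.path = path


def reduce_structure(
    stack: HistoryStack,
    global_spec: ModelSpec,
    covariates: pd.DataFrame | None = None,
    families_in_order=("psi", "theta", "theta_prime", "p1", "p2"),
    options: FitOptions | None = None,
) -> tuple[ModelSpec, FittedModel]:
    """Sequentially prune weakly supported covariates family by family.

    Within each family (colonization/extinction structure held fixed),
    repeatedly drops the non-intercept term with the smallest
    |estimate| / SE, refits, and stops once AIC increases, keeping the
    minimum-AIC structure. Ties break lexicographically by term order
    for determinism. Returns the reduced spec and its fit.
    """
    options = options or FitOptions()
    current = fit(stack, global_spec, covariates, options)
    if not current.converged:
        raise ReductionError("global model failed to converge", [])
    path: list[tuple[str, str]] = []

    for family in families_in_order:
        if family in ("gamma", "epsilon"):
            raise ValueError("gamma/epsilon structure is held fixed during reduction")
        while True:
            removable = _removal_candidates(current, family)
            if not removable:
                break
            term, _ = removable[0]
            candidate_spec = current.spec.drop_term(family, term)
            candidate = fit(stack, candidate_spec, covariates, options)
            if not candidate.converged:
                raise ReductionError(
                    f"refit after dropping {family}:{term.label} failed", path
                )
            path.append((family, term.label))
            log.info(
                "reduction: dropped %s:%s (AIC %.2f -> %.2f)",
                family, term.label, current.aic, candidate.aic,
            )
            if candidate.aic > current.aic:
                # AIC rose: keep the pre-drop structure and move on
                path.append((family, "<stop: AIC increased>"))
                break
            current = candidate
    return current.spec, current


def _removal_candidates(fitted: FittedModel, family: str) -> list[tuple[Term, float]]:
    """Non-intercept terms of ``family`` ordered by |estimate|/SE, ties by position."""
    sls = fitted.designs.slices()
    terms = fitted.spec.terms(family)
    est = fitted.estimates[sls[family]]
    se = fitted.std_errors[sls[family]]
    out = []
    for pos, term in enumerate(terms):
        if term.kind == "intercept":
            continue
        ratio = np.inf if not np.isfinite(se[pos]) or se[pos] == 0 else abs(est[pos]) / se[pos]
        out.append((pos, term, ratio))
    out.sort(key=lambda item: (item[2], item[0]))
    return [(term, ratio) for _, term, ratio in out]
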