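"""Synthetic survey-route data with the structure the analysis assumes.

Generates (a) a route-by-year covariate landscape — habitat fraction
with a spatial gradient and a slow decline, heat-stress hours rising,
cold-stress hours falling along a latitude-like index — and (b)
stop-level detection histories drawn from the exact generative
counterpart of the fitted likelihood: a route-level detection class, an
occupancy chain over years, an availability chain along stops, and
Bernoulli detections at available stops, with optional whole-year and
per-stop missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import decompose, standardize
from .design import build_designs, parameter_arrays
from .histories import MISSING, DetectionHistory, HistoryStack
from .likelihood import ParameterArrays
from .modelspec import ModelSpec, covariate, intercept
from .fitting import FitOptions

__all__ = ["SimulationDesign", "generate_landscape", "simulate_dataset", "default_design"]


@dataclass
class SimulationDesign:
    """Everything needed to draw one synthetic dataset deterministically."""

    n_routes: int = 300
    n_years: int = 10
    n_stops: int = 20
    first_year: int = 1997
    spec: ModelSpec | None = None
    #: True coefficients per family, aligned to ``spec``'s term order.
    coefficients: dict[str, list[float]] = field(default_factory=dict)
    # landscape settings
    habitat_base: float = 0.42
    habitat_spatial_sd: float = 0.12
    habitat_trend_per_year: float = -0.005 / 15.0  # fraction/year: ~0.5 pp over 16 years
    heat_base: float = 1.0
    heat_trend_per_year: float = 0.08
    cold_base: float = 5400.0
    cold_gradient: float = 1200.0  # increase with the latitude index
    cold_trend_per_year: float = -10.0
    noise_sd: float = 0.02
    # missingness
    missing_year_rate: float = 0.05
    missing_stop_rate: float = 0.0
    seed: int = 0
    deviation_timing: str = "origin"
    theta0_mode: str = "theta"

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)


def default_design(**overrides) -> SimulationDesign:
    """A modest recovery-test design: one covariate per process block."""
    spec = ModelSpec(
        psi=(intercept(), covariate("habitat", "first_year")),
        theta=(intercept(),),
        theta_prime=(intercept(),),
        gamma=(intercept(), covariate("cold", "mean")),
        epsilon=(intercept(), covariate("cold", "mean")),
        p1=(intercept(),),
        p2=(intercept(),),
        pi_mix=(intercept(),),
    )
    coeffs = {
        "psi": [1.2, 0.5],
        "theta": [-0.4],
        "theta_prime": [1.2],
        "gamma": [-1.2, 0.4],
        "epsilon": [-2.0, -0.4],
        "p1": [-1.0],
        "p2": [0.8],
        "pi_mix": [0.0],
    }
    design = SimulationDesign(spec=spec, coefficients=coeffs)
    for key, value in overrides.items():
        setattr(design, key, value)
    return design


def generate_landscape(design: SimulationDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Route-by-year covariate table with gradient + trend + noise.

    Routes carry a uniform latitude-like index in [0, 1]; cold-stress
    hours increase along it, habitat has independent spatial variation,
    and every covariate drifts linearly over years with small noise.
    Standardized ``*_mean`` / ``*_dev`` components are included.
    """
    rng = rng or np.random.default_rng(design.seed)
    years = design.years
    lat = rng.uniform(0.0, 1.0, design.n_routes)
    hab_route = np.clip(
        design.habitat_base + design.habitat_spatial_sd * rng.standard_normal(design.n_routes),
        0.02, 0.98,
    )
    rows = []
    for i in range(design.n_routes):
        for k, y in enumerate(years):
            hab = hab_route[i] + design.habitat_trend_per_year * k
            hab += design.noise_sd * 0.05 * rng.standard_normal()
            heat = max(
                0.0,
                design.heat_base
                + 2.0 * lat[i]
                + design.heat_trend_per_year * k
                + 0.2 * rng.standard_normal(),
            )
            cold = max(
                0.0,
                design.cold_base
                + design.cold_gradient * lat[i]
                + design.cold_trend_per_year * k
                + 15.0 * rng.standard_normal(),
            )
            rows.append(
                {
                    "route_id": f"r{i:04d}",
                    "year": int(y),
                    "habitat_frac": float(np.clip(hab, 0.0, 1.0)),
                    "heat_hours": heat,
                    "cold_hours": cold,
                }
            )
    table = pd.DataFrame(rows)
    for raw, name in (
        ("habitat_frac", "habitat"),
        ("heat_hours", "heat"),
        ("cold_hours", "cold"),
    ):
        z, _ = standardize(table[raw].to_numpy())
        table[f"{name}_z"] = z
        table = decompose(table, f"{name}_z")
        table = table.rename(
            columns={f"{name}_z_mean": f"{name}_mean", f"{name}_z_dev": f"{name}_dev"}
        )
    return table


def generate_daily_temperatures(
    design: SimulationDesign,
    n_days: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily min/max temperature table with a seasonal cycle per route.

    Intended for exercising the covariate-engineering pipeline end to
    end; warmth decreases along the latitude index.
    """
    rng = rng or np.random.default_rng(design.seed + 1)
    lat = rng.uniform(0.0, 1.0, design.n_routes)
    start = pd.Timestamp(f"{design.first_year - 1}-06-01")
    n_days = n_days or 366 + 365
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    frames = []
    for i in range(design.n_routes):
        mean = 14.0 - 6.0 * lat[i] + 11.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
        spread = 5.0 + 1.5 * rng.standard_normal(n_days).cumsum() * 0.0  # constant spread
        tmin = mean - spread + 0.8 * rng.standard_normal(n_days)
        tmax = mean + spread + 0.8 * rng.standard_normal(n_days)
        frames.append(
            pd.DataFrame(
                {
                    "route_id": f"r{i:04d}",
                    "date": dates,
                    "tmin_c": np.minimum(tmin, tmax),
                    "tmax_c": np.maximum(tmin, tmax),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def true_parameters(
    design: SimulationDesign, covariates: pd.DataFrame
) -> ParameterArrays:
    """Natural-scale parameter arrays implied by the design's coefficients."""
    if design.spec is None:
        raise ValueError("design has no model spec")
    dummy_obs = np.zeros(
        (design.n_routes, design.n_years, design.n_stops), dtype=np.int8
    )
    route_ids = sorted(covariates["route_id"].unique())
    histories = [
        DetectionHistory(rid, design.years, dummy_obs[i])
        for i, rid in enumerate(route_ids)
    ]
    stack = HistoryStack.from_histories(histories)
    designs = build_designs(
        stack,
        design.spec,
        covariates,
        deviation_timing=design.deviation_timing,
        theta0_mode=design.theta0_mode,
    )
    beta = np.concatenate(
        [np.asarray(design.coefficients[fam], dtype=float) for fam in
         ("psi", "theta", "theta_prime", "gamma", "epsilon", "p1", "p2", "pi_mix")]
    )
    return parameter_arrays(designs, beta)


def simulate_dataset(
    design: SimulationDesign,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[HistoryStack, dict]:
    """Draw detection histories from the generative model.

    Returns the stacked histories plus a truth record holding the
    landscape, per-route detection classes, latent occupancy states and
    the true coefficient vector (for recovery tests).
    """
    rng = rng or np.random.default_rng(design.seed)
    if covariates is None:
        covariates = generate_landscape(design, rng)
    params = true_parameters(design, covariates)
    R, T, S = design.n_routes, design.n_years, design.n_stops

    classes = (rng.uniform(size=R) < params.pi_mix).astype(int)  # 1 = low-detection
    # class index into params.p: 0 = low (weight pi), 1 = high
    cls_idx = np.where(classes == 1, 0, 1)

    z = np.empty((R, T), dtype=np.int8)
    z[:, 0] = rng.uniform(size=R) < params.psi
    for t in range(T - 1):
        stay = z[:, t] == 1
        pr = np.where(stay, 1.0 - params.epsilon[:, t], params.gamma[:, t])
        z[:, t + 1] = rng.uniform(size=R) < pr

    obs = np.zeros((R, T, S), dtype=np.int8)
    p = params.p  # (2, R|1, T, S)
    p_route = p[cls_idx, np.arange(R) if p.shape[1] > 1 else 0]  # (R, T, S)
    for t in range(T):
        occ = z[:, t] == 1
        avail = np.zeros((R, S), dtype=bool)
        avail[:, 0] = rng.uniform(size=R) < params.theta0
        for s in range(1, S):
            pr = np.where(avail[:, s - 1], params.theta_prime, params.theta)
            avail[:, s] = rng.uniform(size=R) < pr
        detect = (rng.uniform(size=(R, S)) < p_route[:, t, :]) & avail
        obs[:, t, :] = (detect & occ[:, None]).astype(np.int8)

    if design.missing_year_rate > 0:
        drop = rng.uniform(size=(R, T)) < design.missing_year_rate
        obs[drop] = MISSING
    if design.missing_stop_rate > 0:
        drop = rng.uniform(size=(R, T, S)) < design.missing_stop_rate
        obs[drop] = MISSING

    route_ids = sorted(covariates["route_id"].unique())
    histories = [
        DetectionHistory(rid, design.years, obs[i]) for i, rid in enumerate(route_ids)
    ]
    stack = HistoryStack.from_histories(histories)
    truth = {
        "covariates": covariates,
        "classes": classes,
        "z": z,
        "params": params,
        "coefficients": {k: list(v) for k, v in design.coefficients.items()},
    }
    return stack, truth


def fit_options_for(design: SimulationDesign, **overrides) -> FitOptions:
    """Fit options consistent with the design's conventions."""
    base = dict(
        deviation_timing=design.deviation_timing,
        theta0_mode=design.theta0_mode,
        seed=design.seed,
    )
    base.update(overrides)
    return FitOptions(**base)
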