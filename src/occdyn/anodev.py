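"""Six-model colonization/extinction set, likelihood-ratio tests and
deviance partitioning.

The model set varies only the gamma/epsilon structure while every other
family is frozen at a shared (already reduced) structure:

1. null — intercepts only;
2. global/full — year dummies plus spatial covariate means;
3. spatial — spatial covariate means only;
4. spatial + climate deviations;
5. spatial + habitat deviation;
6. spatial + climate and habitat deviations.

The explained-deviance ratio compares a covariate model's improvement
over the spatial model to the improvement achieved by the fully
year-varying model; because models 4–6 are not strictly nested within
model 2, the ratio may exceed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .fitting import FittedModel
from .modelspec import ModelSpec, Term, covariate, intercept, year_dummies

__all__ = [
    "build_model_set",
    "rdev2",
    "likelihood_ratio_test",
    "anodev_table",
    "LRTResult",
    "MODEL_IDS",
]

MODEL_IDS = (1, 2, 3, 4, 5, 6)

#: Covariate-flag columns of the summary table, in display order.
FLAG_COLUMNS = (
    "intercept",
    "average_habitat",
    "average_climate",
    "habitat_deviation",
    "climate_deviation",
    "year_effect",
)

_MODEL_FLAGS = {
    1: {"intercept"},
    2: {"intercept", "average_habitat", "average_climate", "year_effect"},
    3: {"intercept", "average_habitat", "average_climate"},
    4: {"intercept", "average_habitat", "average_climate", "climate_deviation"},
    5: {"intercept", "average_habitat", "average_climate", "habitat_deviation"},
    6: {
        "intercept",
        "average_habitat",
        "average_climate",
        "habitat_deviation",
        "climate_deviation",
    },
}


def build_model_set(
    base_spec: ModelSpec,
    years,
    habitat: list[str] | None = None,
    climate: list[str] | None = None,
) -> dict[int, ModelSpec]:
    """Models 1–6 as variations of ``base_spec``'s gamma/epsilon blocks.

    ``habitat`` and ``climate`` are covariate base names (defaults:
    ``["habitat"]`` and ``["heat", "cold"]``); each must resolve to
    ``*_mean`` / ``*_dev`` components in the covariate table. All other
    families are inherited from ``base_spec`` unchanged.
    """
    habitat = habitat if habitat is not None else ["habitat"]
    climate = climate if climate is not None else ["heat", "cold"]
    if not habitat or not climate:
        raise ValueError("habitat and climate covariate name lists must be non-empty")
    years = [int(y) for y in years]

    means = [covariate(n, "mean") for n in habitat + climate]
    hab_dev = [covariate(n, "deviation") for n in habitat]
    clim_dev = [covariate(n, "deviation") for n in climate]
    dummies = year_dummies(years[2:])  # baseline: the first transition

    blocks: dict[int, list[Term]] = {
        1: [intercept()],
        2: [intercept()] + dummies + means,
        3: [intercept()] + means,
        4: [intercept()] + means + clim_dev,
        5: [intercept()] + means + hab_dev,
        6: [intercept()] + means + hab_dev + clim_dev,
    }
    out = {}
    for mid, block in blocks.items():
        out[mid] = base_spec.with_family("gamma", block).with_family("epsilon", block)
    return out


def rdev2(dev_null: float, dev_cov: float, dev_full: float) -> float:
    """Share of the null-to-full deviance drop achieved by the covariate model.

    ``(dev_null - dev_cov) / (dev_null - dev_full)``; deviances may be
    -2LL values or offsets from any common reference: the ratio is
    invariant to a shared additive constant (and to a global sign flip,
    so tabulated offsets relative to the full model work unchanged).

    A ``dev_null < dev_full`` ordering is flagged with a warning — it
    violates the partitioning premise for genuine deviances, but is
    expected when the inputs are offsets measured from the full model.
    """
    denom = dev_null - dev_full
    if denom == 0.0:
        raise ValueError("dev_null equals dev_full: explained deviance undefined")
    if denom < 0.0:
        warnings.warn(
            f"dev_null ({dev_null}) below dev_full ({dev_full}): either the "
            "inputs are full-model-relative offsets or the partitioning "
            "premise is violated",
            stacklevel=2,
        )
    return (dev_null - dev_cov) / denom


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float


def likelihood_ratio_test(
    fit_reduced: FittedModel, fit_general: FittedModel, tol: float = 1e-6
) -> LRTResult:
    """Chi-square test of a reduced model against a nesting general model."""
    if not (fit_reduced.converged and fit_general.converged):
        raise ValueError("both fits must have converged")
    df = fit_general.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the general model")
    stat = fit_reduced.neg2ll - fit_general.neg2ll
    if stat < -tol:
        raise ValueError(
            f"likelihood ratio statistic {stat:.6g} is negative: models not nested "
            "or fits not at their optima"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return LRTResult(chi2=stat, df=0, p_value=1.0)
    return LRTResult(chi2=stat, df=df, p_value=float(chi2_dist.sf(stat, df)))


def anodev_table(fits: dict[int, FittedModel], percent: bool = True) -> pd.DataFrame:
    """Summary of the six-model set: -2LL offsets and explained deviance.

    Offsets are relative to model 2 (so model 2 is 0 and better-fitting
    models are closer to 0); explained deviance uses model 3 as the null
    and model 2 as the full model. Model 1 is reported without a ratio.
    """
    if set(fits) != set(MODEL_IDS):
        raise ValueError(f"need exactly models {MODEL_IDS}, got {sorted(fits)}")
    ref = fits[2].neg2ll
    dev = {m: fits[m].neg2ll for m in MODEL_IDS}
    offsets = {m: ref - dev[m] for m in MODEL_IDS}  # <= 0 for worse models
    if abs(dev[3] - dev[2]) < 1e-12:
        raise ValueError("model 3 and model 2 deviances coincide; table degenerate")

    rows = []
    for m in (2, 6, 4, 5, 3, 1):
        row = {"model": m}
        for flag in FLAG_COLUMNS:
            row[flag] = flag in _MODEL_FLAGS[m]
        row["delta_neg2ll"] = offsets[m]
        if m == 1:
            row["rdev2"] = np.nan
        else:
            val = rdev2(dev[3], dev[m], dev[2])
            row["rdev2"] = 100.0 * val if percent else val
        row["n_params"] = fits[m].n_params
        row["aic"] = fits[m].aic
        rows.append(row)
    return pd.DataFrame(rows)
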