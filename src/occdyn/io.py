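"""CSV interchange for detection histories, covariates and results.

Detection histories: one row per route-year with columns ``route_id,
year, stop_01 .. stop_NN`` and values ``0``, ``1`` or ``NA``. Stops are
1-based in files and 0-based in memory. Missing years may be absent
rows (they are filled in as all-missing) or rows of all-``NA``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .histories import MISSING, DetectionHistory, HistoryStack

__all__ = [
    "read_detections",
    "write_detections",
    "read_covariates",
    "write_covariates",
]

log = logging.getLogger(__name__)

NA_TOKEN = "NA"


def _stop_columns(n_stops: int) -> list[str]:
    return [f"stop_{i:02d}" for i in range(1, n_stops + 1)]


def read_detections(path: str | Path) -> HistoryStack:
    """Load a detection-history CSV into a stacked collection.

    Validates the schema (values in {0, 1, NA}, no duplicate
    route-years, rectangular stop block) and pads every route onto the
    common year span with all-missing rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"route_id": str}, na_values=[NA_TOKEN], keep_default_na=False)
    required = {"route_id", "year"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {required - set(df.columns)}")
    stop_cols = [c for c in df.columns if c.startswith("stop_")]
    if not stop_cols:
        raise ValueError(f"{path}: no stop_* columns found")
    stop_cols = sorted(stop_cols)

    dup = df.duplicated(subset=["route_id", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate route-year row (route {row['route_id']}, "
            f"year {row['year']})"
        )
    vals = df[stop_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid value {vals[i, j]!r} in column {stop_cols[j]} "
            f"of row {i + 2} (route {df.iloc[i]['route_id']})"
        )

    years = np.arange(int(df["year"].min()), int(df["year"].max()) + 1)
    histories = []
    for route_id, sub in df.groupby("route_id", sort=True):
        obs = np.full((years.size, len(stop_cols)), MISSING, dtype=np.int8)
        for _, row in sub.iterrows():
            t = int(row["year"]) - years[0]
            v = row[stop_cols].to_numpy(dtype=float)
            obs[t] = np.where(np.isnan(v), MISSING, v).astype(np.int8)
        histories.append(DetectionHistory(str(route_id), years, obs))
    stack = HistoryStack.from_histories(histories)
    pct_missing = float((stack.obs == MISSING).mean()) * 100
    log.info(
        "read %s: %d routes, %d years, %d stops, %.1f%% missing",
        path, stack.n_routes, stack.n_years, stack.n_stops, pct_missing,
    )
    return stack


def write_detections(stack: HistoryStack, path: str | Path) -> None:
    path = Path(path)
    stop_cols = _stop_columns(stack.n_stops)
    rows = []
    for h in stack:
        for t, year in enumerate(h.years):
            row = {"route_id": h.route_id, "year": int(year)}
            for j, col in enumerate(stop_cols):
                v = int(h.obs[t, j])
                row[col] = NA_TOKEN if v == MISSING else v
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


COVARIATE_COLUMNS = [
    "route_id", "year", "habitat_frac", "heat_hours", "cold_hours",
    "habitat_mean", "habitat_dev", "heat_mean", "heat_dev",
    "cold_mean", "cold_dev",
]


def read_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"route_id": str})
    missing = {"route_id", "year"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: covariate table lacks columns {missing}")
    return df


def write_covariates(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in COVARIATE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols and not c.endswith("_z")]
    table[cols + extra].to_csv(Path(path), index=False)
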