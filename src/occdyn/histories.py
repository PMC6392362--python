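"""Stop-level detection history containers.

A detection history is the per-route observation record: for each
calendar year, a vector of one observation per roadside stop, each 0
(no detection), 1 (detection) or missing. Never-surveyed years are
rows of all-missing values so that the year axis stays contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing (not surveyed) stop observation.
MISSING: int = -1


@dataclass
class DetectionHistory:
    """Binary detection/nondetection record for one survey route.

    Parameters
    ----------
    route_id
        Identifier of the route.
    years
        Strictly increasing, gap-free calendar years (gaps must be
        represented by all-missing rows, not absent rows).
    obs
        Integer matrix of shape ``(n_years, n_stops)`` with entries in
        ``{0, 1, MISSING}``.
    """

    route_id: str
    years: np.ndarray
    obs: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.obs = np.asarray(self.obs, dtype=np.int8)
        if self.years.ndim != 1 or self.years.size == 0:
            raise ValueError(f"route {self.route_id}: empty or non-1d year axis")
        if self.obs.ndim != 2 or self.obs.shape[0] != self.years.size:
            raise ValueError(
                f"route {self.route_id}: obs shape {self.obs.shape} does not "
                f"match {self.years.size} years"
            )
        if not np.all(np.diff(self.years) == 1):
            raise ValueError(
                f"route {self.route_id}: years must be consecutive; gaps are "
                "all-missing rows, not absent rows"
            )
        bad = ~np.isin(self.obs, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"route {self.route_id}: invalid observation {self.obs[i, j]} "
                f"at year {self.years[i]}, stop {j + 1}"
            )

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_stops(self) -> int:
        return self.obs.shape[1]

    def surveyed(self) -> np.ndarray:
        """Boolean mask over years: at least one non-missing stop."""
        return (self.obs != MISSING).any(axis=1)

    def detected(self) -> np.ndarray:
        """Boolean mask over years: at least one detection."""
        return (self.obs == 1).any(axis=1)


@dataclass
class HistoryStack:
    """A collection of detection histories on a common year/stop grid.

    The likelihood machinery is vectorized over routes, which requires
    every route to share the same year span and stop count.
    """

    route_ids: list[str]
    years: np.ndarray
    obs: np.ndarray  # (n_routes, n_years, n_stops)
    histories: list[DetectionHistory] = field(repr=False, default_factory=list)

    @classmethod
    def from_histories(cls, histories: list[DetectionHistory]) -> "HistoryStack":
        if not histories:
            raise ValueError("no detection histories supplied")
        years = histories[0].years
        n_stops = histories[0].n_stops
        for h in histories:
            if not np.array_equal(h.years, years):
                raise ValueError(
                    f"route {h.route_id}: year axis differs from route "
                    f"{histories[0].route_id}"
                )
            if h.n_stops != n_stops:
                raise ValueError(
                    f"route {h.route_id}: {h.n_stops} stops, expected {n_stops}"
                )
        obs = np.stack([h.obs for h in histories])
        return cls(
            route_ids=[h.route_id for h in histories],
            years=years.copy(),
            obs=obs,
            histories=list(histories),
        )

    @property
    def n_routes(self) -> int:
        return self.obs.shape[0]

    @property
    def n_years(self) -> int:
        return self.obs.shape[1]

    @property
    def n_stops(self) -> int:
        return self.obs.shape[2]

    def __len__(self) -> int:
        return self.n_routes

    def __iter__(self):
        return iter(self.histories)
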