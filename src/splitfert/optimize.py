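"""Exhaustive split-fertilization timing search and surface analytics.

Every admissible timing pair (t1, t2) with t_min <= t1 <= t2 <= t_max on a
regular grid is simulated; the resulting uptake surface supports the
precipitation-optimal pair, the close-to-optimal set (within 5% of the
maximum), a neighborhood "stability" metric (worst-case uptake within
+/- r days of a pair, as a proportion of the pair's own uptake) and the
season-level mean stability over close-to-optimal pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from splitfert.column import FertilizerSchedule, ModelConfig, simulate_season
from splitfert.precip import SeasonForcing


@dataclass(frozen=True)
class TimingGrid:
    """Regular grid of admissible (t1, t2) pairs, t_min <= t1 <= t2 <= t_max."""

    resolution: float = 1.2  # days
    t_max: float = 70.0
    t_min: float | None = None  # defaults to resolution (no day-0 application)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        tmin = self.resolution if self.t_min is None else self.t_min
        if tmin > self.t_max:
            raise ValueError(f"t_min {tmin} exceeds t_max {self.t_max}")
        object.__setattr__(self, "t_min", tmin)

    @property
    def points(self) -> np.ndarray:
        """Grid points t_min, t_min + resolution, ... <= t_max."""
        n = int(np.floor((self.t_max - self.t_min) / self.resolution + 1e-9)) + 1
        return self.t_min + self.resolution * np.arange(n)

    @property
    def pairs(self) -> list[tuple[float, float]]:
        """All admissible pairs in deterministic lexicographic order."""
        pts = self.points
        return [(float(pts[i]), float(pts[j])) for i in range(len(pts)) for j in range(i, len(pts))]

    def __len__(self) -> int:
        m = len(self.points)
        return m * (m + 1) // 2


def enumerate_pairs(grid: TimingGrid) -> list[tuple[float, float]]:
    """Deterministic ordered list of admissible (t1, t2) pairs."""
    return grid.pairs


@dataclass(frozen=True)
class UptakeSurface:
    """Uptake (kg N ha^-1) for every admissible pair of one season."""

    grid: TimingGrid
    pairs: tuple[tuple[float, float], ...]
    uptake: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.uptake, dtype=float)
        if len(u) != len(self.pairs):
            raise ValueError("uptake length must match number of pairs")
        if len(u) == 0:
            raise ValueError("empty surface")
        if (u < 0).any() or np.isnan(u).any():
            raise ValueError("uptake values must be finite and >= 0")
        object.__setattr__(self, "uptake", u)

    def lookup(self, pair: tuple[float, float]) -> float:
        idx = self._index(pair)
        return float(self.uptake[idx])

    def _index(self, pair: tuple[float, float]) -> int:
        for i, p in enumerate(self.pairs):
            if abs(p[0] - pair[0]) < 1e-9 and abs(p[1] - pair[1]) < 1e-9:
                return i
        raise KeyError(f"pair {pair} not on grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t1": [p[0] for p in self.pairs],
                "t2": [p[1] for p in self.pairs],
                "uptake_kg_ha": self.uptake,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, grid: TimingGrid, year: int | None = None) -> "UptakeSurface":
        df = pd.read_csv(path)
        pairs = tuple(zip(df["t1"].astype(float), df["t2"].astype(float)))
        return cls(grid=grid, pairs=pairs, uptake=df["uptake_kg_ha"].values, year=year)


@dataclass(frozen=True)
class StabilityConfig:
    radius_r: float = 2.4  # days

    def __post_init__(self) -> None:
        if self.radius_r < 0:
            raise ValueError("radius_r must be >= 0")


@dataclass(frozen=True)
class SeasonOptimum:
    year: int | None
    best_pair: tuple[float, float]
    max_uptake: float
    close_set: tuple[tuple[float, float], ...]
    n_close: int
    median_t1: float
    median_t2: float
    stability: float


def compute_surface(
    forcing: SeasonForcing,
    grid: TimingGrid,
    config: ModelConfig = ModelConfig(),
    uptake_fn: Callable[[SeasonForcing, FertilizerSchedule], float] | None = None,
) -> UptakeSurface:
    """Simulate every admissible timing pair of one season.

    Each pair is an independent model instance (results do not depend on
    evaluation order).  ``uptake_fn`` may replace the full simulator (e.g.
    a stub in tests); the default runs :func:`simulate_season`.
    """
    pairs = tuple(grid.pairs)
    if uptake_fn is None:
        def uptake_fn(f: SeasonForcing, s: FertilizerSchedule) -> float:
            return simulate_season(f, s, config).uptake_n

    uptakes = np.empty(len(pairs))
    for i, (t1, t2) in enumerate(pairs):
        schedule = FertilizerSchedule(t1=t1, t2=t2, t_max=grid.t_max)
        uptakes[i] = uptake_fn(forcing, schedule)
    return UptakeSurface(grid=grid, pairs=pairs, uptake=uptakes, year=forcing.year)


def find_optimum(surface: UptakeSurface) -> tuple[tuple[float, float], float]:
    """Global maximum of the surface; ties break to the lexicographically
    earliest (t1, t2), favoring earlier application."""
    best = float(np.max(surface.uptake))
    for pair, u in zip(surface.pairs, surface.uptake):  # pairs are lex-ordered
        if u == best:
            return pair, best
    raise AssertionError("unreachable")


def close_to_optimal(surface: UptakeSurface, tol: float = 0.05) -> list[tuple[float, float]]:
    """Pairs achieving uptake within ``tol`` (default 5%) of the maximum."""
    _, best = find_optimum(surface)
    cutoff = (1.0 - tol) * best
    return [p for p, u in zip(surface.pairs, surface.uptake) if u >= cutoff]


def stability(
    surface: UptakeSurface,
    pair: tuple[float, float],
    cfg: StabilityConfig = StabilityConfig(),
) -> float:
    """Worst-case uptake within +/- r days of ``pair``, as a proportion.

    The neighborhood S_r is the Chebyshev box |t1 - t1*| <= r,
    |t2 - t2*| <= r intersected with the admissible triangle (clipped at
    grid edges); the returned value is min uptake over S_r divided by the
    uptake at ``pair`` and lies in (0, 1] whenever the center uptake is
    positive.
    """
    center = surface.lookup(pair)  # KeyError if off grid
    if center <= 0:
        raise ValueError("stability undefined for zero uptake at the center pair")
    r = cfg.radius_r + 1e-9
    t1s, t2s = pair
    neigh = [
        u
        for (a, b), u in zip(surface.pairs, surface.uptake)
        if abs(a - t1s) <= r and abs(b - t2s) <= r
    ]
    return float(min(neigh) / center)


def season_stability(
    surface: UptakeSurface,
    cfg: StabilityConfig = StabilityConfig(),
    tol: float = 0.05,
) -> float:
    """Mean stability over the close-to-optimal set of the season."""
    close = close_to_optimal(surface, tol)
    return float(np.mean([stability(surface, p, cfg) for p in close]))


def summarize_surface(
    surface: UptakeSurface,
    cfg: StabilityConfig = StabilityConfig(),
    tol: float = 0.05,
) -> SeasonOptimum:
    """Optimum, close-to-optimal set, medians and stability of one surface.

    Medians of t1 and t2 are taken independently over close-set members
    (midpoint convention for even-sized sets, i.e. numpy's median).
    """
    best_pair, best = find_optimum(surface)
    close = close_to_optimal(surface, tol)
    return SeasonOptimum(
        year=surface.year,
        best_pair=best_pair,
        max_uptake=best,
        close_set=tuple(close),
        n_close=len(close),
        median_t1=float(np.median([p[0] for p in close])),
        median_t2=float(np.median([p[1] for p in close])),
        stability=season_stability(surface, cfg, tol),
    )
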