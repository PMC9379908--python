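"""Orchestration of the full multi-season study.

For every growing season in a precipitation record: build the uptake
surface, locate the precipitation-optimal pair, close-to-optimal set and
stability; aggregate yearly series into decadal medians and 11-year rolling
means; and correlate precipitation metrics (seasonal mean daily rate, mean
1-month SPI) with maximum uptake and the median close-to-optimal timings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from splitfert.column import FertilizerSchedule, ModelConfig, simulate_season
from splitfert.optimize import (
    SeasonOptimum,
    StabilityConfig,
    TimingGrid,
    UptakeSurface,
    compute_surface,
    summarize_surface,
)
from splitfert.precip import (
    DailyPrecipRecord,
    SpiConfig,
    extract_season,
    heavy_day_fraction,
    heavy_rain_threshold,
    mean_daily_rate,
    rolling_mean,
    season_mean_spi,
    spi,
)


@dataclass(frozen=True)
class StudyConfig:
    grid: TimingGrid = field(default_factory=TimingGrid)
    model: ModelConfig = field(default_factory=ModelConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    close_tol: float = 0.05
    spi: SpiConfig = field(default_factory=SpiConfig)
    ref_years: tuple[int, int] | None = None  # heavy-rain reference window
    rolling_width: int = 11
    years: tuple[int, ...] | None = None  # default: every complete season


@dataclass(frozen=True)
class StudyReport:
    seasons: pd.DataFrame  # one row per year
    decades: pd.DataFrame
    correlations: pd.DataFrame
    surfaces: dict[int, UptakeSurface]
    optima: dict[int, SeasonOptimum]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.seasons.to_csv(out / "seasons.csv", index=False)
        self.decades.to_csv(out / "decades.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        for year, surf in self.surfaces.items():
            surf.to_csv(out / f"surface_{year}.csv")


def pearson(x, y) -> float:
    """Product-moment correlation; NaN when undefined (n < 3 or zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def run_study(record: DailyPrecipRecord, config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the per-season optimization and aggregation over a whole record.

    Deterministic given the record and config.  Any season's solver failure
    aborts the study with the season context attached.
    """
    years = list(config.years) if config.years is not None else record.years
    spis = spi(record, config.spi)

    threshold = None
    if config.ref_years is not None:
        threshold = heavy_rain_threshold(record, config.ref_years)

    rows = []
    surfaces: dict[int, UptakeSurface] = {}
    optima: dict[int, SeasonOptimum] = {}
    for year in years:
        forcing = extract_season(record, year)
        surface = compute_surface(forcing, config.grid, config.model)
        opt = summarize_surface(surface, config.stability, config.close_tol)
        surfaces[year] = surface
        optima[year] = opt
        rows.append(
            {
                "year": year,
                "mean_rate_mm_d": mean_daily_rate(forcing),
                "mean_spi": season_mean_spi(spis, year),
                "max_uptake_kg_ha": opt.max_uptake,
                "opt_t1": opt.best_pair[0],
                "opt_t2": opt.best_pair[1],
                "median_t1": opt.median_t1,
                "median_t2": opt.median_t2,
                "n_close": opt.n_close,
                "stability": opt.stability,
            }
        )
    seasons = pd.DataFrame(rows)

    decades = _decade_table(record, seasons, surfaces, optima, threshold, config)
    correlations = _correlation_table(seasons, config.rolling_width)
    return StudyReport(
        seasons=seasons,
        decades=decades,
        correlations=correlations,
        surfaces=surfaces,
        optima=optima,
    )


def _decade_table(
    record: DailyPrecipRecord,
    seasons: pd.DataFrame,
    surfaces: dict[int, UptakeSurface],
    optima: dict[int, SeasonOptimum],
    threshold: float | None,
    config: StudyConfig,
) -> pd.DataFrame:
    rows = []
    years = seasons["year"].tolist()
    for d0 in sorted({(y // 10) * 10 for y in years}):
        dec_years = [y for y in years if d0 <= y < d0 + 10]
        # pool all close-to-optimal pairs and their uptakes over the decade
        all_uptakes: list[float] = []
        all_t1: list[float] = []
        all_t2: list[float] = []
        for y in dec_years:
            surf = surfaces[y]
            cutoff = (1.0 - config.close_tol) * optima[y].max_uptake
            for p, u in zip(surf.pairs, surf.uptake):
                if u >= cutoff:
                    all_uptakes.append(float(u))
                    all_t1.append(p[0])
                    all_t2.append(p[1])
        sub = seasons[seasons["year"].isin(dec_years)]
        row = {
            "decade": f"{d0}s",
            "start_year": d0,
            "n_years": len(dec_years),
            "median_close_uptake_kg_ha": float(np.median(all_uptakes)),
            "median_close_t1": float(np.median(all_t1)),
            "median_close_t2": float(np.median(all_t2)),
            "mean_n_close": float(sub["n_close"].mean()),
            "median_max_uptake_kg_ha": float(sub["max_uptake_kg_ha"].median()),
        }
        if threshold is not None:
            forcings = [extract_season(record, y) for y in dec_years]
            row["heavy_day_pct"] = 100.0 * heavy_day_fraction(forcings, threshold)
        rows.append(row)
    return pd.DataFrame(rows)


def _correlation_table(seasons: pd.DataFrame, width: int) -> pd.DataFrame:
    metrics = ["mean_rate_mm_d", "mean_spi"]
    targets = ["max_uptake_kg_ha", "median_t1", "median_t2", "n_close"]
    rows = []
    n = len(seasons)
    for m in metrics:
        for t in targets:
            r_raw = pearson(seasons[m], seasons[t]) if n >= 3 else float("nan")
            if n >= 3:
                r_roll = pearson(
                    rolling_mean(seasons[m].values, width),
                    rolling_mean(seasons[t].values, width),
                )
            else:
                r_roll = float("nan")
            rows.append({"metric": m, "target": t, "r_raw": r_raw, "r_rolling": r_roll, "n": n})
    # co-movement of the two timings
    if n >= 3:
        rows.append(
            {
                "metric": "median_t1",
                "target": "median_t2",
                "r_raw": pearson(seasons["median_t1"], seasons["median_t2"]),
                "r_rolling": pearson(
                    rolling_mean(seasons["median_t1"].values, width),
                    rolling_mean(seasons["median_t2"].values, width),
                ),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def fixed_strategy_efficiency(
    report: StudyReport, fixed_pair: tuple[float, float]
) -> float:
    """Mean percentage of each season's maximum achieved by one fixed pair.

    Emulates a farmer who always fertilizes on the same (t1, t2): for every
    season, uptake at the fixed pair divided by that season's maximum
    uptake; returns the mean over seasons as a percentage.
    """
    ratios = []
    for year, surface in report.surfaces.items():
        u = surface.lookup(fixed_pair)  # KeyError if off grid
        best = report.optima[year].max_uptake
        ratios.append(u / best)
    if not ratios:
        raise ValueError("report contains no surfaces")
    return 100.0 * float(np.mean(ratios))


def leaching_rainfall_correlation(
    record: DailyPrecipRecord,
    schedule: FertilizerSchedule,
    config: ModelConfig = ModelConfig(),
    window_days: int = 21,
    years: list[int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Correlate seasonal N leaching with post-fertilization rainfall.

    For each season the column is run with the fixed ``schedule``; the
    cumulative rainfall in the ``window_days`` after the second (final)
    application is correlated against leached N across seasons.  Returns
    (Pearson r, per-season table); r is NaN when undefined.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    years = years if years is not None else record.years
    rows = []
    for year in years:
        forcing = extract_season(record, year)
        res = simulate_season(forcing, schedule, config)
        d0 = int(np.floor(schedule.t2))
        d1 = min(len(forcing.rain), d0 + window_days)
        rows.append(
            {
                "year": year,
                "leached_n_kg_ha": res.leached_n,
                "post_fert_rain_mm": float(np.sum(forcing.rain[d0:d1])),
            }
        )
    df = pd.DataFrame(rows)
    r = pearson(df["post_fert_rain_mm"], df["leached_n_kg_ha"])
    return r, df
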