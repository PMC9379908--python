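"""Precipitation records, growing-season windows and precipitation analytics.

The growing season is 1 March - 30 June (122 days; the window contains no
leap day).  Analytics follow standard drought-index practice: mean daily
rates per season, centered rolling means across years, heavy-rainfall days
relative to a reference-period 99th percentile, and the 1-month
Standardized Precipitation Index (SPI) from a per-calendar-month gamma
maximum-likelihood fit with zero-inflation handling, classified into
drought severity bands at 0 / -1 / -1.5 / -2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SEASON_MONTHS = (3, 4, 5, 6)
SEASON_LENGTH = 122  # 31 + 30 + 31 + 30 days, March through June

DROUGHT_CLASSES = ("none", "mild", "moderate", "severe", "extreme")


@dataclass(frozen=True)
class DailyPrecipRecord:
    """Date-indexed daily rainfall in mm day^-1.

    ``series`` is a pandas Series with a strictly increasing DatetimeIndex;
    all values must be non-negative.  The record may contain only in-season
    days (March-June), which is all the analysis uses.
    """

    series: pd.Series

    def __post_init__(self) -> None:
        s = self.series
        if not isinstance(s.index, pd.DatetimeIndex):
            raise ValueError("record index must be datetime")
        if not s.index.is_monotonic_increasing or s.index.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        if (s.values < 0).any():
            raise ValueError("negative rainfall values are not allowed")

    @property
    def years(self) -> list[int]:
        """Years with at least one in-season day present."""
        mask = self.series.index.month.isin(SEASON_MONTHS)
        return sorted(set(self.series.index[mask].year.tolist()))

    def __len__(self) -> int:
        return len(self.series)


@dataclass(frozen=True)
class SeasonForcing:
    """One growing season: 122 ordered daily rates (mm day^-1) and its year."""

    year: int
    rain: np.ndarray

    def __post_init__(self) -> None:
        rain = np.asarray(self.rain, dtype=float)
        if rain.shape != (SEASON_LENGTH,):
            raise ValueError(
                f"season must have exactly {SEASON_LENGTH} days, got {rain.shape}"
            )
        if (rain < 0).any():
            raise ValueError("negative rainfall in season forcing")
        object.__setattr__(self, "rain", rain)


@dataclass(frozen=True)
class SpiConfig:
    """Configuration of the SPI computation.

    aggregation_months: width of the rainfall aggregation window (the study
        uses 1 month, the shortest viable scale for fertilization timing).
    fit_years: inclusive (start, end) year range used for the gamma fit;
        None fits on the full record.
    zero_inflated: mix a point mass at zero into the fitted distribution,
        SPI = Phi^-1(q + (1 - q) G(x)) with q the zero fraction.
    min_fit_years: below this many years the fit is flagged as small-sample.
    """

    aggregation_months: int = 1
    fit_years: tuple[int, int] | None = None
    zero_inflated: bool = True
    min_fit_years: int = 20

    def __post_init__(self) -> None:
        if self.aggregation_months < 1:
            raise ValueError("aggregation_months must be >= 1")


@dataclass(frozen=True)
class SpiValue:
    year: int
    month: int
    spi: float  # standard deviations; NaN if undefined
    drought_class: str

    def __post_init__(self) -> None:
        if self.drought_class not in DROUGHT_CLASSES and self.drought_class != "missing":
            raise ValueError(f"unknown drought class {self.drought_class!r}")


@dataclass(frozen=True)
class DecadeSummary:
    decade: str  # e.g. "1950s"
    start_year: int
    heavy_day_pct: float
    moderate_plus_drought_pct: float
    severe_plus_drought_pct: float
    n_years: int


# ---------------------------------------------------------------------------
# I/O


def write_daily_csv(record: DailyPrecipRecord, path: str | Path) -> None:
    """Write a record as CSV with columns ``date, rain_mm`` (ISO-8601 dates)."""
    df = pd.DataFrame(
        {"date": record.series.index.strftime("%Y-%m-%d"), "rain_mm": record.series.values}
    )
    df.to_csv(path, index=False)


def read_daily_csv(path: str | Path) -> DailyPrecipRecord:
    """Read a ``date, rain_mm`` CSV into a validated record.

    Raises ValueError on unparseable dates, non-numeric or negative rain.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "rain_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
    try:
        idx = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in {path}: {exc}") from exc
    rain = pd.to_numeric(df["rain_mm"], errors="raise").astype(float)
    if rain.isna().any():
        raise ValueError("missing rain_mm values")
    series = pd.Series(rain.values, index=pd.DatetimeIndex(idx), name="rain_mm")
    return DailyPrecipRecord(series)


# ---------------------------------------------------------------------------
# Season windowing


def season_index(year: int) -> pd.DatetimeIndex:
    """The 122 calendar days of the growing season of ``year``."""
    return pd.date_range(f"{year}-03-01", f"{year}-06-30", freq="D")


def extract_season(record: DailyPrecipRecord, year: int) -> SeasonForcing:
    """Slice the 1 March - 30 June window of ``year`` out of a record.

    Raises ValueError naming the missing days if the window is incomplete.
    """
    idx = season_index(year)
    sub = record.series.reindex(idx)
    if sub.isna().any():
        missing = sub.index[sub.isna()]
        raise ValueError(
            f"season {year} incomplete: missing {len(missing)} day(s), "
            f"first gap {missing[0].date()}"
        )
    return SeasonForcing(year=year, rain=sub.values)


def mean_daily_rate(season: SeasonForcing) -> float:
    """Arithmetic mean of the season's 122 daily rates, mm day^-1."""
    return float(np.mean(season.rain))


def rolling_mean(values: Sequence[float], width: int = 11) -> np.ndarray:
    """Centered rolling mean over a yearly series.

    Windows are truncated symmetrically at the ends (the half-width shrinks
    near the boundary so the output covers the full series).  ``width`` must
    be odd.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("rolling-mean width must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    half = width // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        h = min(half, i, len(x) - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


# ---------------------------------------------------------------------------
# Heavy rainfall


def heavy_rain_threshold(
    record: DailyPrecipRecord, ref_years: tuple[int, int] = (1950, 1979)
) -> float:
    """99th percentile of in-season daily rainfall over a reference period.

    A heavy-rainfall day is any day with rain at or above this threshold.
    Uses linear interpolation of the empirical CDF (numpy default).
    """
    start, end = ref_years
    days = []
    for year in range(start, end + 1):
        days.append(extract_season(record, year).rain)
    pool = np.concatenate(days)
    if pool.size == 0:
        raise ValueError("empty reference period")
    return float(np.percentile(pool, 99.0))


def heavy_day_fraction(seasons: Iterable[SeasonForcing], threshold: float) -> float:
    """Fraction of in-season days at or above the heavy-rain threshold."""
    rains = np.concatenate([s.rain for s in seasons])
    if rains.size == 0:
        raise ValueError("no days supplied")
    return float(np.mean(rains >= threshold))


# ---------------------------------------------------------------------------
# SPI


def monthly_totals(record: DailyPrecipRecord) -> pd.DataFrame:
    """In-season monthly rainfall totals: columns year, month, total_mm."""
    s = record.series
    mask = s.index.month.isin(SEASON_MONTHS)
    s = s[mask]
    keys = [
        pd.Index(s.index.year, name="year"),
        pd.Index(s.index.month, name="month"),
    ]
    df = s.groupby(keys).sum().reset_index()
    df.columns = ["year", "month", "total_mm"]
    return df


def classify_drought(spi_value: float) -> str:
    """Drought class from an SPI value.

    Bands: 0 >= SPI > -1 mild; -1 >= SPI > -1.5 moderate; -1.5 >= SPI > -2
    severe; SPI <= -2 extreme; SPI > 0 none.  Boundary values fall in the
    drier band (SPI = -1 is moderate, -1.5 severe, -2 extreme).
    """
    if np.isnan(spi_value):
        return "missing"
    if spi_value > 0:
        return "none"
    if spi_value > -1.0:
        return "mild"
    if spi_value > -1.5:
        return "moderate"
    if spi_value > -2.0:
        return "severe"
    return "extreme"


def _fit_gamma_ml(x: np.ndarray) -> tuple[float, float, float]:
    """Gamma ML fit (loc fixed at 0) returning (shape, scale, zero_fraction)."""
    x = np.asarray(x, dtype=float)
    q = float(np.mean(x == 0.0))
    pos = x[x > 0]
    if pos.size < 2 or np.allclose(pos, pos[0]):
        return np.nan, np.nan, q
    shape, _, scale = stats.gamma.fit(pos, floc=0.0)
    return float(shape), float(scale), q


def spi(record: DailyPrecipRecord, cfg: SpiConfig = SpiConfig()) -> list[SpiValue]:
    """1-month SPI for every in-season month of the record.

    For each calendar month (March-June) the monthly totals across the fit
    window are fitted with a gamma distribution by maximum likelihood (zeros
    handled as a point-mass mixture: SPI = Phi^-1(q + (1 - q) G(x))).  Each
    month's total is then mapped through the fitted CDF and the standard
    normal quantile.  Degenerate months (all totals zero, or fewer than two
    distinct positive values) yield NaN / class "missing".
    """
    if cfg.aggregation_months != 1:
        raise NotImplementedError("only 1-month aggregation is supported")
    df = monthly_totals(record)
    if cfg.fit_years is not None:
        lo, hi = cfg.fit_years
        fit_df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        if fit_df.empty:
            raise ValueError(f"no data in fit window {cfg.fit_years}")
    else:
        fit_df = df

    fits: dict[int, tuple[float, float, float]] = {}
    for month in SEASON_MONTHS:
        x = fit_df.loc[fit_df["month"] == month, "total_mm"].values
        fits[month] = _fit_gamma_ml(x)

    out: list[SpiValue] = []
    for _, row in df.iterrows():
        year, month, total = int(row["year"]), int(row["month"]), float(row["total_mm"])
        shape, scale, q = fits[month]
        if np.isnan(shape):
            value = np.nan
        else:
            g = stats.gamma.cdf(total, shape, scale=scale)
            p = q + (1.0 - q) * g if cfg.zero_inflated else g
            # clip away exact 0/1 so the normal quantile stays finite
            p = min(max(p, 1e-9), 1.0 - 1e-9)
            value = float(stats.norm.ppf(p))
        out.append(SpiValue(year=year, month=month, spi=value, drought_class=classify_drought(value)))
    return out


def spi_table(values: list[SpiValue]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [v.year for v in values],
            "month": [v.month for v in values],
            "spi": [v.spi for v in values],
            "drought_class": [v.drought_class for v in values],
        }
    )


def season_mean_spi(values: list[SpiValue], year: int) -> float:
    """Mean of the four 1-month SPI values of one growing season."""
    vals = [v.spi for v in values if v.year == year]
    if not vals:
        raise ValueError(f"no SPI values for {year}")
    finite = [v for v in vals if not np.isnan(v)]
    if not finite:  # every month undefined (e.g. single-year record)
        return float("nan")
    return float(np.mean(finite))


# ---------------------------------------------------------------------------
# Decadal aggregation


def decade_summary(
    record: DailyPrecipRecord,
    spis: list[SpiValue],
    threshold: float,
    require_complete: bool = True,
) -> list[DecadeSummary]:
    """Heavy-day and drought-month percentages per calendar decade.

    A decade is the ten calendar years 10k..10k+9 ("1950s").  Partial
    decades are excluded when ``require_complete`` (the default); the
    drought percentages count season-months with SPI <= -1.0 (moderate and
    worse) and <= -1.5 (severe and worse) out of the decade's season-months.
    """
    years = record.years
    spi_df = spi_table(spis)
    out: list[DecadeSummary] = []
    decades = sorted({(y // 10) * 10 for y in years})
    for d0 in decades:
        decade_years = [y for y in years if d0 <= y < d0 + 10]
        if require_complete and len(decade_years) < 10:
            continue
        seasons = [extract_season(record, y) for y in decade_years]
        heavy_pct = 100.0 * heavy_day_fraction(seasons, threshold)
        sub = spi_df[spi_df["year"].isin(decade_years)]
        n_months = len(sub)
        if n_months == 0:
            raise ValueError(f"no SPI values in decade {d0}s")
        mod = 100.0 * float(np.mean(sub["spi"].values <= -1.0))
        sev = 100.0 * float(np.mean(sub["spi"].values <= -1.5))
        out.append(
            DecadeSummary(
                decade=f"{d0}s",
                start_year=d0,
                heavy_day_pct=heavy_pct,
                moderate_plus_drought_pct=mod,
                severe_plus_drought_pct=sev,
                n_years=len(decade_years),
            )
        )
    return out
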