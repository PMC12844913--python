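"""Accumulated PAR, intercepted PAR and radiation-use-efficiency estimation.

RUE (g MJ-1) is accumulated dry matter divided by cumulative intercepted PAR,
``RUE = ADM / sum_d(I_d * F_d)``, where ``I_d`` is daily incoming PAR (half of
daily total solar radiation) and ``F_d`` the daily interception fraction of
the intercropped soybean canopy.  Sensor accumulations are kept on two scales:
the raw sum of 15-min instantaneous readings (the trial's "x1e5 umol m-2 s-1"
bookkeeping, used wherever reported numbers are reproduced) and the physical
time integral in mol m-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .solar_sim import SensorSeries

__all__ = [
    "SOLAR_TO_PAR",
    "SECONDS_PER_STEP",
    "DEFAULT_STAGES",
    "DailyRadiation",
    "AccumulatedPAR",
    "RUEEstimate",
    "par_from_solar",
    "accumulate_par",
    "daily_interception",
    "row_interception_weights",
    "rue",
    "rue_from_trajectory",
    "per_plant_to_area",
    "read_weather_csv",
    "write_weather_csv",
]

log = logging.getLogger(__name__)

SOLAR_TO_PAR = 0.5          # PAR share of total solar radiation
SECONDS_PER_STEP = 900.0    # 15-min sensor cadence

#: stage calendar of the virtual trial: recording starts at V5 (20 Jul),
#: harvest at R8 (15 Oct); intermediate stages are configurable defaults.
DEFAULT_STAGES = {"V5": "07-20", "R3": "08-15", "R5": "09-10", "R8": "10-15"}


@dataclass(frozen=True)
class DailyRadiation:
    date: pd.Timestamp
    total_solar: float   # MJ m-2 day-1

    @property
    def par(self) -> float:
        return SOLAR_TO_PAR * self.total_solar


@dataclass(frozen=True)
class AccumulatedPAR:
    """Windowed sensor accumulation for one row."""

    row_index: int
    window: tuple[pd.Timestamp, pd.Timestamp]
    sensor_sum: float          # sum of 15-min readings, umol m-2 s-1
    physical_integral: float   # mol m-2 (sensor_sum * 900 s / 1e6)
    n_steps: int
    n_interpolated: int


@dataclass(frozen=True)
class RUEEstimate:
    scope: str
    window: str
    adm: float    # g m-2
    ipar: float   # MJ m-2
    rue: float    # g MJ-1


def par_from_solar(total_solar: float | np.ndarray) -> float | np.ndarray:
    """Convert daily total solar radiation (MJ m-2) to PAR (MJ m-2)."""
    arr = np.asarray(total_solar, dtype=float)
    if (arr < 0).any():
        raise ValueError("total solar radiation must be non-negative")
    out = SOLAR_TO_PAR * arr
    return float(out) if np.isscalar(total_solar) else out


def accumulate_par(
    series: SensorSeries,
    window: tuple[str | pd.Timestamp, str | pd.Timestamp],
    *,
    max_gap_steps: int = 4,
    max_gap_fraction: float = 0.1,
) -> AccumulatedPAR:
    """Accumulate a sensor series over a stage window.

    Missing steps are filled by linear interpolation when a gap spans at most
    ``max_gap_steps`` consecutive samples; days containing longer gaps are
    dropped (and logged).  If more than ``max_gap_fraction`` of the window is
    missing, the window is rejected.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end <= start:
        raise ValueError(f"empty or reversed window {start} .. {end}")
    full = pd.date_range(start, end, freq="15min", inclusive="left")
    s = pd.Series(series.par, index=series.times).reindex(full)
    missing = s.isna()
    if len(full) == 0:
        raise ValueError("window contains no sensor steps")
    if missing.all():
        raise ValueError(f"series does not cover window {start.date()} .. {end.date()}")
    gap_fraction = missing.mean()
    if gap_fraction > max_gap_fraction:
        gaps = full[missing]
        raise ValueError(
            f"{gap_fraction:.0%} of window missing (> {max_gap_fraction:.0%}); "
            f"first gaps: {list(gaps[:4])}"
        )
    n_interp = 0
    if missing.any():
        runs = (missing != missing.shift()).cumsum()
        filled = s.interpolate(limit_area="inside")
        for _, idx in missing[missing].groupby(runs[missing]).groups.items():
            if len(idx) <= max_gap_steps and not filled[idx].isna().any():
                s[idx] = filled[idx]
                n_interp += len(idx)
            else:
                days = pd.DatetimeIndex(idx).normalize().unique()
                log.warning("dropping day(s) %s: gap of %d steps exceeds %d",
                            [str(d.date()) for d in days], len(idx), max_gap_steps)
                for d in days:
                    s[(s.index >= d) & (s.index < d + pd.Timedelta(days=1))] = np.nan
    total = float(s.sum(skipna=True))
    return AccumulatedPAR(
        row_index=series.row_index,
        window=(start, end),
        sensor_sum=total,
        physical_integral=total * SECONDS_PER_STEP / 1e6,
        n_steps=int(s.notna().sum()),
        n_interpolated=n_interp,
    )


def daily_interception(radiation: pd.DataFrame, fractions: pd.DataFrame) -> float:
    """Cumulative intercepted PAR (MJ m-2): sum over days of PAR * F.

    ``radiation`` has columns (date, total_solar); ``fractions`` has columns
    (date, fb).  Dates must align one-to-one.
    """
    rad = radiation.copy()
    rad["date"] = pd.to_datetime(rad["date"])
    fr = fractions.copy()
    fr["date"] = pd.to_datetime(fr["date"])
    merged = rad.merge(fr, on="date", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "date"]
        raise ValueError(f"radiation and fraction dates misaligned at {list(bad.dt.date)[:5]}")
    fb = merged["fb"].to_numpy()
    if ((fb < 0) | (fb > 1)).any():
        raise ValueError("interception fractions must lie in [0, 1]")
    return float(np.sum(par_from_solar(merged["total_solar"].to_numpy()) * fb))


def row_interception_weights(daily_sums: pd.DataFrame) -> pd.DataFrame:
    """Per-row interception weights from per-row daily sensor sums.

    The strip-level fraction ``Fb`` describes the whole soybean strip; the
    rows split it in proportion to the light each row's sensor saw:
    ``w_row = s_row / mean_row(s_row)`` per day, so the across-row mean of
    ``Fb * w_row`` returns ``Fb``.  Input columns: (date, row_index, sensor_sum).
    """
    df = daily_sums.copy()
    mean = df.groupby("date")["sensor_sum"].transform("mean")
    if (mean <= 0).any():
        raise ValueError("daily sensor sums must be positive to derive row weights")
    df["weight"] = df["sensor_sum"] / mean
    return df[["date", "row_index", "weight"]]


def cumulative_row_ipar(daily_sums: pd.DataFrame, fractions: pd.DataFrame,
                        weather: pd.DataFrame) -> pd.DataFrame:
    """Cumulative per-row intercepted PAR (MJ m-2) for one treatment.

    ``daily_sums`` holds per-row daily sensor sums (date, row_index,
    sensor_sum); ``fractions`` the strip-level daily fraction (date, fb);
    ``weather`` the daily totals (date, total_solar).  The strip fraction is
    split across rows by the sensor-sum weights of
    :func:`row_interception_weights`; the result is indexed by date with one
    column per row.
    """
    pivot = daily_sums.pivot(index="date", columns="row_index", values="sensor_sum")
    means = pivot.mean(axis=1)
    if (means <= 0).any() or pivot.isna().any().any():
        raise ValueError("per-row daily sums must be positive and complete")
    weights = pivot.div(means, axis=0)
    par_s = SOLAR_TO_PAR * weather.set_index("date")["total_solar"]
    fb_s = fractions.set_index("date")["fb"]
    daily = weights.mul(fb_s.reindex(pivot.index) * par_s.reindex(pivot.index), axis=0)
    if daily.isna().any().any():
        raise ValueError("weather/fraction dates do not cover the sensor dates")
    return daily.cumsum()


def rue(adm: float, ipar: float, scope: str = "", window: str = "") -> RUEEstimate:
    """Radiation use efficiency, g dry matter per MJ intercepted PAR."""
    if ipar <= 0:
        raise ValueError(f"intercepted PAR must be positive, got {ipar}")
    if adm < 0:
        raise ValueError(f"accumulated dry matter must be non-negative, got {adm}")
    return RUEEstimate(scope=scope, window=window, adm=adm, ipar=ipar, rue=adm / ipar)


def rue_from_trajectory(adm_by_stage: np.ndarray, ipar_by_stage: np.ndarray) -> float:
    """RUE from several cumulative (IPAR, ADM) stage points.

    Least-squares slope through the origin; with a single stage this reduces
    to the plain quotient.  Pooling stages averages independent sampling
    noise and is the package's default treatment-scope estimator.
    """
    a = np.asarray(adm_by_stage, float)
    i = np.asarray(ipar_by_stage, float)
    if a.shape != i.shape or a.size == 0:
        raise ValueError("need equal-length, non-empty stage vectors")
    if (i <= 0).any():
        raise ValueError("cumulative IPAR must be positive at every stage")
    return float(np.dot(i, a) / np.dot(i, i))


def per_plant_to_area(value_per_plant: float | np.ndarray, density_ha: float) -> float | np.ndarray:
    """Convert a per-plant quantity (g plant-1) to an area basis (g m-2)."""
    if density_ha <= 0:
        raise ValueError("density must be positive")
    return np.asarray(value_per_plant, float) * (density_ha / 10_000.0)


def read_weather_csv(path: str | Path) -> pd.DataFrame:
    """Read a daily weather table (date, total_solar_MJ_m2)."""
    df = pd.read_csv(path, parse_dates=["date"])
    if "total_solar_MJ_m2" not in df.columns:
        raise ValueError("weather table needs columns: date, total_solar_MJ_m2")
    return df.rename(columns={"total_solar_MJ_m2": "total_solar"})[["date", "total_solar"]]


def write_weather_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["date", "total_solar"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out = out.rename(columns={"total_solar": "total_solar_MJ_m2"})
    out["total_solar_MJ_m2"] = out["total_solar_MJ_m2"].round(4)
    out.to_csv(path, index=False)
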