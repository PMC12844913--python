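"""Diurnal per-row PAR simulation from solar geometry and maize-row shadowing.

The trial's rows run north-south at 36.7 N, so morning sun lights the western
soybean rows first (the eastern rows sit in the shadow of the maize strip on
their east side) and the situation mirrors in the afternoon.  The simulator
reproduces that mechanism: a clear-sky sine-of-elevation envelope, split into
a direct beam that a row receives only while outside every maize row's shadow
interval, and isotropic diffuse sky scaled per row by a between-walls view
factor.  An optional per-step cloud factor (seeded by the synthetic-experiment
generator) emulates broken cloud; an optional afternoon attenuation ramp
(convective cloud build-up) dims late hours relative to the morning, the
mechanism behind the west-over-east seasonal PAR surplus.

The simulator works in local solar time (solar noon = 12:00 exactly);
``clock_offset_minutes`` shifts the emitted timestamps to clock time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import StripGeometry, RowLayout
from .rcrt import black_view_factor

__all__ = [
    "SITE_LATITUDE",
    "SITE_LONGITUDE",
    "SITE_UTC_OFFSET",
    "SolarPosition",
    "SkyModel",
    "SensorSeries",
    "solar_position",
    "shadow_offset",
    "simulate_day",
    "peak_time",
    "write_sensor_csv",
    "read_sensor_csv",
    "read_hobo_csv",
]

# Weifang trial site
SITE_LATITUDE = 36.70664
SITE_LONGITUDE = 119.12683
SITE_UTC_OFFSET = 8

#: photon content of PAR energy, umol per J (broadband daylight average)
UMOL_PER_J = 4.57


@dataclass(frozen=True)
class SolarPosition:
    elevation: float   # degrees above horizon
    azimuth: float     # degrees clockwise from north
    timestamp: pd.Timestamp

    def __post_init__(self) -> None:
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation {self.elevation} outside [-90, 90]")


@dataclass(frozen=True)
class SkyModel:
    """Daily incoming PAR and how it is distributed over the day.

    ``daily_total`` is in MJ m-2 of PAR.  ``direct_fraction`` is the direct
    beam share; the rest is isotropic diffuse.  ``pm_attenuation`` emulates
    the convective cloud build-up typical of warm-temperate monsoon summers:
    the sky stays clear through the morning and midday, then dims linearly
    from ``pm_onset`` (solar hour) over ``pm_ramp`` hours down to
    ``1 - pm_attenuation`` of its clear value.  The envelope is re-normalised
    afterwards, so ``daily_total`` is conserved for an unshadowed point
    regardless of the attenuation.
    """

    daily_total: float
    direct_fraction: float = 0.7
    pm_attenuation: float = 0.0
    pm_onset: float = 13.0
    pm_ramp: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.direct_fraction <= 1.0:
            raise ValueError(f"direct_fraction {self.direct_fraction} outside [0, 1]")
        if self.daily_total < 0:
            raise ValueError("daily_total must be non-negative")
        if not 0.0 <= self.pm_attenuation <= 1.0:
            raise ValueError("pm_attenuation must lie in [0, 1]")
        if self.pm_ramp <= 0:
            raise ValueError("pm_ramp must be positive")


@dataclass
class SensorSeries:
    """A 15-min PAR record for one row position (umol m-2 s-1)."""

    row_index: int
    times: pd.DatetimeIndex
    par: np.ndarray
    placement: str = "10 cm above soybean canopy"

    def __post_init__(self) -> None:
        self.par = np.asarray(self.par, dtype=float)
        if len(self.times) != len(self.par):
            raise ValueError("times and par must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times.asi8)
            quantum = 15 * 60 * 10**9
            # records sit on a strict 15-min grid; gaps (missing records) are
            # allowed and handled downstream
            if (steps <= 0).any() or (steps % quantum != 0).any():
                raise ValueError("sensor timestamps must increase on a 15-min cadence")
        if (self.par < 0).any():
            raise ValueError("PAR values must be non-negative")

    def daily_sum(self) -> float:
        """Sum of instantaneous readings (the trial's accumulation bookkeeping)."""
        return float(self.par.sum())


def _day_angle(doy: np.ndarray | float, hour: np.ndarray | float = 12.0) -> np.ndarray:
    return 2 * np.pi * (np.asarray(doy, float) - 1 + (np.asarray(hour, float) - 12) / 24) / 365.0

def declination(doy, hour=12.0):
    """Solar declination (radians), Spencer's Fourier fit."""
    g = _day_angle(doy, hour)
    return (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))

def equation_of_time(doy, hour=12.0):
    """Equation of time in minutes (apparent minus mean solar time)."""
    g = _day_angle(doy, hour)
    return 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                     - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))


def _elev_azim(latitude: float, doy, solar_hour):
    """Elevation and azimuth (degrees) from day of year and local solar hour."""
    lat = math.radians(latitude)
    dec = declination(doy, solar_hour)
    h = np.radians(15.0 * (np.asarray(solar_hour, float) - 12.0))
    sin_el = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(h)
    el = np.degrees(np.arcsin(np.clip(sin_el, -1, 1)))
    az = np.degrees(np.arctan2(np.sin(h), np.cos(h) * np.sin(lat) - np.tan(dec) * np.cos(lat))) + 180.0
    return el, np.mod(az, 360.0)


def solar_position(latitude: float, longitude: float, when: datetime | pd.Timestamp,
                   utc_offset: float | None = None) -> SolarPosition:
    """Sun elevation and azimuth at a clock timestamp.

    ``when`` must either be timezone-aware or be accompanied by an explicit
    ``utc_offset`` (hours); silent assumptions about the clock convention are
    refused because a wrong offset shifts every shadow by the same error.
    Accuracy of the underlying approximation is a few hundredths of a degree,
    ample for shadow geometry.
    """
    ts = pd.Timestamp(when)
    if ts.tzinfo is not None:
        offset = ts.utcoffset().total_seconds() / 3600.0
        ts = ts.tz_localize(None)
    elif utc_offset is not None:
        offset = float(utc_offset)
    else:
        raise ValueError("naive timestamp: pass utc_offset (hours) or a tz-aware timestamp")
    clock_hour = ts.hour + ts.minute / 60 + ts.second / 3600
    doy = ts.dayofyear
    solar_hour = clock_hour + (float(equation_of_time(doy, clock_hour))
                               + 4.0 * (longitude - 15.0 * offset)) / 60.0
    el, az = _elev_azim(latitude, doy, solar_hour)
    return SolarPosition(elevation=float(el), azimuth=float(az), timestamp=pd.Timestamp(when))


def shadow_offset(Ha: float, Hb: float, sun: SolarPosition, row_azimuth: float = 0.0) -> float:
    """Cross-row reach (m) of the shadow a maize wall casts at soybean height.

    The wall top sits ``Ha - Hb`` above the sensor plane; the shadow's
    cross-row component is ``(Ha - Hb)/tan(elevation) * |sin(azimuth -
    row_azimuth)|``, directed to the anti-solar side.  Below the horizon the
    reach is infinite (night).
    """
    if Hb > Ha:
        raise ValueError("soybean must not overtop maize")
    if sun.elevation <= 0:
        return math.inf
    return (Ha - Hb) / math.tan(math.radians(sun.elevation)) * \
        abs(math.sin(math.radians(sun.azimuth - row_azimuth)))


def simulate_day(
    geom: StripGeometry,
    layout: list[RowLayout],
    sky: SkyModel,
    date: str | datetime | pd.Timestamp,
    *,
    latitude: float = SITE_LATITUDE,
    maize_rows: tuple[float, ...] = (0.0, 0.4),
    row_azimuth: float = 0.0,
    step_minutes: int = 15,
    cloud: np.ndarray | None = None,
    clock_offset_minutes: float = 0.0,
) -> list[SensorSeries]:
    """Simulate one day of 15-min PAR at every soybean row of one cell.

    Returns one :class:`SensorSeries` per entry of ``layout``.  ``cloud``, if
    given, is a per-step multiplicative sky factor (whole-sky, shared by all
    rows); the envelope is normalised after applying it, so an unshadowed
    reference still integrates to ``sky.daily_total``.
    """
    date = pd.Timestamp(date).normalize()
    if step_minutes <= 0 or 1440 % step_minutes:
        raise ValueError("step_minutes must divide the day")
    n_steps = 1440 // step_minutes
    hours = np.arange(n_steps) * step_minutes / 60.0
    el, az = _elev_azim(latitude, date.dayofyear, hours)
    env = np.maximum(np.sin(np.radians(el)), 0.0)
    if not env.any():
        raise ValueError(f"zero-length day at latitude {latitude} on {date.date()}")
    pm = 1.0 - sky.pm_attenuation * np.clip((hours - sky.pm_onset) / sky.pm_ramp, 0.0, 1.0)
    w = env * pm
    if cloud is not None:
        cloud = np.asarray(cloud, dtype=float)
        if cloud.shape != w.shape:
            raise ValueError(f"cloud must have {n_steps} steps")
        w = w * cloud
    # instantaneous whole-sky PAR, umol m-2 s-1, normalised to the daily total
    scale = sky.daily_total * 1e6 / (w.sum() * step_minutes * 60.0)
    inst = w * scale * UMOL_PER_J
    direct = inst * sky.direct_fraction
    diffuse = inst - direct

    period = geom.width
    wall_h = max(geom.Ha - geom.Hb, 0.0)
    with np.errstate(divide="ignore"):
        reach = np.where(
            el > 0,
            wall_h / np.tan(np.radians(np.clip(el, 1e-6, None)))
            * np.abs(np.sin(np.radians(az - row_azimuth))),
            np.inf,
        )
    sun_east = np.sin(np.radians(az - row_azimuth)) >= 0.0

    times = pd.date_range(date + pd.Timedelta(minutes=clock_offset_minutes),
                          periods=n_steps, freq=f"{step_minutes}min")
    out = []
    for row in layout:
        x = row.cross_row_position % period
        if wall_h == 0.0 or not maize_rows:
            dvf = 1.0
            shaded = np.zeros(n_steps, dtype=bool)
        else:
            d_east = min((x - m) % period for m in maize_rows)
            d_west = min((m - x) % period for m in maize_rows)
            dvf = 0.5 * (black_view_factor(wall_h, d_east) + black_view_factor(wall_h, d_west))
            # morning sun (east): shadows extend westward, i.e. to larger x
            shaded = np.where(sun_east, d_east <= reach, d_west <= reach)
        par = diffuse * dvf + direct * (~shaded)
        out.append(SensorSeries(row_index=row.row_index, times=times, par=par))
    return out


def peak_time(series: SensorSeries, smoothing_window: int = 3) -> pd.Timestamp:
    """Timestamp of the (smoothed) daily PAR maximum.

    A centred moving mean (default 3 samples = 45 min) suppresses the
    spurious single-sample maxima that broken cloud produces; ties resolve to
    the earlier timestamp.
    """
    if len(series.par) == 0 or not np.any(series.par > 0):
        raise ValueError("cannot locate a peak in an all-zero series")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd number of samples")
    if smoothing_window == 1:
        sm = series.par
    else:
        sm = (pd.Series(series.par)
              .rolling(smoothing_window, center=True, min_periods=1)
              .mean().to_numpy())
    return series.times[int(np.argmax(sm))]


# ---------------------------------------------------------------------------
# sensor-table I/O

def write_sensor_csv(series_list: list[SensorSeries], path: str | Path) -> None:
    """Write sensor series as tidy delimited text (timestamp, row, PAR)."""
    frames = [pd.DataFrame({"timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S"),
                            "row_index": s.row_index,
                            "par_umol_m2_s": np.round(s.par, 4)})
              for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensor_csv(path: str | Path) -> list[SensorSeries]:
    """Read the tidy sensor format back into per-row series."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    needed = {"timestamp", "row_index", "par_umol_m2_s"}
    if not needed.issubset(df.columns):
        raise ValueError(f"sensor table must have columns {sorted(needed)}")
    out = []
    for row_idx, grp in df.groupby("row_index", sort=True):
        grp = grp.sort_values("timestamp")
        out.append(SensorSeries(row_index=int(row_idx),
                                times=pd.DatetimeIndex(grp["timestamp"]),
                                par=grp["par_umol_m2_s"].to_numpy()))
    return out


def read_hobo_csv(path: str | Path, row_index: int | None = None) -> SensorSeries:
    """Read a two-column logger export (timestamp, intensity).

    The row is taken from a ``row<k>`` token in the file name unless given
    explicitly.
    """
    path = Path(path)
    if row_index is None:
        m = re.search(r"row(\d+)", path.stem)
        if not m:
            raise ValueError(f"cannot infer row index from file name {path.name!r}; pass row_index")
        row_index = int(m.group(1))
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("logger export must have two columns: timestamp, intensity")
    times = pd.DatetimeIndex(pd.to_datetime(df.iloc[:, 0]))
    return SensorSeries(row_index=row_index, times=times, par=df.iloc[:, 1].to_numpy())
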