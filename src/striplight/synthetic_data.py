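"""Seeded virtual strip-intercropping experiment.

Generates everything the analysis pipeline consumes — daily weather, per-row
15-min canopy PAR, stage-wise plant traits with three replicates, and yield
tables — for the six strip-width treatments plus the sole-soybean control,
with known ground truth (true per-row RUE, interception history, seed), so
every pipeline stage is testable without any field data.

What is emulated, and how:

* canopy growth: logistic height and leaf-area curves (maize to 2.6 m and a
  strip-local LAI of 5.5; soybean to 0.8 m and 2.75) — plausible for the
  cultivars and climate, asserted nowhere as measured facts;
* sky: clear-sky seasonal envelope with a seeded day-level cloud factor, a
  seeded 15-min broken-cloud factor, and a calibrated afternoon convective
  attenuation that reproduces the configured west-over-east seasonal PAR
  surplus (default +6.5%);
* measurements: multiplicative lognormal noise per sensor reading and per
  replicate plant; three "uniformly growing plants" per row and stage;
* dry matter: per-row truth is ``RUE_row x cumulative intercepted PAR``, with
  the strip-level interception fraction from the consistent view-factor model
  split across rows in proportion to each row's simulated light; leaf area
  follows dry matter through a stage-specific area:mass ratio; yield is a
  fixed harvest index on maturity dry matter, decomposed into pods, grains
  and 100-seed weight.

Regenerating with the same seed and config is reproducible to the byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, rcrt, solar_sim
from .geometry import LayoutParams, StripGeometry
from .rue_pipeline import SOLAR_TO_PAR, DEFAULT_STAGES, cumulative_row_ipar, rue_from_trajectory

__all__ = [
    "GrowthCurves",
    "EffectConfig",
    "VirtualExperiment",
    "gen_weather",
    "calibrate_pm_attenuation",
    "gen_field",
    "export_fixtures",
]

SOWING = "06-15"
DEFAULT_YEAR = 2023


def _logistic(t: np.ndarray | float, y_max: float, t_mid: float, rate: float,
              y0: float = 0.0) -> np.ndarray | float:
    return y0 + (y_max - y0) / (1.0 + np.exp(-rate * (np.asarray(t, float) - t_mid)))


@dataclass(frozen=True)
class GrowthCurves:
    """Logistic canopy trajectories, in days after sowing.

    Asymptotes are configuration, not measurements: maize height 2.6 m and
    strip-local LAI 5.5; soybean height 0.8 m and strip-local LAI 2.75
    (scaled across treatments so wider strips carry slightly larger soybean
    leaf area, mirroring the reported leaf-area ordering).
    """

    ha_max: float = 2.6
    ha_mid: float = 40.0
    ha_rate: float = 0.12
    hb_max: float = 0.8
    hb_mid: float = 45.0
    hb_rate: float = 0.10
    laia_max: float = 5.5      # strip-local
    laia_mid: float = 50.0
    laia_rate: float = 0.12
    laib_max: float = 2.75     # strip-local, mid treatment
    laib_mid: float = 55.0
    laib_rate: float = 0.10
    laib_width_gain: float = 0.04   # fractional gain per soybean row beyond 5

    def heights(self, t: float) -> tuple[float, float]:
        ha = float(_logistic(t, self.ha_max, self.ha_mid, self.ha_rate, 0.2))
        hb = float(_logistic(t, self.hb_max, self.hb_mid, self.hb_rate, 0.05))
        return ha, min(hb, ha)

    def local_lai(self, t: float, n_soy_rows: int = 5) -> tuple[float, float]:
        la = float(_logistic(t, self.laia_max, self.laia_mid, self.laia_rate, 0.05))
        scale = 1.0 + self.laib_width_gain * (n_soy_rows - 5)
        lb = float(_logistic(t, self.laib_max * scale, self.laib_mid, self.laib_rate, 0.02))
        return la, lb


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect sizes and noise levels of the virtual trial."""

    west_east_par_delta: float = 0.065          # target fractional west-over-east PAR surplus
    gradient_slope: float = 0.08                # extra fractional RUE/trait gain per m from maize
    true_rue: dict = field(default_factory=lambda: {"east": 1.37, "middle": 1.50, "west": 1.44})
    noise_cv: dict = field(default_factory=lambda: {"par": 0.05, "trait": 0.10, "yield": 0.10})
    cloud_cv: float = 0.30                      # 15-min broken-cloud variability
    day_cloud_sigma: float = 0.35               # day-level lognormal sigma of the weather
    direct_fraction: float = 0.7
    harvest_index: float = 0.45
    hundred_seed_weight: float = 18.0           # g
    grains_per_pod: float = 2.2
    sla: dict = field(default_factory=lambda: {"V5": 140.0, "R3": 95.0, "R5": 70.0, "R8": 45.0})
    curves: GrowthCurves = field(default_factory=GrowthCurves)
    year: int = DEFAULT_YEAR
    stages: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))

    def __post_init__(self) -> None:
        if self.west_east_par_delta <= -1:
            raise ValueError("west_east_par_delta must exceed -1")
        if any(v < 0 for v in self.noise_cv.values()) or self.cloud_cv < 0:
            raise ValueError("noise CVs must be non-negative")

    def noiseless(self) -> "EffectConfig":
        """Copy with all measurement noise off (clouds stay on)."""
        return EffectConfig(**{**asdict(self) | {
            "noise_cv": {k: 0.0 for k in self.noise_cv},
            "curves": self.curves, "true_rue": dict(self.true_rue),
            "sla": dict(self.sla), "stages": dict(self.stages)}})

    def stage_dates(self) -> dict[str, pd.Timestamp]:
        return {s: pd.Timestamp(f"{self.year}-{d}") for s, d in self.stages.items()}

    def to_jsonable(self) -> dict:
        return json.loads(json.dumps(asdict(self), sort_keys=True, default=float))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "curves" in raw:
            raw["curves"] = GrowthCurves(**raw["curves"])
        return cls(**raw)


@dataclass
class VirtualExperiment:
    """A complete generated trial with its ground truth."""

    config: EffectConfig
    seed: int
    treatments: list[str]
    weather: pd.DataFrame            # date, total_solar
    sensors: dict                    # (treatment, row_index) -> SensorSeries (measured)
    clean_daily: pd.DataFrame        # treatment, row_index, date, sensor_sum (noise-free)
    fb_daily: pd.DataFrame           # treatment, date, fb (strip-level interception fraction)
    traits: pd.DataFrame             # treatment, row_index, stage, rep, dry_matter_g, leaf_area_cm2
    yields: pd.DataFrame             # treatment, row_index, rep, yield components
    ground_truth: dict
    stage_points: dict               # stage name -> sampling date inside the generated window

    def layout(self, treatment: str):
        return geometry.row_positions(geometry.build_treatment(treatment))

    def measured_daily_sums(self) -> pd.DataFrame:
        """Daily sensor sums recomputed from the measured (noisy) series."""
        rows = []
        for (trt, row), s in self.sensors.items():
            daily = pd.Series(s.par, index=s.times).resample("D").sum()
            for d, v in daily.items():
                rows.append({"treatment": trt, "row_index": row,
                             "date": d, "sensor_sum": float(v)})
        return pd.DataFrame(rows)


def gen_weather(start: str | pd.Timestamp, end: str | pd.Timestamp,
                seed: int = 0, day_cloud_sigma: float = 0.35) -> pd.DataFrame:
    """Daily total solar radiation (MJ m-2): seasonal clear-sky sinusoid times
    a seeded lognormal cloud factor capped at the clear-sky value."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise ValueError(f"reversed date range {start.date()} .. {end.date()}")
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy()
    clear = 21.0 + 8.0 * np.cos(2 * np.pi * (doy - 172) / 365.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    factor = 0.8 * rng.lognormal(-0.5 * day_cloud_sigma**2, day_cloud_sigma, len(dates))
    total = clear * np.minimum(factor, 1.0)
    return pd.DataFrame({"date": dates, "total_solar": total})


def _day_geometry(cfg: EffectConfig, treatment: geometry.Treatment,
                  date: pd.Timestamp) -> tuple[StripGeometry, rcrt.CanopyState]:
    t = (date - pd.Timestamp(f"{cfg.year}-{SOWING}")).days
    base = geometry.split_strip(treatment)
    ha, hb = cfg.curves.heights(t)
    geom = base.with_heights(ha, hb)
    la_loc, lb_loc = cfg.curves.local_lai(t, treatment.n_soy_rows)
    canopy = rcrt.CanopyState(LAIa=la_loc * geom.fa, LAIb=lb_loc * geom.fb)
    return geom, canopy


def calibrate_pm_attenuation(cfg: EffectConfig, tol: float = 1e-4, max_iter: int = 40) -> float:
    """Afternoon attenuation depth reproducing the configured west-east surplus.

    The western rows lose the afternoon beam to maize shading, the eastern
    rows the morning beam; a convective afternoon dimming therefore favours
    the west while leaving midday symmetric.  The depth is solved by
    bisection on a noise-free reference day (full canopy, 15 Aug) so that the
    across-treatment ratio of mean western to mean eastern daily sums equals
    ``1 + west_east_par_delta``.  Deterministic: no random numbers involved.
    """
    target = cfg.west_east_par_delta

    def west_east_ratio(depth: float) -> float:
        west, east = [], []
        date = pd.Timestamp(f"{cfg.year}-08-15")
        for name in geometry.INTERCROP_NAMES:
            trt = geometry.build_treatment(name)
            layout = geometry.row_positions(trt)
            geom, _ = _day_geometry(cfg, trt, date)
            sky = solar_sim.SkyModel(daily_total=10.0,
                                     direct_fraction=cfg.direct_fraction,
                                     pm_attenuation=depth)
            series = solar_sim.simulate_day(geom, layout, sky, date)
            east.append(series[0].daily_sum())
            west.append(series[-1].daily_sum())
        return float(np.mean(west) / np.mean(east)) - 1.0

    if abs(target) < 1e-12:
        return 0.0
    lo, hi = 0.0, 1.0
    f_lo = west_east_ratio(lo) - target
    f_hi = west_east_ratio(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError(
            f"cannot reach west-east delta {target:+.3f} with attenuation in [0, {hi}] "
            f"(achievable range {f_lo + target:+.4f} .. {f_hi + target:+.4f})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = west_east_ratio(mid) - target
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def gen_field(cfg: EffectConfig | None = None, seed: int = 0, *,
              treatments: list[str] | None = None,
              n_days: int | None = None,
              include_ss: bool = True) -> VirtualExperiment:
    """Generate the full virtual experiment.

    ``n_days`` truncates the season after the recording start (useful for
    fast tests); stage dates beyond the truncated window are compressed onto
    its last day so trait tables always exist.
    """
    cfg = cfg or EffectConfig()
    treatments = list(treatments or geometry.INTERCROP_NAMES)
    bad = [t for t in treatments if t not in geometry.INTERCROP_NAMES]
    if bad:
        raise ValueError(f"invalid intercrop treatments {bad}")
    stage_dates = cfg.stage_dates()
    start, end = stage_dates["V5"], stage_dates["R8"]
    if n_days is not None:
        if n_days < 2:
            raise ValueError("n_days must be at least 2")
        end = min(end, start + pd.Timedelta(days=n_days - 1))
    dates = pd.date_range(start, end, freq="D")
    stage_points = {s: min(d, dates[-1]) for s, d in stage_dates.items() if d >= dates[0]}

    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 2024])
    _, rng_cloud, rng_sensor, rng_trait, rng_yield = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    weather = gen_weather(start, end, seed=seed & 0x7FFFFFFF,
                          day_cloud_sigma=cfg.day_cloud_sigma)
    pm_depth = calibrate_pm_attenuation(cfg)
    cloud_sigma = math.sqrt(math.log(1 + cfg.cloud_cv**2))
    par_sigma = math.sqrt(math.log(1 + cfg.noise_cv["par"]**2)) if cfg.noise_cv["par"] > 0 else 0.0

    sensors: dict = {}
    clean_rows, fb_rows = [], []
    density_m2 = geometry.SOY_DENSITY / 10_000.0
    soy_k_steps = 96

    for name in treatments:
        trt = geometry.build_treatment(name)
        layout = geometry.row_positions(trt)
        clean_mat = {r.row_index: [] for r in layout}
        noisy_mat = {r.row_index: [] for r in layout}
        times_all = []
        for di, date in enumerate(dates):
            geom, canopy = _day_geometry(cfg, trt, date)
            fb = rcrt.partition(geom, canopy, variant="consistent").Fb
            fb_rows.append({"treatment": name, "date": date, "fb": fb})
            sky = solar_sim.SkyModel(
                daily_total=SOLAR_TO_PAR * float(weather["total_solar"].iloc[di]),
                direct_fraction=cfg.direct_fraction, pm_attenuation=pm_depth)
            cloud = rng_cloud.lognormal(-0.5 * cloud_sigma**2, cloud_sigma, soy_k_steps) \
                if cfg.cloud_cv > 0 else None
            series = solar_sim.simulate_day(geom, layout, sky, date, cloud=cloud)
            for s in series:
                clean_mat[s.row_index].append(s.par)
                if par_sigma > 0:
                    noise = rng_sensor.lognormal(-0.5 * par_sigma**2, par_sigma, s.par.size)
                    noisy_mat[s.row_index].append(s.par * noise)
                else:
                    noisy_mat[s.row_index].append(s.par)
                clean_rows.append({"treatment": name, "row_index": s.row_index,
                                   "date": date, "sensor_sum": float(s.par.sum())})
            times_all.append(series[0].times)
        times = times_all[0].append(times_all[1:]) if len(times_all) > 1 else times_all[0]
        for r in layout:
            sensors[(name, r.row_index)] = solar_sim.SensorSeries(
                row_index=r.row_index, times=times,
                par=np.concatenate(noisy_mat[r.row_index]))

    if include_ss:
        ss_trt = geometry.build_treatment("SS")
        ss_layout = [geometry.RowLayout(1, 0.25, "middle", math.inf)]
        noisy = []
        times_all = []
        for di, date in enumerate(dates):
            t = (date - pd.Timestamp(f"{cfg.year}-{SOWING}")).days
            _, lb_loc = cfg.curves.local_lai(t)
            fb_rows.append({"treatment": "SS", "date": date,
                            "fb": rcrt.mono_fraction(lb_loc, rcrt.K_SOY_MONO)})
            geom = geometry.split_strip(ss_trt)
            sky = solar_sim.SkyModel(
                daily_total=SOLAR_TO_PAR * float(weather["total_solar"].iloc[di]),
                direct_fraction=cfg.direct_fraction, pm_attenuation=pm_depth)
            cloud = rng_cloud.lognormal(-0.5 * cloud_sigma**2, cloud_sigma, soy_k_steps) \
                if cfg.cloud_cv > 0 else None
            s = solar_sim.simulate_day(geom, ss_layout, sky, date, maize_rows=(), cloud=cloud)[0]
            noise = (rng_sensor.lognormal(-0.5 * par_sigma**2, par_sigma, s.par.size)
                     if par_sigma > 0 else 1.0)
            noisy.append(s.par * noise)
            clean_rows.append({"treatment": "SS", "row_index": 1, "date": date,
                               "sensor_sum": float(s.par.sum())})
            times_all.append(s.times)
        times = times_all[0].append(times_all[1:]) if len(times_all) > 1 else times_all[0]
        sensors[("SS", 1)] = solar_sim.SensorSeries(row_index=1, times=times,
                                                    par=np.concatenate(noisy))

    clean_daily = pd.DataFrame(clean_rows)
    fb_daily = pd.DataFrame(fb_rows)

    # --- ground-truth interception and dry matter ---------------------------
    truth: dict = {"seed": seed, "pm_attenuation": pm_depth,
                   "west_east_par_delta": cfg.west_east_par_delta,
                   "rue": {}, "ipar": {}}
    trait_rows, yield_rows = [], []
    trait_sigma = math.sqrt(math.log(1 + cfg.noise_cv["trait"]**2)) if cfg.noise_cv["trait"] > 0 else 0.0
    yield_sigma = math.sqrt(math.log(1 + cfg.noise_cv["yield"]**2)) if cfg.noise_cv["yield"] > 0 else 0.0

    for name in treatments:
        trt = geometry.build_treatment(name)
        layout = geometry.row_positions(trt)
        mean_d = float(np.mean([r.distance_to_nearest_maize_row for r in layout]))
        sub = clean_daily[clean_daily["treatment"] == name]
        cum_ipar = cumulative_row_ipar(
            sub, fb_daily[fb_daily["treatment"] == name], weather)
        truth["ipar"][name] = {
            int(r): {s: float(cum_ipar.loc[d, r]) for s, d in stage_points.items()}
            for r in cum_ipar.columns
        }
        for r in layout:
            rue_row = cfg.true_rue[r.role] * (
                1.0 + cfg.gradient_slope * (r.distance_to_nearest_maize_row - mean_d))
            truth["rue"].setdefault(name, {})[r.row_index] = rue_row
            for s_name, s_date in stage_points.items():
                adm_area = rue_row * float(cum_ipar.loc[s_date, r.row_index])  # g m-2
                dm_plant = adm_area / density_m2
                for rep in range(1, 4):
                    f = (rng_trait.lognormal(-0.5 * trait_sigma**2, trait_sigma)
                         if trait_sigma > 0 else 1.0)
                    g = (rng_trait.lognormal(-0.5 * trait_sigma**2, trait_sigma)
                         if trait_sigma > 0 else 1.0)
                    trait_rows.append({
                        "treatment": name, "row_index": r.row_index, "stage": s_name,
                        "rep": rep, "dry_matter_g": dm_plant * f,
                        "leaf_area_cm2": cfg.sla[s_name] * dm_plant * g,
                    })
            adm_final = rue_row * float(cum_ipar.loc[stage_points["R8"], r.row_index]) \
                if "R8" in stage_points else rue_row * float(cum_ipar.iloc[-1][r.row_index])
            dm_final = adm_final / density_m2
            for rep in range(1, 4):
                f = (rng_yield.lognormal(-0.5 * yield_sigma**2, yield_sigma)
                     if yield_sigma > 0 else 1.0)
                y_plant = cfg.harvest_index * dm_final * f
                grains = y_plant / (cfg.hundred_seed_weight / 100.0)
                yield_rows.append({
                    "treatment": name, "row_index": r.row_index, "rep": rep,
                    "yield_g_plant": y_plant,
                    "yield_kg_ha": y_plant * geometry.SOY_DENSITY / 1000.0,
                    "grains_per_plant": grains,
                    "pods_per_plant": grains / cfg.grains_per_pod,
                    "hundred_seed_weight_g": cfg.hundred_seed_weight,
                })

    return VirtualExperiment(
        config=cfg, seed=seed, treatments=treatments, weather=weather,
        sensors=sensors, clean_daily=clean_daily, fb_daily=fb_daily,
        traits=pd.DataFrame(trait_rows), yields=pd.DataFrame(yield_rows),
        ground_truth=truth, stage_points=stage_points,
    )


def pipeline_rue_estimates(exp: VirtualExperiment, scope: str = "row") -> pd.DataFrame:
    """Run the measurement pipeline on a virtual experiment and estimate RUE.

    Uses only what a field campaign would have: the measured (noisy) sensor
    series, the trait tables, the weather table and the model interception
    fractions.  ``scope="row"`` returns the plain quotient ADM/IPAR per row
    and stage; ``scope="treatment"`` pools rows and fits the slope through
    the origin over the cumulative stage trajectory (the package's default,
    variance-efficient treatment estimator).  Ground-truth RUE is merged in
    for convenience as ``truth``.
    """
    if scope not in ("row", "treatment"):
        raise ValueError("scope must be 'row' or 'treatment'")
    density_m2 = geometry.SOY_DENSITY / 10_000.0
    measured = exp.measured_daily_sums()
    adm = (exp.traits.groupby(["treatment", "row_index", "stage"])["dry_matter_g"]
           .mean() * density_m2)
    out = []
    for name in exp.treatments:
        cum_ipar = cumulative_row_ipar(
            measured[measured["treatment"] == name],
            exp.fb_daily[exp.fb_daily["treatment"] == name], exp.weather)
        stages = list(exp.stage_points)
        if scope == "row":
            for r in cum_ipar.columns:
                for s in stages:
                    ipar_rs = float(cum_ipar.loc[exp.stage_points[s], r])
                    out.append({
                        "treatment": name, "row_index": int(r), "stage": s,
                        "estimate": float(adm.loc[(name, r, s)]) / ipar_rs,
                        "truth": exp.ground_truth["rue"][name][int(r)],
                    })
        else:
            ipar_s = np.array([
                float(cum_ipar.loc[exp.stage_points[s]].mean()) for s in stages])
            adm_s = np.array([
                float(adm.loc[(name, slice(None), s)].mean()) for s in stages])
            ipar_last = cum_ipar.loc[exp.stage_points[stages[-1]]]
            rue_truth = exp.ground_truth["rue"][name]
            truth_val = float(
                sum(rue_truth[int(r)] * ipar_last[r] for r in cum_ipar.columns)
                / ipar_last.sum())
            out.append({"treatment": name, "stage": "+".join(stages),
                        "estimate": rue_from_trajectory(adm_s, ipar_s),
                        "truth": truth_val})
    df = pd.DataFrame(out)
    df["rel_err"] = df["estimate"] / df["truth"] - 1.0
    return df


# ---------------------------------------------------------------------------
# fixture export

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_fixtures(exp: VirtualExperiment, directory: str | Path) -> dict:
    """Write the experiment as delimited-text fixtures plus a manifest.

    The manifest records the seed and a hash of the generating configuration;
    it changes if and only if the configuration or seed changes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sensor_dir = directory / "sensors"
    sensor_dir.mkdir(exist_ok=True)

    from .rue_pipeline import write_weather_csv
    from .solar_sim import write_sensor_csv

    write_weather_csv(exp.weather, directory / "weather.csv")
    files = ["weather.csv"]
    for (trt, row), series in sorted(exp.sensors.items()):
        name = f"sensors/{trt}_row{row}.csv"
        write_sensor_csv([series], directory / name)
        files.append(name)
    for frame, name in ((exp.traits, "traits.csv"), (exp.yields, "yields.csv"),
                        (exp.fb_daily, "interception.csv")):
        out = frame.copy()
        if "date" in out.columns:
            out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.round(6).to_csv(directory / name, index=False)
        files.append(name)
    (directory / "ground_truth.json").write_text(
        json.dumps(exp.ground_truth, indent=1, sort_keys=True, default=float))
    files.append("ground_truth.json")

    config_hash = hashlib.sha256(
        json.dumps(exp.config.to_jsonable(), sort_keys=True).encode()).hexdigest()
    manifest = {
        "seed": exp.seed,
        "config_sha256": config_hash,
        "treatments": exp.treatments,
        "files": {f: _sha256(directory / f) for f in sorted(files)},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
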