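"""Synthetic collocation and network data with known ground truth.

The generator emulates a field deployment of dual-channel optical PM2.5
sensors in equatorial East Africa: a baseline that is higher at urban
sites, a bimodal seasonal cycle (wet seasons March-May and
September-November depress concentrations), a double-peaked diurnal
template (morning rush 06-09, a higher evening peak 18-22), and AR(1)
hour-to-hour persistence.  Raw sensor readings are obtained by
*inverting* the linear calibration relation

    ref = beta0 + beta1 * raw + beta2 * RH + N(0, sigma)

so that regressing the simulated reference on raw PM and RH estimates
exactly ``TruthParams`` — the generator's coefficients are the estimand.

A collocated reference instrument is emulated as a 5-min nephelometric
stream divided by a weekly "true" correction factor (the nephelometer's
humidity/composition bias), plus weekly 47-mm filters whose net mass
integrates the true concentration over the sampled volume at 2.0 L/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .types import Site, TruthParams

__all__ = [
    "default_truth_params",
    "simulate_true_pm",
    "simulate_rh",
    "simulate_temperature",
    "simulate_pressure",
    "derive_raw_sensor",
    "simulate_reference",
    "simulate_bundle",
    "SimulatedBundle",
]

#: Monthly mean RH (%) annual cycle; January lowest (73.8), November highest (86.3).
RH_MONTHLY_MEANS = (73.8, 74.5, 78.0, 82.0, 84.0, 80.0, 77.0, 78.5, 83.0, 85.0, 86.3, 78.0)

MINUTES_PER_INTERVAL = 2
INTERVALS_PER_HOUR = 30
NEPH_PER_HOUR = 12  # 5-min readings
HOURS_PER_WEEK = 168


def default_truth_params(setting: str, city: str | None = None, **overrides) -> TruthParams:
    """Study-condition truth parameters for a site setting.

    Baselines and seasonal amplitudes are chosen so pooled seasonal means
    land near the field values (rural ~22 dry / ~13 wet µg/m³, urban
    ~38 / ~23; Kampala above Masaka).
    """
    presets = {
        "rural": dict(baseline=17.4, seasonal_amp=4.7, diurnal_amps=(4.0, 6.0)),
        "urban": dict(baseline=30.4, seasonal_amp=7.2, diurnal_amps=(6.0, 9.0)),
    }
    city_presets = {
        "Masaka": dict(baseline=26.5, seasonal_amp=6.0, diurnal_amps=(5.0, 8.0)),
        "Kampala": dict(baseline=37.0, seasonal_amp=9.3, diurnal_amps=(7.0, 11.0)),
    }
    if setting not in presets:
        raise ConfigError(f"unknown setting {setting!r}")
    kw = dict(presets[setting])
    if city in city_presets:
        kw.update(city_presets[city])
    kw.update(overrides)
    return TruthParams(**kw)


def _hourly_index(n_hours: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start=start, periods=n_hours, freq="h")


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


def _diurnal_template(hours: np.ndarray, amps: tuple[float, float]) -> np.ndarray:
    """Double-peaked daily cycle: morning bump at 06-09, higher evening bump 18-22."""
    a_morning, a_evening = amps
    morning = a_morning * np.exp(-0.5 * ((hours - 7.5) / 1.3) ** 2)
    evening = a_evening * np.exp(-0.5 * ((hours - 20.0) / 1.6) ** 2)
    return morning + evening


def _seasonal_cycle(index: pd.DatetimeIndex, amp: float) -> np.ndarray:
    """Six-month cosine: maxima mid dry seasons (Jan-Feb, Jul-Aug), minima in the rains."""
    doy = index.dayofyear.to_numpy(dtype=float)
    return amp * np.cos(2.0 * np.pi * (doy - 30.0) / 182.62)


def simulate_true_pm(
    n_hours: int,
    params: TruthParams,
    seed: int,
    start: str = "2022-10-27 00:00",
) -> pd.Series:
    """Hourly true ambient PM2.5 (µg/m³), nonnegative.

    baseline + seasonal cosine (wet months lower) + double-peaked diurnal
    template + AR(1) noise, clipped at zero.
    """
    if n_hours < 24:
        raise ContractError("need at least 24 hours (diurnal template undefined)")
    rng = np.random.default_rng(seed)
    idx = _hourly_index(n_hours, start)
    hours = idx.hour.to_numpy(dtype=float)
    series = (
        params.baseline
        + _seasonal_cycle(idx, params.seasonal_amp)
        + _diurnal_template(hours, params.diurnal_amps)
        + _ar1(n_hours, params.ar1_rho, params.ar1_sd, rng)
    )
    return pd.Series(np.clip(series, 0.0, None), index=idx, name="true_pm")


def simulate_rh(
    n_hours: int,
    seed: int,
    start: str = "2022-10-27 00:00",
    monthly_means: tuple[float, ...] = RH_MONTHLY_MEANS,
    diurnal_amp: float = 6.0,
    noise_sd: float = 4.0,
    rho: float = 0.7,
) -> pd.Series:
    """Hourly relative humidity (%), clipped to [20, 100].

    Monthly means follow the configured annual cycle (~74-86 %); the
    diurnal component is anti-phase with temperature (driest mid-afternoon).
    """
    rng = np.random.default_rng(seed)
    idx = _hourly_index(n_hours, start)
    month_mean = np.asarray(monthly_means)[idx.month.to_numpy() - 1]
    hours = idx.hour.to_numpy(dtype=float)
    diurnal = -diurnal_amp * np.cos(2.0 * np.pi * (hours - 15.0) / 24.0)
    series = month_mean + diurnal + _ar1(n_hours, rho, noise_sd, rng)
    return pd.Series(np.clip(series, 20.0, 100.0), index=idx, name="rh")


def simulate_temperature(
    n_hours: int,
    seed: int,
    start: str = "2022-10-27 00:00",
    mean: float = 23.0,
    diurnal_amp: float = 5.0,
    noise_sd: float = 1.5,
) -> pd.Series:
    """Hourly ambient temperature (°C): diurnal cycle peaking mid-afternoon."""
    rng = np.random.default_rng(seed)
    idx = _hourly_index(n_hours, start)
    hours = idx.hour.to_numpy(dtype=float)
    series = mean + diurnal_amp * np.cos(2.0 * np.pi * (hours - 15.0) / 24.0)
    series = series + _ar1(n_hours, 0.8, noise_sd, rng)
    return pd.Series(series, index=idx, name="temperature")


def simulate_pressure(
    n_hours: int,
    seed: int,
    start: str = "2022-10-27 00:00",
    mean: float = 1013.0,
    noise_sd: float = 1.0,
) -> pd.Series:
    """Hourly barometric pressure (hPa): near-constant with slow noise."""
    rng = np.random.default_rng(seed)
    idx = _hourly_index(n_hours, start)
    return pd.Series(mean + _ar1(n_hours, 0.95, noise_sd, rng), index=idx, name="pressure")


def _disaggregate(
    hourly: np.ndarray,
    n_per: int,
    rng: np.random.Generator,
    jitter_sigma: float = 0.0,
    preserve_mean: bool = True,
) -> np.ndarray:
    """Spread hourly values onto an ``n_per``-per-hour grid.

    Linear interpolation between hour centres, then each hour's segment is
    rescaled so its mean equals the hourly value exactly — plain
    interpolation smooths across hours and would attenuate any regression
    slope estimated from re-aggregated data.  Optional mean-one lognormal
    jitter roughens the sub-hourly trace.
    """
    n = len(hourly)
    centres = np.arange(n) + 0.5
    fine_t = (np.arange(n * n_per) + 0.5) / n_per
    fine = np.interp(fine_t, centres, hourly)
    if preserve_mean:
        seg = fine.reshape(n, n_per)
        seg_mean = seg.mean(axis=1)
        scale = np.divide(hourly, seg_mean, out=np.ones(n), where=seg_mean > 0)
        fine = (seg * scale[:, None]).ravel()
    if jitter_sigma > 0:
        fine = fine * np.exp(rng.normal(0.0, jitter_sigma, size=fine.size) - jitter_sigma**2 / 2)
    return fine


def _fine_index(idx: pd.DatetimeIndex, minutes: int) -> pd.DatetimeIndex:
    per = 60 // minutes
    offsets = pd.to_timedelta(np.arange(per) * minutes, unit="m")
    return pd.DatetimeIndex(np.add.outer(idx.values, offsets.values).ravel())


def derive_raw_sensor(
    true_pm: pd.Series,
    rh: pd.Series,
    params: TruthParams,
    seed: int,
    temperature: pd.Series | None = None,
    pressure: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """2-min dual-channel raw sensor records consistent with the truth.

    The hourly latent raw signal is the calibration relation inverted,
    ``raw = (true - beta0 - beta2*rh) / beta1`` floored at 0.  Channels A
    and B multiply it by independent mean-one lognormal noise; in fault
    hours one channel is scaled by a factor drawn uniformly from [2, 5]
    so the hour trips the A/B agreement filter; ``missing_rate`` of hours
    are dropped entirely.

    Returns the 2-min record frame and a boolean hourly fault-flag series.
    """
    if params.beta1 == 0:
        raise ConfigError("beta1 = 0: calibration relation cannot be inverted")
    if not true_pm.index.equals(rh.index):
        raise ContractError("true_pm and rh series are not aligned")
    rng = np.random.default_rng(seed)
    idx = true_pm.index
    n = len(idx)
    if temperature is None:
        temperature = simulate_temperature(n, seed + 1, start=str(idx[0]))
    if pressure is None:
        pressure = simulate_pressure(n, seed + 2, start=str(idx[0]))

    latent = np.clip(
        (true_pm.to_numpy() - params.beta0 - params.beta2 * rh.to_numpy()) / params.beta1,
        0.0,
        None,
    )
    s = params.chan_sigma
    chan_a = latent * np.exp(rng.normal(0.0, s, n) - s**2 / 2)
    chan_b = latent * np.exp(rng.normal(0.0, s, n) - s**2 / 2)

    fault = rng.random(n) < params.fault_rate
    factors = rng.uniform(2.0, 5.0, size=n)
    hit_a = rng.random(n) < 0.5
    chan_a = np.where(fault & hit_a, chan_a * factors, chan_a)
    chan_b = np.where(fault & ~hit_a, chan_b * factors, chan_b)

    fine_idx = _fine_index(idx, MINUTES_PER_INTERVAL)
    records = pd.DataFrame(
        {
            "timestamp": fine_idx,
            "pm_a_cf1": _disaggregate(chan_a, INTERVALS_PER_HOUR, rng, params.jitter_sigma),
            "pm_b_cf1": _disaggregate(chan_b, INTERVALS_PER_HOUR, rng, params.jitter_sigma),
            "temperature": _disaggregate(temperature.to_numpy(), INTERVALS_PER_HOUR, rng),
            "rh": np.clip(_disaggregate(rh.to_numpy(), INTERVALS_PER_HOUR, rng), 0.0, 100.0),
            "pressure": _disaggregate(pressure.to_numpy(), INTERVALS_PER_HOUR, rng),
        }
    )
    if params.missing_rate > 0:
        keep_hour = rng.random(n) >= params.missing_rate
        records = records[np.repeat(keep_hour, INTERVALS_PER_HOUR)].reset_index(drop=True)
    fault_flags = pd.Series(fault, index=idx, name="fault")
    return records, fault_flags


def simulate_reference(
    true_pm: pd.Series,
    seed: int,
    cf_median: float = 1.30,
    cf_log_sd: float = 0.12,
    cf_outlier_rate: float = 0.0,
    ref_sigma: float = 4.44,
    neph_sigma: float = 0.02,
    flow_l_min: float = 2.0,
    blank_mean: float = 0.020,
    blank_sd: float = 0.008,
    weigh_sd: float = 0.003,
    n_blanks: int = 3,
    tare_mass: float = 140.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Collocated reference streams: 5-min nephelometer + weekly filters.

    Each full week draws a true correction factor lognormally (truncated
    at ±2 SD) around ``cf_median``; ``cf_outlier_rate`` of weeks have
    their *filter mass* corrupted by a gross handling artifact (×[0.3,
    0.5] or ×[1.8, 2.5]) of the kind the downstream Tukey-fence rule is
    designed to repair.  The nephelometric stream is the true concentration
    plus hourly additive reference noise ``N(0, ref_sigma)`` (the
    residual scatter of the calibration relation lives on the reference
    side, independent of the raw sensor signal), divided by that factor
    (the bias the gravimetric correction must undo), with small
    multiplicative instrument noise.  Filter net mass integrates the true
    concentration over the sampled volume at ``flow_l_min``, plus a blank
    artifact and weighing noise; ``n_blanks`` field blanks carry the
    artifact only.  Output is truncated to full 168-hour weeks.

    Returns ``(neph_5min, filters, cf_true)``; masses in mg, flows L/min.
    """
    n_weeks = len(true_pm) // HOURS_PER_WEEK
    if n_weeks < 1:
        raise ContractError("need at least one full week of true PM")
    rng = np.random.default_rng(seed)
    truth = true_pm.iloc[: n_weeks * HOURS_PER_WEEK]
    week_ids = [f"W{k + 1:03d}" for k in range(n_weeks)]

    # lognormal truncated at ±2 SD: the heavy tails of field CF distributions
    # are filter-handling artifacts, injected into the filter masses below
    z = np.clip(rng.normal(0.0, 1.0, size=n_weeks), -2.0, 2.0)
    cf_true = pd.Series(
        cf_median * np.exp(cf_log_sd * z),
        index=pd.Index(week_ids, name="week_id"),
        name="cf_true",
    )
    bad_week = rng.random(n_weeks) < cf_outlier_rate
    direction = rng.random(n_weeks) < 0.5
    artifact = np.where(bad_week,
                        np.where(direction, rng.uniform(0.3, 0.5, n_weeks),
                                 rng.uniform(1.8, 2.5, n_weeks)),
                        1.0)

    fine_idx = _fine_index(truth.index, 5)
    hourly_eps = rng.normal(0.0, ref_sigma, size=len(truth))
    observed = np.clip(truth.to_numpy() + hourly_eps, 0.0, None)
    fine_true = _disaggregate(observed, NEPH_PER_HOUR, rng)
    week_per_point = np.repeat(cf_true.to_numpy(), HOURS_PER_WEEK * NEPH_PER_HOUR)
    noise = np.exp(rng.normal(0.0, neph_sigma, fine_true.size) - neph_sigma**2 / 2)
    neph = pd.DataFrame(
        {
            "timestamp": fine_idx,
            "pm25": np.clip(fine_true / week_per_point * noise, 0.0, None),
            "week_id": np.repeat(week_ids, HOURS_PER_WEEK * NEPH_PER_HOUR),
        }
    )

    minutes_per_week = HOURS_PER_WEEK * 60
    volume_m3 = flow_l_min * minutes_per_week / 1000.0
    rows = []
    weekly_mean = truth.to_numpy().reshape(n_weeks, HOURS_PER_WEEK).mean(axis=1)
    for wid, wmean, art in zip(week_ids, weekly_mean, artifact):
        deposited_mg = wmean * volume_m3 / 1000.0 * art  # µg/m³ × m³ → µg → mg
        pre = tare_mass + rng.normal(0.0, 0.5)
        post = pre + deposited_mg + blank_mean + rng.normal(0.0, weigh_sd)
        rows.append((wid, pre, post, False, flow_l_min, minutes_per_week))
    for b in range(n_blanks):
        pre = tare_mass + rng.normal(0.0, 0.5)
        post = pre + blank_mean + rng.normal(0.0, blank_sd)
        rows.append((f"BLK{b + 1}", pre, post, True, flow_l_min, minutes_per_week))
    filters = pd.DataFrame(
        rows,
        columns=["week_id", "pre_mass", "post_mass", "is_blank", "flow", "minutes_sampled"],
    )
    return neph, filters, cf_true


# ---------------------------------------------------------------------------
# whole-network bundle


@dataclass
class SimulatedBundle:
    """All artifacts of one simulated deployment, with truth tables."""

    sites: pd.DataFrame
    sensor_records: dict = field(default_factory=dict)  # site_id -> 2-min DataFrame
    neph_5min: pd.DataFrame | None = None
    filters: pd.DataFrame | None = None
    truth_hourly: pd.DataFrame | None = None            # site_id, hour, true_pm, fault
    cf_true: pd.Series | None = None
    collocation_site: str = ""


def _make_sites(n_rural: int, n_masaka: int, n_kampala: int, rng: np.random.Generator) -> list[Site]:
    sites = []
    for i in range(n_rural):
        sites.append(
            Site(
                f"R{i + 1:02d}",
                lat=-0.72 + rng.uniform(-0.25, 0.25),
                lon=31.45 + rng.uniform(-0.25, 0.25),
                setting="rural",
            )
        )
    for i in range(n_masaka):
        sites.append(
            Site(
                f"M{i + 1:02d}",
                lat=-0.34 + rng.uniform(-0.03, 0.03),
                lon=31.73 + rng.uniform(-0.03, 0.03),
                setting="urban",
                city="Masaka",
            )
        )
    for i in range(n_kampala):
        sites.append(
            Site(
                f"K{i + 1:02d}",
                lat=0.31 + rng.uniform(-0.05, 0.05),
                lon=32.58 + rng.uniform(-0.05, 0.05),
                setting="urban",
                city="Kampala",
            )
        )
    return sites


def simulate_bundle(
    n_hours: int,
    seed: int,
    start: str = "2022-10-27 00:00",
    n_rural: int = 18,
    n_masaka: int = 4,
    n_kampala: int = 5,
    params_overrides: dict | None = None,
) -> SimulatedBundle:
    """Simulate the full deployment: 27 sensor sites, one collocated reference.

    The collocation site is the first rural site (the reference sampler sat
    at a rural office in the study design).  ``params_overrides`` are
    applied to every site's :class:`TruthParams` (e.g. fault/missing rates).
    """
    rng = np.random.default_rng(seed)
    site_objs = _make_sites(n_rural, n_masaka, n_kampala, rng)
    sites = pd.DataFrame(
        [
            {"site_id": s.site_id, "lat": s.lat, "lon": s.lon, "setting": s.setting,
             "city": s.city or ""}
            for s in site_objs
        ]
    )
    overrides = params_overrides or {}
    bundle = SimulatedBundle(sites=sites, collocation_site=site_objs[0].site_id)
    truth_frames = []
    for i, s in enumerate(site_objs):
        site_seed = (seed * 1_000_003 + 7 * i + 1) % (2**31)
        params = default_truth_params(s.setting, s.city, **overrides)
        true_pm = simulate_true_pm(n_hours, params, site_seed, start)
        rh = simulate_rh(n_hours, site_seed + 101, start)
        records, fault = derive_raw_sensor(true_pm, rh, params, site_seed + 202)
        records.insert(0, "site_id", s.site_id)
        bundle.sensor_records[s.site_id] = records
        truth_frames.append(
            pd.DataFrame(
                {"site_id": s.site_id, "hour": true_pm.index,
                 "true_pm": true_pm.to_numpy(), "fault": fault.to_numpy()}
            )
        )
        if s.site_id == bundle.collocation_site:
            neph, filters, cf_true = simulate_reference(
                true_pm, site_seed + 303, ref_sigma=params.sigma
            )
            bundle.neph_5min, bundle.filters, bundle.cf_true = neph, filters, cf_true
    bundle.truth_hourly = pd.concat(truth_frames, ignore_index=True)
    return bundle
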