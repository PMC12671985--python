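"""Seasonal, diurnal and spatial summaries of calibrated network data.

Seasons follow the equatorial bimodal rainfall calendar: wet in
March-May and September-November, dry otherwise.  Group comparisons use
the Mann-Whitney U test; the combined effect of setting and season is
assessed with the Scheirer-Ray-Hare extension of the Kruskal-Wallis test
(two-way ANOVA on global ranks).  Spatial surfaces are inverse-distance
weighted interpolations on great-circle distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import WET_MONTHS_DEFAULT
from .errors import ContractError

__all__ = [
    "label_season",
    "seasonal_summary",
    "percent_excess",
    "mann_whitney",
    "interaction_test",
    "biweekly_means",
    "diurnal_profile",
    "idw_interpolate",
]

EARTH_RADIUS_M = 6_371_000.0


def label_season(timestamps, wet_months=WET_MONTHS_DEFAULT):
    """Map timestamps to ``"wet"``/``"dry"`` by month."""
    months = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype="datetime64[ns]"))).month
    wet = set(wet_months)
    labels = np.where(np.isin(months, list(wet)), "wet", "dry")
    if np.isscalar(timestamps) or isinstance(timestamps, (str, pd.Timestamp)):
        return str(labels[0])
    return labels


def _stratum_stats(values: pd.Series) -> dict:
    q1, med, q3 = values.quantile([0.25, 0.5, 0.75])
    return {
        "n_obs": int(len(values)),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def seasonal_summary(
    calibrated: pd.DataFrame,
    sites: pd.DataFrame,
    wet_months=WET_MONTHS_DEFAULT,
) -> pd.DataFrame:
    """Stratified summary of hourly calibrated PM2.5.

    ``calibrated`` needs ``site_id, hour, pm25_cal``.  Strata are
    setting × season (rural/urban × wet/dry) plus each named city ×
    season.  Hourly values are pooled (observation-weighted) within a
    stratum.
    """
    unknown = set(calibrated["site_id"]) - set(sites["site_id"])
    if unknown:
        raise ContractError(f"unknown site_id(s): {sorted(unknown)}")
    df = calibrated.merge(sites[["site_id", "setting", "city"]], on="site_id", how="left")
    df["season"] = label_season(df["hour"].to_numpy(), wet_months)
    rows = []
    for (setting, season), grp in df.groupby(["setting", "season"]):
        rows.append({"stratum": setting, "season": season, **_stratum_stats(grp["pm25_cal"])})
    for (city, season), grp in df[df["city"].astype(str) != ""].groupby(["city", "season"]):
        rows.append({"stratum": city, "season": season, **_stratum_stats(grp["pm25_cal"])})
    return pd.DataFrame(rows).sort_values(["stratum", "season"]).reset_index(drop=True)


def percent_excess(mean_urban: float, mean_rural: float) -> int:
    """Urban-over-rural excess as an integer percentage, round(100·(u/r − 1))."""
    if mean_rural <= 0:
        raise ContractError("rural mean must be positive")
    return int(round(100.0 * (mean_urban / mean_rural - 1.0)))


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when the pooled sample is small (n_x + n_y ≤ 12)
    and tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Returns ``(U_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def interaction_test(values, factor_a, factor_b) -> pd.DataFrame:
    """Scheirer-Ray-Hare test: nonparametric two-way factorial on ranks.

    Ranks all values globally (midranks for ties), computes two-way ANOVA
    sums of squares on the ranks, and scales each effect's SS by the total
    rank variance MS = SS_total/(N−1); H is referred to a chi-square with
    the effect's df.  Returns a frame with rows ``factor_a``, ``factor_b``,
    ``interaction`` and columns ``df, H, p``.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "a": np.asarray(factor_a),
        "b": np.asarray(factor_b),
    })
    cell_counts = df.groupby(["a", "b"]).size()
    levels_a, levels_b = df["a"].nunique(), df["b"].nunique()
    if len(cell_counts) < levels_a * levels_b or (cell_counts < 2).any():
        raise ContractError("every factor-level cell needs at least 2 observations")
    if levels_a < 2 or levels_b < 2:
        raise ContractError("both factors need at least 2 levels")
    df["r"] = stats.rankdata(df["y"])
    n = len(df)
    grand = df["r"].mean()
    ss_total = float(((df["r"] - grand) ** 2).sum())
    ms_total = ss_total / (n - 1)
    if ms_total == 0:  # all values tied: no evidence against any null
        return pd.DataFrame({
            "effect": ["factor_a", "factor_b", "interaction"],
            "df": [levels_a - 1, levels_b - 1, (levels_a - 1) * (levels_b - 1)],
            "H": [0.0, 0.0, 0.0],
            "p": [1.0, 1.0, 1.0],
        })

    def ss_between(groups) -> float:
        return float(sum(len(g) * (g["r"].mean() - grand) ** 2 for _, g in groups))

    ss_a = ss_between(df.groupby("a"))
    ss_b = ss_between(df.groupby("b"))
    ss_cells = ss_between(df.groupby(["a", "b"]))
    ss_ab = ss_cells - ss_a - ss_b

    rows = []
    for name, ss, dof in (
        ("factor_a", ss_a, levels_a - 1),
        ("factor_b", ss_b, levels_b - 1),
        ("interaction", ss_ab, (levels_a - 1) * (levels_b - 1)),
    ):
        h = max(ss, 0.0) / ms_total
        rows.append({"effect": name, "df": dof, "H": h,
                     "p": float(stats.chi2.sf(h, dof))})
    return pd.DataFrame(rows)


def biweekly_means(
    calibrated: pd.DataFrame,
    sites: pd.DataFrame,
    group: str = "setting",
) -> pd.DataFrame:
    """Mean PM2.5 in consecutive 14-day bins anchored at the first timestamp.

    ``group`` is ``"setting"`` (urban/rural pooled), ``"site"``, or a
    column of ``sites``.  Bins with no data are emitted as missing.
    """
    df = calibrated.merge(sites[["site_id", "setting", "city"]], on="site_id", how="left")
    t = pd.to_datetime(df["hour"])
    start = t.min()
    span_h = (t.max() - start).total_seconds() / 3600.0
    if span_h < 14 * 24 - 1:
        raise ContractError("need at least 14 days of data for biweekly means")
    df["bin"] = ((t - start).dt.total_seconds() // (336 * 3600)).astype(int)
    key = "site_id" if group == "site" else group
    n_bins = int(df["bin"].max()) + 1
    out = (
        df.groupby([key, "bin"])["pm25_cal"].mean().rename("mean_pm25").reset_index()
    )
    full = pd.MultiIndex.from_product(
        [sorted(df[key].unique()), range(n_bins)], names=[key, "bin"]
    )
    out = out.set_index([key, "bin"]).reindex(full).reset_index()
    out["bin_start"] = start + pd.to_timedelta(out["bin"] * 336, unit="h")
    return out


def diurnal_profile(calibrated: pd.DataFrame, sites: pd.DataFrame | None = None,
                    group: str | None = None) -> pd.DataFrame:
    """Median and quartiles of PM2.5 by local clock hour (0-23).

    Optionally stratified by a grouping column of the site table.  Clock
    hours with no data yield missing rows with a warning.
    """
    df = calibrated.copy()
    if group is not None:
        if sites is None:
            raise ContractError("grouping requires a site table")
        df = df.merge(sites[["site_id", "setting", "city"]], on="site_id", how="left")
    df["clock_hour"] = pd.to_datetime(df["hour"]).dt.hour
    keys = ([group] if group else []) + ["clock_hour"]
    prof = (
        df.groupby(keys)["pm25_cal"]
        .agg(median="median", q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
    )
    groups = [None] if not group else sorted(df[group].unique())
    frames = []
    for g in groups:
        sub = prof if g is None else prof[prof[group] == g]
        missing = set(range(24)) - set(sub["clock_hour"])
        if missing:
            warnings.warn(f"no data for clock hour(s) {sorted(missing)}", stacklevel=2)
            pad = pd.DataFrame({"clock_hour": sorted(missing)})
            if g is not None:
                pad[group] = g
            sub = pd.concat([sub, pad], ignore_index=True)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True).sort_values(keys).reset_index(drop=True)


def _great_circle_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in metres (broadcasting)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def idw_interpolate(
    site_values: pd.DataFrame,
    query_points: pd.DataFrame,
    power: float = 2.0,
    exact_hit_m: float = 1.0,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation on great-circle distances.

    ``site_values`` needs ``lat, lon, value``; rows with missing values
    are dropped.  A query within ``exact_hit_m`` metres of a site returns
    that site's value.  Output is a convex combination, hence bounded by
    the input value range.
    """
    if power <= 0:
        raise ContractError("power must be positive")
    sv = site_values.dropna(subset=["value"])
    if sv.empty:
        raise ContractError("no sites with values")
    s_lat = sv["lat"].to_numpy()[None, :]
    s_lon = sv["lon"].to_numpy()[None, :]
    q_lat = np.asarray(query_points["lat"], dtype=float)[:, None]
    q_lon = np.asarray(query_points["lon"], dtype=float)[:, None]
    d = _great_circle_m(q_lat, q_lon, s_lat, s_lon)
    vals = sv["value"].to_numpy()
    out = np.empty(d.shape[0])
    hits = d < exact_hit_m
    for i in range(d.shape[0]):
        if hits[i].any():
            out[i] = vals[np.argmin(d[i])]
        else:
            w = d[i] ** (-power)
            out[i] = float(np.dot(w, vals) / w.sum())
    return out
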