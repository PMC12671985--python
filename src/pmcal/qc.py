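"""Cleaning and hourly aggregation of dual-channel optical sensor data.

The cleaning chain, applied per device:

1. aggregate 2-min cf=1 readings to clock hours (left-closed bins), with
   a completeness fraction out of the 30 expected intervals;
2. exclude hours where channels A and B disagree by **both** more than
   5 µg/m³ and more than 70 % of their mean;
3. average the surviving channels and replace values under 1 µg/m³ with
   1/√2 µg/m³ (optical sensors are unreliable at very low mass loadings).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .types import FLOOR_SUBSTITUTE

__all__ = [
    "aggregate_hourly",
    "ab_agreement_filter",
    "floor_low_values",
    "combine_channels",
    "qc_hourly",
]

EXPECTED_INTERVALS_PER_HOUR = 30

FLAG_LOW_COMPLETENESS = "LOW_COMPLETENESS"
FLAG_AB_FAIL = "AB_FAIL"
FLAG_FLOORED = "FLOORED"

_MET_COLS = ("rh", "temperature", "pressure")


def aggregate_hourly(
    records: pd.DataFrame,
    min_completeness: float = 0.75,
    expected_per_hour: int = EXPECTED_INTERVALS_PER_HOUR,
) -> pd.DataFrame:
    """Aggregate one site's 2-min records to hourly channel pairs.

    Returns one row per clock hour present in the data with columns
    ``hour, mean_a, mean_b, rh, temperature, pressure, n_intervals,
    completeness, low_completeness`` (``site_id`` carried through when
    present).  Hours below ``min_completeness`` are flagged, not dropped;
    downstream steps exclude them.
    """
    if "site_id" in records.columns and records["site_id"].nunique() > 1:
        raise ContractError(
            f"aggregate_hourly expects one site, got {sorted(records['site_id'].unique())}"
        )
    df = records.copy()
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.floor("h")
    agg = {
        "pm_a_cf1": "mean",
        "pm_b_cf1": "mean",
        **{c: "mean" for c in _MET_COLS if c in df.columns},
        "timestamp": "size",
    }
    hourly = df.groupby("hour").agg(agg).rename(
        columns={"pm_a_cf1": "mean_a", "pm_b_cf1": "mean_b", "timestamp": "n_intervals"}
    )
    hourly["completeness"] = hourly["n_intervals"] / expected_per_hour
    hourly["low_completeness"] = hourly["completeness"] < min_completeness
    hourly = hourly.reset_index()
    if "site_id" in records.columns and len(records):
        hourly.insert(0, "site_id", records["site_id"].iloc[0])
    return hourly


def ab_agreement_filter(
    mean_a,
    mean_b,
    pct_threshold: float = 70.0,
    abs_threshold: float = 5.0,
):
    """Keep/exclude decision for hourly channel pairs (vectorised).

    An hour is excluded only when the channel deviation exceeds *both*
    thresholds: ``|A−B| > abs_threshold`` **and**
    ``100·|A−B| / ((A+B)/2) > pct_threshold``.  The percent difference of
    an all-zero pair is defined as 0.  Returns True where the hour is kept.
    """
    if pct_threshold < 0 or abs_threshold < 0:
        raise ConfigError("A/B agreement thresholds must be nonnegative")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    diff = np.abs(a - b)
    mean = (a + b) / 2.0
    pct = np.divide(100.0 * diff, mean, out=np.zeros_like(diff), where=mean != 0)
    keep = ~((diff > abs_threshold) & (pct > pct_threshold))
    if np.isscalar(mean_a) and np.isscalar(mean_b):
        return bool(keep)
    return keep


def floor_low_values(
    values,
    floor: float = 1.0,
    substitute: float = FLOOR_SUBSTITUTE,
) -> tuple[np.ndarray, int]:
    """Replace values strictly under ``floor`` with ``substitute``.

    Returns the substituted array and the substitution count.  The
    boundary is strict: a value exactly at the floor is unchanged.
    """
    if not substitute < floor:
        raise ConfigError("substitute must be below floor")
    arr = np.asarray(values, dtype=float)
    mask = arr < floor
    out = np.where(mask, substitute, arr)
    return out, int(mask.sum())


def combine_channels(pair: pd.Series | dict, floor: float = 1.0,
                     substitute: float = FLOOR_SUBSTITUTE) -> tuple[float, bool]:
    """Average channels A and B of one kept hour, then apply the low floor.

    Returns ``(pa_cf1, floored)``.  Calling this on an hour the agreement
    filter excluded is a contract violation.
    """
    a, b = float(pair["mean_a"]), float(pair["mean_b"])
    if not ab_agreement_filter(a, b):
        raise ContractError("combine_channels called on an A/B-excluded hour")
    value = (a + b) / 2.0
    out, n = floor_low_values([value], floor, substitute)
    return float(out[0]), bool(n)


def qc_hourly(
    records: pd.DataFrame,
    pct_threshold: float = 70.0,
    abs_threshold: float = 5.0,
    min_completeness: float = 0.75,
    floor: float = 1.0,
    substitute: float = FLOOR_SUBSTITUTE,
) -> tuple[pd.DataFrame, dict]:
    """Full QC chain for one site's raw records.

    Returns the hourly frame (all hours, with ``qc_flags`` and ``pa_cf1``
    set only for hours passing every filter) and an accounting dict with
    rows in/out per rule.
    """
    hourly = aggregate_hourly(records, min_completeness)
    keep_ab = ab_agreement_filter(
        hourly["mean_a"].to_numpy(), hourly["mean_b"].to_numpy(), pct_threshold, abs_threshold
    )
    hourly["ab_fail"] = ~keep_ab
    ok = ~hourly["low_completeness"] & keep_ab
    pa = (hourly["mean_a"] + hourly["mean_b"]).to_numpy() / 2.0
    floored_vals, _ = floor_low_values(pa, floor, substitute)
    hourly["pa_cf1"] = np.where(ok, floored_vals, np.nan)
    hourly["floored"] = ok & (pa < floor)

    flags = []
    for low, ab, fl in zip(hourly["low_completeness"], hourly["ab_fail"], hourly["floored"]):
        tokens = []
        if low:
            tokens.append(FLAG_LOW_COMPLETENESS)
        if ab:
            tokens.append(FLAG_AB_FAIL)
        if fl:
            tokens.append(FLAG_FLOORED)
        flags.append(";".join(tokens))
    hourly["qc_flags"] = flags

    accounting = {
        "hours_in": int(len(hourly)),
        "hours_low_completeness": int(hourly["low_completeness"].sum()),
        "hours_ab_excluded": int(hourly["ab_fail"].sum()),
        "hours_out": int(ok.sum()),
        "values_floored": int(hourly["floored"].sum()),
    }
    return hourly, accounting
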