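"""Gravimetric correction of the nephelometric reference stream.

A light-scattering monitor drifts with humidity and particle composition,
so each week's 5-min nephelometric readings are rescaled by the ratio of
the filter-weighed mean concentration to the nephelometric weekly mean.
Filter masses are blank-corrected and censored at the limit of detection
(3 × SD of field blanks); implausible weekly correction factors (outside
Tukey fences of the CF distribution) are replaced by the median CF.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ContractError
from .qc import floor_low_values
from .types import FLOOR_SUBSTITUTE

__all__ = [
    "compute_lod",
    "blank_correct_and_censor",
    "filter_concentration",
    "weekly_correction_factor",
    "fence_correction_factors",
    "apply_correction",
    "gravimetric_reference",
]


def compute_lod(blank_net_masses) -> float:
    """Limit of detection: 3 × sample SD (ddof=1) of blank net masses (mg)."""
    blanks = np.asarray(blank_net_masses, dtype=float)
    if blanks.size < 2:
        raise ContractError("need at least 2 blanks to compute an LOD")
    return 3.0 * float(np.std(blanks, ddof=1))


def blank_correct_and_censor(
    sample_net_mass: float, mean_blank: float, lod: float
) -> tuple[float, bool]:
    """Blank-correct a net mass and censor below-LOD values to LOD/√2 (mg)."""
    if lod < 0:
        raise ContractError("LOD must be nonnegative")
    corrected = sample_net_mass - mean_blank
    if corrected < lod:
        return lod / math.sqrt(2.0), True
    return corrected, False


def filter_concentration(corrected_mass: float, flow: float, minutes: float) -> float:
    """Mean concentration over the sampling period, µg/m³.

    ``corrected_mass`` in mg, ``flow`` in L/min.  Volume = flow × minutes
    / 1000 m³.
    """
    if flow <= 0 or minutes <= 0:
        raise ContractError("flow and minutes must be positive")
    volume_m3 = flow * minutes / 1000.0
    return corrected_mass * 1000.0 / volume_m3


def weekly_correction_factor(filter_conc: float, neph_week_mean: float) -> float:
    """Ratio of filter-based to weekly-mean nephelometric concentration."""
    if neph_week_mean <= 0:
        raise ContractError("weekly nephelometric mean must be positive")
    return filter_conc / neph_week_mean


def fence_correction_factors(raw_cfs: pd.Series | list) -> pd.DataFrame:
    """Replace outlying weekly CFs by the median CF.

    Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with linear-interpolation
    quantiles; CFs *strictly* outside are replaced by the median of the
    raw (pre-replacement) CFs.  Returns a frame with ``week_id`` (when the
    input is an indexed Series), ``raw_cf``, ``final_cf``, ``fenced``.
    """
    cfs = pd.Series(raw_cfs, dtype=float)
    if len(cfs) < 4:
        raise ContractError("need at least 4 weekly CFs to fence")
    q1, q3 = cfs.quantile([0.25, 0.75], interpolation="linear")
    iqr = q3 - q1
    low, high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    median = cfs.median()
    fenced = (cfs < low) | (cfs > high)
    out = pd.DataFrame(
        {
            "raw_cf": cfs.to_numpy(),
            "final_cf": np.where(fenced, median, cfs.to_numpy()),
            "fenced": fenced.to_numpy(),
        },
        index=cfs.index,
    )
    out.attrs["fences"] = (float(low), float(high))
    out.attrs["median_cf"] = float(median)
    return out


def apply_correction(
    neph_5min: pd.DataFrame,
    cfs: pd.DataFrame,
    floor: float = 1.0,
    substitute: float = FLOOR_SUBSTITUTE,
) -> pd.DataFrame:
    """Correct and hourly-average the 5-min nephelometric stream.

    ``neph_5min`` needs ``timestamp, pm25, week_id`` columns; ``cfs`` is
    indexed by ``week_id`` with a ``final_cf`` column.  5-min values under
    the floor are substituted with 1/√2 *before* multiplication, then the
    corrected stream is averaged to clock hours.
    """
    missing = set(neph_5min["week_id"].unique()) - set(cfs.index)
    if missing:
        orphans = neph_5min.loc[neph_5min["week_id"].isin(missing), "timestamp"]
        raise ContractError(
            f"no correction factor for weeks {sorted(missing)}; "
            f"{len(orphans)} uncovered timestamps starting {orphans.min()}"
        )
    values, _ = floor_low_values(neph_5min["pm25"].to_numpy(), floor, substitute)
    cf_per_row = cfs["final_cf"].reindex(neph_5min["week_id"]).to_numpy()
    df = pd.DataFrame(
        {
            "hour": pd.to_datetime(neph_5min["timestamp"]).dt.floor("h"),
            "pm25_ref": values * cf_per_row,
            "week_id": neph_5min["week_id"].to_numpy(),
        }
    )
    hourly = (
        df.groupby("hour")
        .agg(pm25_ref=("pm25_ref", "mean"), week_id=("week_id", "first"))
        .reset_index()
    )
    hourly["corrected"] = True
    return hourly


def gravimetric_reference(
    neph_5min: pd.DataFrame,
    filters: pd.DataFrame,
    floor: float = 1.0,
    substitute: float = FLOOR_SUBSTITUTE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full reference chain: filters + nephelometer → corrected hourly series.

    ``filters`` holds one row per filter with ``week_id, pre_mass,
    post_mass, is_blank, flow, minutes_sampled``.  Returns
    ``(reference_hourly, correction_factors)``.
    """
    filt = filters.copy()
    filt["net_mass"] = filt["post_mass"] - filt["pre_mass"]
    blanks = filt.loc[filt["is_blank"], "net_mass"]
    lod = compute_lod(blanks)
    mean_blank = float(blanks.mean())

    samples = filt.loc[~filt["is_blank"]].set_index("week_id")
    raw_cfs = {}
    censored = {}
    neph_week_mean = neph_5min.groupby("week_id")["pm25"].mean()
    for wid, row in samples.iterrows():
        mass, cens = blank_correct_and_censor(row["net_mass"], mean_blank, lod)
        conc = filter_concentration(mass, row["flow"], row["minutes_sampled"])
        raw_cfs[wid] = weekly_correction_factor(conc, float(neph_week_mean[wid]))
        censored[wid] = cens
    cfs = fence_correction_factors(pd.Series(raw_cfs))
    cfs.index.name = "week_id"
    cfs["censored"] = pd.Series(censored)
    cfs.attrs["lod_mg"] = lod
    cfs.attrs["mean_blank_mg"] = mean_blank
    reference = apply_correction(neph_5min, cfs, floor, substitute)
    return reference, cfs
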