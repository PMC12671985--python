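"""CSV readers/writers and run manifests.

All concentrations are µg/m³, masses mg, flows L/min.  Timestamps are
timezone-naive local clock time (the deployment region has no DST).
Duplicate timestamps for one device are collapsed to the last occurrence
(SD-card/cloud merges can duplicate rows); malformed rows are counted
and logged, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .errors import EmptyInputError, FormatError
from .types import Site

logger = logging.getLogger("pmcal")

SENSOR_LOG_COLUMNS = ("timestamp", "pm_a_cf1", "pm_b_cf1", "temperature", "rh", "pressure")
SITE_COLUMNS = ("site_id", "lat", "lon", "setting")


def read_sensor_log(path, dialect: str = "two_channel_cf1") -> pd.DataFrame:
    """Read a 2-min dual-channel sensor log.

    Records are sorted by timestamp; duplicate timestamps per device keep
    the last occurrence.  Rows whose timestamp fails to parse are counted
    in ``df.attrs["n_malformed"]`` and logged.
    """
    if dialect != "two_channel_cf1":
        raise FormatError(f"unknown sensor-log dialect {dialect!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    for col in SENSOR_LOG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    n_malformed = int(ts.isna().sum())
    if n_malformed:
        logger.warning("%s: rejected %d row(s) with unparseable timestamps", path, n_malformed)
    df = df.assign(timestamp=ts).dropna(subset=["timestamp"])
    keys = ["site_id", "timestamp"] if "site_id" in df.columns else ["timestamp"]
    df = df.drop_duplicates(subset=keys, keep="last").sort_values("timestamp")
    df = df.reset_index(drop=True)
    df.attrs["n_malformed"] = n_malformed
    return df


def read_site_table(path) -> pd.DataFrame:
    """Read and validate the site table (site_id, lat, lon, setting[, city])."""
    df = pd.read_csv(path, dtype={"site_id": str})
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    for col in SITE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate site_id(s): {sorted(set(dupes))}")
    if "city" not in df.columns:
        df["city"] = ""
    df["city"] = df["city"].fillna("")
    for _, row in df.iterrows():  # Site.__post_init__ validates ranges and enum
        Site(row["site_id"], float(row["lat"]), float(row["lon"]), str(row["setting"]),
             str(row["city"]) or None)
    return df.reset_index(drop=True)


def write_manifest(path, stage: str, inputs: list, config_hash: str, seed: int,
                   rows: dict) -> None:
    """Write the per-stage run manifest (inputs, config hash, seed, row accounting)."""
    payload = {
        "stage": stage,
        "inputs": [str(p) for p in inputs],
        "config_hash": config_hash,
        "seed": seed,
        "rows": rows,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
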