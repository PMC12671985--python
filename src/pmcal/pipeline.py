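"""Stage orchestration: simulate → qc → gravcal → fit → apply → trends.

Each stage reads the previous stage's CSV artifacts from the output
directory, writes its own, and records a JSON manifest with row
accounting (rows_in = rows_out + rows_rejected for every filter).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import gravimetric as grav
from . import qc as qcmod
from . import spatiotemporal as st
from .config import PipelineConfig
from .errors import DependencyError
from .io import read_manifest, read_sensor_log, read_site_table, write_manifest
from .simulate import simulate_bundle

STAGES = ("simulate", "qc", "gravcal", "fit", "apply", "trends")


def _require(outdir: Path, filename: str, producer: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise DependencyError(
            f"missing artifact {filename!r}; run the {producer!r} stage first"
        )
    return path


def stage_simulate(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    bundle = simulate_bundle(
        n_hours=config.n_days * 24,
        seed=seed,
        start=config.start,
        n_rural=config.n_rural,
        n_masaka=config.n_masaka,
        n_kampala=config.n_kampala,
    )
    bundle.sites.to_csv(outdir / "sites.csv", index=False)
    records = pd.concat(bundle.sensor_records.values(), ignore_index=True)
    records.to_csv(outdir / "sensor_records.csv", index=False)
    bundle.neph_5min.to_csv(outdir / "neph_5min.csv", index=False)
    bundle.filters.to_csv(outdir / "filters.csv", index=False)
    bundle.truth_hourly.to_csv(outdir / "truth_hourly.csv", index=False)
    bundle.cf_true.rename_axis("week_id").reset_index().to_csv(
        outdir / "truth_cf.csv", index=False
    )
    rows = {
        "sites": len(bundle.sites),
        "sensor_records": len(records),
        "neph_5min": len(bundle.neph_5min),
        "filters": len(bundle.filters),
        "collocation_site": bundle.collocation_site,
    }
    write_manifest(outdir / "manifest_simulate.json", "simulate", [], config.content_hash(),
                   seed, rows)
    return rows


def stage_qc(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    path = _require(outdir, "sensor_records.csv", "simulate")
    records = read_sensor_log(path)
    frames, acct_total = [], {"hours_in": 0, "hours_low_completeness": 0,
                              "hours_ab_excluded": 0, "hours_out": 0, "values_floored": 0}
    for site_id, grp in records.groupby("site_id"):
        hourly, acct = qcmod.qc_hourly(
            grp,
            pct_threshold=config.pct_threshold,
            abs_threshold=config.abs_threshold,
            min_completeness=config.min_completeness,
            floor=config.floor,
            substitute=config.substitute,
        )
        frames.append(hourly)
        for k in acct_total:
            acct_total[k] += acct[k]
    hourly_all = pd.concat(frames, ignore_index=True)
    hourly_all.to_csv(outdir / "hourly_qc.csv", index=False)
    rows = {
        "rows_in": int(len(records)),
        "rows_malformed": int(records.attrs.get("n_malformed", 0)),
        **acct_total,
        "hours_rejected": acct_total["hours_in"] - acct_total["hours_out"],
    }
    write_manifest(outdir / "manifest_qc.json", "qc", [str(path)], config.content_hash(),
                   seed, rows)
    return rows


def stage_gravcal(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    neph_path = _require(outdir, "neph_5min.csv", "simulate")
    filt_path = _require(outdir, "filters.csv", "simulate")
    neph = pd.read_csv(neph_path, parse_dates=["timestamp"])
    filters = pd.read_csv(filt_path)
    reference, cfs = grav.gravimetric_reference(
        neph, filters, floor=config.floor, substitute=config.substitute
    )
    reference.to_csv(outdir / "reference_hourly.csv", index=False)
    cfs.reset_index().to_csv(outdir / "correction_factors.csv", index=False)
    rows = {
        "neph_rows_in": int(len(neph)),
        "reference_hours_out": int(len(reference)),
        "n_weeks": int(len(cfs)),
        "n_fenced": int(cfs["fenced"].sum()),
        "lod_mg": cfs.attrs["lod_mg"],
    }
    write_manifest(outdir / "manifest_gravcal.json", "gravcal",
                   [str(neph_path), str(filt_path)], config.content_hash(), seed, rows)
    return rows


def _collocation_site(outdir: Path) -> str:
    man = outdir / "manifest_simulate.json"
    if man.exists():
        return read_manifest(man)["rows"]["collocation_site"]
    sites = read_site_table(_require(outdir, "sites.csv", "simulate"))
    return str(sites["site_id"].iloc[0])


def stage_fit(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    qc_path = _require(outdir, "hourly_qc.csv", "qc")
    ref_path = _require(outdir, "reference_hourly.csv", "gravcal")
    hourly = pd.read_csv(qc_path, parse_dates=["hour"])
    reference = pd.read_csv(ref_path, parse_dates=["hour"])
    coll_site = _collocation_site(outdir)
    sensor = hourly[hourly["site_id"] == coll_site]

    obs = cal.build_collocation(sensor, reference)
    obs, n_removed = cal.residual_outlier_filter(obs, k_sd=config.residual_k_sd)
    train, test = cal.chronological_split(obs, config.train_fraction)

    comparison, final_fit = [], None
    for spec_id in config.models:
        spec = cal.ModelSpec.from_id(spec_id)
        fit = cal.fit_model(spec, train, seed=seed,
                            cv_params=(config.cv_initial, config.cv_horizon, config.cv_step))
        if not fit.converged:
            comparison.append({"model": spec_id, "converged": False})
            continue
        metrics = cal.evaluate(cal.predict(fit, test), test["pm25_ref"].to_numpy())
        comparison.append({"model": spec_id, "converged": True, **metrics.as_dict()})
        if spec_id == config.final_model:
            final_fit = fit
    if final_fit is None:
        final_fit = cal.fit_model(cal.ModelSpec.from_id(config.final_model), train, seed=seed)
    pd.DataFrame(comparison).to_csv(outdir / "model_comparison.csv", index=False)
    (outdir / "final_fit.json").write_text(json.dumps({
        "model": config.final_model,
        "coefficients": final_fit.coefficients,
        "std_errors": final_fit.std_errors,
        "resid_sd": final_fit.resid_sd,
        "n_train": final_fit.n_train,
        "df_resid": final_fit.df_resid,
    }, indent=2))
    rows = {
        "collocated_hours": int(obs.attrs.get("join_stats", {}).get("collocated_hours",
                                                                    len(obs) + n_removed)),
        "residual_outliers_removed": n_removed,
        "rows_in": int(len(obs)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    write_manifest(outdir / "manifest_fit.json", "fit", [str(qc_path), str(ref_path)],
                   config.content_hash(), seed, rows)
    return rows


def linear_predict(coefficients: dict, df: pd.DataFrame) -> np.ndarray:
    """Evaluate a linear model from its named coefficients.

    Term names follow the fitted formula: ``Intercept``, covariate names,
    and ``a:b`` interactions.
    """
    out = np.zeros(len(df), dtype=float)
    for name, coef in coefficients.items():
        if name == "Intercept":
            out += coef
        elif ":" in name:
            a, b = name.split(":")
            out += coef * df[a].to_numpy() * df[b].to_numpy()
        else:
            out += coef * df[name].to_numpy()
    return out


def stage_apply(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    fit_path = _require(outdir, "final_fit.json", "fit")
    qc_path = _require(outdir, "hourly_qc.csv", "qc")
    final = json.loads(fit_path.read_text())
    if not final.get("coefficients"):
        raise DependencyError(
            f"final model {final.get('model')!r} has no serialized coefficients; "
            "the apply stage supports linear and benchmark final models"
        )
    hourly = pd.read_csv(qc_path, parse_dates=["hour"])
    hourly = hourly.dropna(subset=["pa_cf1", "rh", "temperature", "pressure"]).copy()
    hourly["dew_point"] = cal.dew_point(hourly["temperature"], hourly["rh"])
    pred = linear_predict(final["coefficients"], hourly)
    calibrated, _ = qcmod.floor_low_values(pred, config.floor, config.substitute)
    out = hourly[["site_id", "hour"]].copy()
    out["pm25_cal"] = calibrated
    out.to_csv(outdir / "calibrated_network.csv", index=False)
    rows = {"rows_in": int(len(hourly)), "rows_out": int(len(out))}
    write_manifest(outdir / "manifest_apply.json", "apply", [str(fit_path), str(qc_path)],
                   config.content_hash(), seed, rows)
    return rows


def stage_trends(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    cal_path = _require(outdir, "calibrated_network.csv", "apply")
    sites_path = _require(outdir, "sites.csv", "simulate")
    calibrated = pd.read_csv(cal_path, parse_dates=["hour"])
    sites = read_site_table(sites_path)

    summary = st.seasonal_summary(calibrated, sites, config.wet_months)
    summary.to_csv(outdir / "seasonal_summary.csv", index=False)
    biweekly = st.biweekly_means(calibrated, sites, group="setting")
    biweekly.to_csv(outdir / "biweekly.csv", index=False)
    diurnal = st.diurnal_profile(calibrated, sites, group="setting")
    diurnal.to_csv(outdir / "diurnal.csv", index=False)

    # IDW surface for the first full week on a coarse grid over the network extent
    t = calibrated["hour"]
    week0 = calibrated[t < t.min() + pd.Timedelta(days=7)]
    site_means = (
        week0.groupby("site_id")["pm25_cal"].mean().rename("value").reset_index()
        .merge(sites[["site_id", "lat", "lon"]], on="site_id")
    )
    lat = np.linspace(sites["lat"].min(), sites["lat"].max(), 15)
    lon = np.linspace(sites["lon"].min(), sites["lon"].max(), 15)
    gl, gn = np.meshgrid(lat, lon)
    grid = pd.DataFrame({"lat": gl.ravel(), "lon": gn.ravel()})
    grid["value"] = st.idw_interpolate(site_means, grid, power=config.idw_power)
    grid.to_csv(outdir / "idw_grid_week1.csv", index=False)

    rows = {
        "calibrated_hours": int(len(calibrated)),
        "strata": int(len(summary)),
        "biweekly_bins": int(biweekly["bin"].nunique()),
        "idw_points": int(len(grid)),
    }
    write_manifest(outdir / "manifest_trends.json", "trends",
                   [str(cal_path), str(sites_path)], config.content_hash(), seed, rows)
    return rows


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "gravcal": stage_gravcal,
    "fit": stage_fit,
    "apply": stage_apply,
    "trends": stage_trends,
}


def run_pipeline(config: PipelineConfig, stage: str, outdir, seed: int | None = None) -> dict:
    """Run one stage (or ``"all"``) writing artifacts + manifests to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    if stage == "all":
        return {s: _STAGE_FUNCS[s](config, outdir, seed) for s in STAGES}
    if stage not in _STAGE_FUNCS:
        raise DependencyError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return {stage: _STAGE_FUNCS[stage](config, outdir, seed)}
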