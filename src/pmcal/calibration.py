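"""Calibration-model fitting, comparison and application.

The collocation dataset pairs QC'd hourly sensor readings (``pa_cf1``)
with gravimetrically corrected reference concentrations (``pm25_ref``)
and meteorological covariates.  The model zoo comprises eleven linear
specifications (main effects and single interactions of RH, temperature,
dew point and pressure), tuned random-forest and gradient-boosting
regressors, a penalized-spline GAM, an ARIMAX time-series model, and the
fixed U.S.-wide benchmark correction

    PM2.5 = 5.75 + 0.524 · PA_cf1 − 0.0862 · RH

which is never refit.  Model comparison uses a chronological whole-day
80/20 split with expanding-window cross-validation inside the training
portion, respecting the strong temporal autocorrelation of ambient PM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ContractError, FormatError
from .qc import floor_low_values
from .types import FLOOR_SUBSTITUTE, ModelMetrics

__all__ = [
    "dew_point",
    "build_collocation",
    "residual_outlier_filter",
    "chronological_split",
    "expanding_window_cv",
    "ModelSpec",
    "CalibrationFit",
    "default_model_specs",
    "fit_model",
    "predict",
    "evaluate",
    "apply_calibration",
    "impute_gaps",
    "BARKJOHN_COEF",
]

MAGNUS_A = 17.27
MAGNUS_B = 237.7  # °C

#: Published U.S.-wide correction; fixed, never refit.
BARKJOHN_COEF = {"Intercept": 5.75, "pa_cf1": 0.524, "rh": -0.0862}

COVARIATES = ("pa_cf1", "rh", "temperature", "dew_point", "pressure")

LIN_FORMULAS = {
    "lin1": "pm25_ref ~ pa_cf1",
    "lin2": "pm25_ref ~ pa_cf1 + temperature",
    "lin3": "pm25_ref ~ pa_cf1 + rh",
    "lin4": "pm25_ref ~ pa_cf1 + dew_point",
    "lin5": "pm25_ref ~ pa_cf1 + pressure",
    "lin6": "pm25_ref ~ pa_cf1 + temperature + rh + temperature:rh",
    "lin7": "pm25_ref ~ pa_cf1 + temperature + dew_point + temperature:dew_point",
    "lin8": "pm25_ref ~ pa_cf1 + temperature + pressure + temperature:pressure",
    "lin9": "pm25_ref ~ pa_cf1 + rh + dew_point + rh:dew_point",
    "lin10": "pm25_ref ~ pa_cf1 + rh + pressure + rh:pressure",
    "lin11": "pm25_ref ~ pa_cf1 + dew_point + pressure + dew_point:pressure",
}


def dew_point(temperature, rh, a: float = MAGNUS_A, b: float = MAGNUS_B):
    """Magnus-Tetens dew point (°C) from temperature (°C) and RH (%).

    γ = a·T/(b+T) + ln(RH/100); DP = b·γ/(a − γ).  DP ≤ T, with equality
    at saturation.
    """
    t = np.asarray(temperature, dtype=float)
    r = np.asarray(rh, dtype=float)
    if np.any(r <= 0):
        raise ContractError("rh must be positive for dew point")
    gamma = a * t / (b + t) + np.log(r / 100.0)
    dp = b * gamma / (a - gamma)
    if np.isscalar(temperature) and np.isscalar(rh):
        return float(dp)
    return dp


def build_collocation(hourly_sensor: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Inner-join hourly sensor and reference series into model-ready rows.

    Keeps complete cases only and computes dew point.  Join statistics are
    attached as ``.attrs["join_stats"]``.
    """
    sensor = hourly_sensor.dropna(subset=["pa_cf1"])
    merged = sensor.merge(reference[["hour", "pm25_ref"]], on="hour", how="inner")
    cols = ["hour", "pa_cf1", "rh", "temperature", "pressure", "pm25_ref"]
    merged = merged[[c for c in cols if c in merged.columns]]
    if merged.empty:
        raise ContractError("sensor and reference series have no overlapping hours")
    merged = merged.dropna().reset_index(drop=True)
    merged["dew_point"] = dew_point(merged["temperature"], merged["rh"])
    merged = merged.sort_values("hour").reset_index(drop=True)
    merged.attrs["join_stats"] = {
        "sensor_hours": int(len(sensor)),
        "reference_hours": int(len(reference)),
        "collocated_hours": int(len(merged)),
    }
    return merged


def residual_outlier_filter(
    obs: pd.DataFrame, k_sd: float = 2.0
) -> tuple[pd.DataFrame, int]:
    """Drop observations with large residuals from the full linear model.

    A single pass: fit ``pm25_ref ~ pa_cf1 + rh + temperature + dew_point
    + pressure`` by OLS on all rows, then remove rows with
    ``|residual| > k_sd × SD(residuals)``.
    """
    if len(obs) < 50:
        raise ContractError("need at least 50 observations for the residual filter")
    X = sm.add_constant(obs[list(COVARIATES)].to_numpy())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ContractError(
            "design matrix is rank-deficient; check covariates for collinearity: "
            + ", ".join(COVARIATES)
        )
    res = smf.ols(
        "pm25_ref ~ pa_cf1 + rh + temperature + dew_point + pressure", data=obs
    ).fit()
    resid = res.resid
    sd = float(np.std(resid, ddof=0))
    # a residual SD at float round-off scale means an exact fit: keep everything
    tol = 1e-10 * max(1.0, float(np.std(obs["pm25_ref"])))
    keep = np.abs(resid) <= k_sd * sd if sd > tol else np.ones(len(obs), dtype=bool)
    filtered = obs.loc[keep].reset_index(drop=True)
    return filtered, int(len(obs) - len(filtered))


def chronological_split(
    obs: pd.DataFrame, train_fraction: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time-ordered train/test split rounded down to whole 24-hour days.

    ``train = first floor(train_fraction·N/24)·24`` rows; the remainder is
    the held-out test tail.  No shuffling.
    """
    n = len(obs)
    if n < 48:
        raise ContractError("need at least 48 observations to split")
    n_train = int(np.floor(train_fraction * n / 24.0)) * 24
    return obs.iloc[:n_train].reset_index(drop=True), obs.iloc[n_train:].reset_index(drop=True)


def expanding_window_cv(
    n_train: int, initial: int = 576, horizon: int = 576, step: int = 576
) -> list[tuple[range, range]]:
    """Expanding-window time-series CV fold indices.

    Fold k trains on ``[0, initial + k·step)`` and validates on the next
    ``horizon`` hours; folds are emitted while the validation block fits
    entirely inside ``n_train``.
    """
    if n_train < initial + horizon:
        raise ContractError(
            f"n_train={n_train} too small for initial={initial} + horizon={horizon}"
        )
    folds = []
    k = 0
    while initial + k * step + horizon <= n_train:
        end_train = initial + k * step
        folds.append((range(0, end_train), range(end_train, end_train + horizon)))
        k += 1
    return folds


# ---------------------------------------------------------------------------
# model zoo


@dataclass
class ModelSpec:
    """One entry of the model zoo.

    ``kind`` ∈ {linear, rf, gbm, gam, arimax, barkjohn}.  Hyperparameters
    default to the tuned optima; set ``tune=True`` to re-tune over a
    20-point grid scored by expanding-window CV RMSE.
    """

    id: str
    kind: str
    formula: str | None = None
    hyperparams: dict = field(default_factory=dict)
    tune: bool = False

    @classmethod
    def from_id(cls, spec_id: str) -> "ModelSpec":
        sid = spec_id.lower()
        if sid in LIN_FORMULAS:
            return cls(sid, "linear", formula=LIN_FORMULAS[sid])
        if sid == "rf":
            return cls(sid, "rf", hyperparams={"ntree": 100, "mtry": 4})
        if sid == "gbm":
            return cls(sid, "gbm", hyperparams={"nrounds": 100, "eta": 0.1, "max_depth": 4})
        if sid == "gam":
            return cls(sid, "gam")
        if sid == "arimax":
            return cls(sid, "arimax", hyperparams={"order": (24, 1, 6)})
        if sid == "barkjohn":
            return cls(sid, "barkjohn")
        raise ContractError(f"unknown model spec {spec_id!r}")


@dataclass
class CalibrationFit:
    """A fitted calibration model plus training diagnostics."""

    spec: ModelSpec
    coefficients: dict | None = None      # linear/barkjohn: name -> value
    std_errors: dict | None = None
    resid_sd: float | None = None
    n_train: int = 0
    df_resid: int | None = None
    handle: object = None                 # fitted model object for non-linear kinds
    converged: bool = True
    extra: dict = field(default_factory=dict)


def default_model_specs(ids) -> list[ModelSpec]:
    return [ModelSpec.from_id(i) for i in ids]


def _check_finite(train: pd.DataFrame, cols) -> None:
    sub = train[list(cols)]
    if not np.isfinite(sub.to_numpy(dtype=float)).all():
        raise ContractError("non-finite values in training data")


def _fit_linear(spec: ModelSpec, train: pd.DataFrame) -> CalibrationFit:
    res = smf.ols(spec.formula, data=train).fit()
    return CalibrationFit(
        spec=spec,
        coefficients=dict(res.params),
        std_errors=dict(res.bse),
        resid_sd=float(np.sqrt(res.mse_resid)),
        n_train=int(res.nobs),
        df_resid=int(res.df_resid),
        handle=res,
    )


def _cv_rmse(make_model, train: pd.DataFrame, folds) -> float:
    errs = []
    X = train[list(COVARIATES)].to_numpy()
    y = train["pm25_ref"].to_numpy()
    for tr, va in folds:
        model = make_model()
        model.fit(X[list(tr)], y[list(tr)])
        pred = model.predict(X[list(va)])
        errs.append(np.sqrt(np.mean((pred - y[list(va)]) ** 2)))
    return float(np.mean(errs))


def _fit_ml(spec: ModelSpec, train: pd.DataFrame, seed: int,
            cv_params: tuple[int, int, int]) -> CalibrationFit:
    from sklearn.ensemble import RandomForestRegressor
    from xgboost import XGBRegressor

    hp = dict(spec.hyperparams)
    if spec.tune:
        if spec.kind == "rf":
            grid = [{"ntree": n, "mtry": m} for m in (1, 2, 3, 4, 5)
                    for n in (100, 300, 500, 1000)]
        else:
            grid = [{"nrounds": n, "eta": e, "max_depth": d}
                    for e in (0.05, 0.1) for d in (2, 3, 4, 6, 8) for n in (100, 300)]
        folds = expanding_window_cv(len(train), *cv_params)
        scores = []
        for cand in grid:
            maker = (lambda c=cand: _make_ml_model(spec.kind, c, seed))
            scores.append(_cv_rmse(maker, train, folds))
        hp = grid[int(np.argmin(scores))]
    model = _make_ml_model(spec.kind, hp, seed)
    model.fit(train[list(COVARIATES)].to_numpy(), train["pm25_ref"].to_numpy())
    resid = train["pm25_ref"].to_numpy() - model.predict(train[list(COVARIATES)].to_numpy())
    return CalibrationFit(
        spec=spec, handle=model, n_train=len(train),
        resid_sd=float(np.std(resid, ddof=1)), extra={"hyperparams": hp},
    )


def _make_ml_model(kind: str, hp: dict, seed: int):
    if kind == "rf":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(
            n_estimators=hp["ntree"], max_features=hp["mtry"], random_state=seed, n_jobs=1
        )
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=hp["nrounds"], learning_rate=hp["eta"], max_depth=hp["max_depth"],
        random_state=seed, n_jobs=1, verbosity=0,
    )


def _fit_gam(spec: ModelSpec, train: pd.DataFrame) -> CalibrationFit:
    from statsmodels.gam.api import BSplines, GLMGam

    smooth_vars = train[["pa_cf1", "rh"]]
    bs = BSplines(smooth_vars, df=[10, 10], degree=[3, 3])
    model = GLMGam(train["pm25_ref"], smoother=bs, alpha=[1.0, 1.0])
    res = model.fit()
    resid = train["pm25_ref"].to_numpy() - np.asarray(res.fittedvalues)
    bounds = smooth_vars.agg(["min", "max"])
    return CalibrationFit(
        spec=spec, handle=(res, bs), n_train=len(train),
        resid_sd=float(np.std(resid, ddof=1)), extra={"smooth_bounds": bounds},
    )


def _fit_arimax(spec: ModelSpec, train: pd.DataFrame, seed: int) -> CalibrationFit:
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    order = tuple(spec.hyperparams.get("order", (24, 1, 6)))
    exog = train[list(COVARIATES)].to_numpy()
    endog = train["pm25_ref"].to_numpy()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SARIMAX(endog, exog=exog, order=order,
                            enforce_stationarity=False, enforce_invertibility=False)
            res = model.fit(disp=False, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        res, converged = None, False
    if not converged:
        warnings.warn(f"ARIMAX{order} did not converge; fit flagged", stacklevel=2)
    resid_sd = float(np.std(res.resid[order[1]:], ddof=1)) if res is not None else None
    return CalibrationFit(spec=spec, handle=res, n_train=len(train),
                          resid_sd=resid_sd, converged=converged)


def fit_model(
    spec: ModelSpec,
    train: pd.DataFrame,
    seed: int = 0,
    cv_params: tuple[int, int, int] = (576, 576, 576),
) -> CalibrationFit:
    """Fit one model-zoo entry on the training partition.

    The fixed benchmark (``barkjohn``) ignores ``train`` entirely.  ARIMAX
    is fitted on a gap-free copy (callers pass imputed data); its
    convergence failures are flagged, not raised.
    """
    if spec.kind == "barkjohn":
        return CalibrationFit(spec=spec, coefficients=dict(BARKJOHN_COEF), n_train=0)
    if train is None or len(train) == 0:
        raise ContractError("empty training data")
    _check_finite(train, COVARIATES + ("pm25_ref",))
    if spec.kind == "linear":
        return _fit_linear(spec, train)
    if spec.kind in ("rf", "gbm"):
        return _fit_ml(spec, train, seed, cv_params)
    if spec.kind == "gam":
        return _fit_gam(spec, train)
    if spec.kind == "arimax":
        return _fit_arimax(spec, train, seed)
    raise ContractError(f"unknown model kind {spec.kind!r}")


def predict(fit: CalibrationFit, obs: pd.DataFrame) -> np.ndarray:
    """Pointwise predictions; no low-concentration floor is applied here."""
    kind = fit.spec.kind
    needed = {"linear": None, "barkjohn": ("pa_cf1", "rh")}.get(kind, COVARIATES)
    if kind == "linear":
        needed = [t for t in COVARIATES if t in fit.spec.formula]
    missing = [c for c in (needed or []) if c not in obs.columns]
    if missing:
        raise FormatError(f"missing covariate column(s): {missing}")
    if kind == "barkjohn":
        c = fit.coefficients
        return (c["Intercept"] + c["pa_cf1"] * obs["pa_cf1"].to_numpy()
                + c["rh"] * obs["rh"].to_numpy())
    if kind == "linear":
        return np.asarray(fit.handle.predict(obs))
    if kind in ("rf", "gbm"):
        return np.asarray(fit.handle.predict(obs[list(COVARIATES)].to_numpy()))
    if kind == "gam":
        res, bs = fit.handle
        sv = obs[["pa_cf1", "rh"]]
        bounds = fit.extra.get("smooth_bounds")
        if bounds is not None:  # splines do not extrapolate: clamp to train range
            sv = sv.clip(lower=bounds.loc["min"], upper=bounds.loc["max"], axis=1)
        return np.asarray(res.predict(exog_smooth=sv))
    if kind == "arimax":
        if fit.handle is None:
            raise ContractError("ARIMAX fit did not converge; no predictions")
        return np.asarray(
            fit.handle.forecast(steps=len(obs), exog=obs[list(COVARIATES)].to_numpy())
        )
    raise ContractError(f"unknown model kind {kind!r}")


def evaluate(pred, obs_ref) -> ModelMetrics:
    """Error and agreement metrics for predictions against the reference.

    bias/RMSE/MAE/MAPE on predicted − reference; R² as squared Pearson
    correlation; Spearman's rho; Bland-Altman mean difference and
    ±1.96 SD limits of agreement (predicted − reference).
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs_ref, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ContractError("pred and obs_ref must be equal-length with n >= 3")
    d = p - o
    bias = float(d.mean())
    rmse = float(np.sqrt(np.mean(d**2)))
    mae = float(np.abs(d).mean())
    mape = float(100.0 * np.mean(np.abs(d) / o))
    sd_d = float(np.std(d, ddof=1))
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        r2 = rho = None
    else:
        r = stats.pearsonr(p, o).statistic
        r2 = float(r**2)
        rho = float(stats.spearmanr(p, o).statistic)
    return ModelMetrics(
        rmse=rmse, bias=bias, mae=mae, mape=mape, r2_pearson=r2, spearman_rho=rho,
        ba_mean_diff=bias, ba_loa_low=bias - 1.96 * sd_d, ba_loa_high=bias + 1.96 * sd_d,
    )


def apply_calibration(
    fit: CalibrationFit,
    network_hourly: pd.DataFrame,
    floor: float = 1.0,
    substitute: float = FLOOR_SUBSTITUTE,
) -> pd.Series:
    """Predict with the selected model, then floor values under 1 µg/m³ to 1/√2."""
    pred = predict(fit, network_hourly)
    out, _ = floor_low_values(pred, floor, substitute)
    return pd.Series(out, index=network_hourly.index, name="pm25_cal")


def impute_gaps(
    df: pd.DataFrame,
    seed: int = 0,
    max_rounds: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative tree-ensemble imputation of gaps in an hourly frame.

    Each gappy column is regressed on the other columns plus hour-of-day
    and day index, cycling until the largest relative change in imputed
    values drops below ``tol`` or ``max_rounds`` rounds.  Returns the
    filled frame and a boolean mask of imputed cells.  A column with a
    ``hour`` timestamp is used for the clock features and passed through.
    """
    from sklearn.ensemble import RandomForestRegressor

    out = df.copy()
    num_cols = [c for c in out.columns if c != "hour" and np.issubdtype(out[c].dtype, np.number)]
    mask = out[num_cols].isna()
    if mask.to_numpy().all(axis=0).any():
        bad = [c for c in num_cols if mask[c].all()]
        raise ContractError(f"column(s) entirely missing: {bad}")
    if float(mask.to_numpy().mean()) >= 0.5:
        raise ContractError("gap fraction >= 50 %; refusing to impute")
    if "hour" in out.columns:
        ts = pd.to_datetime(out["hour"])
        clock = ts.dt.hour.to_numpy(dtype=float)
        day = (ts - ts.min()).dt.total_seconds().to_numpy() / 86400.0
    else:
        clock = np.arange(len(out), dtype=float) % 24
        day = np.arange(len(out), dtype=float) / 24.0

    for c in num_cols:  # initialise with column medians
        out[c] = out[c].fillna(out[c].median())
    gappy = [c for c in num_cols if mask[c].any()]
    rng_seed = seed
    for _ in range(max_rounds if gappy else 0):
        max_change = 0.0
        for c in gappy:
            others = [o for o in num_cols if o != c]
            X = np.column_stack([out[others].to_numpy(dtype=float), clock, day])
            y = out[c].to_numpy(dtype=float)
            obs_rows = ~mask[c].to_numpy()
            model = RandomForestRegressor(
                n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
            )
            model.fit(X[obs_rows], y[obs_rows])
            new_vals = model.predict(X[~obs_rows])
            old_vals = y[~obs_rows]
            scale = max(float(np.std(y[obs_rows])), 1e-9)
            max_change = max(max_change, float(np.max(np.abs(new_vals - old_vals))) / scale)
            out.loc[mask[c], c] = new_vals
            rng_seed += 1
        if max_change < tol:
            break
    return out, mask
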