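"""Canned synthetic experiments for validating the calibration estimator.

The headline check: generate collocation data directly from the final
calibration relation with Gaussian reference noise at the reported
residual scale, fit the RH model by OLS, and confirm the coefficients
and the residual SD are recovered across seeded replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal

EQ1_TRUTH = {"Intercept": 2.9271, "pa_cf1": 0.4994, "rh": -0.0675}
RESIDUAL_SD = 4.44  # µg/m³


def generate_relation_dataset(
    n_hours: int,
    seed: int,
    sigma: float = RESIDUAL_SD,
    raw_median: float = 30.0,
    raw_log_sd: float = 0.5,
) -> pd.DataFrame:
    """One synthetic collocation dataset drawn directly from the calibration relation.

    Raw sensor PM is lognormal (median ``raw_median`` µg/m³), RH uniform
    on [40, 95] %; the reference is the linear relation plus
    ``N(0, sigma)``.  Temperature and pressure are plausible nuisance
    covariates carrying no signal.
    """
    rng = np.random.default_rng(seed)
    pa = rng.lognormal(np.log(raw_median), raw_log_sd, n_hours)
    rh = rng.uniform(40.0, 95.0, n_hours)
    temperature = rng.uniform(16.0, 30.0, n_hours)
    pressure = rng.normal(1013.0, 2.0, n_hours)
    ref = (
        EQ1_TRUTH["Intercept"]
        + EQ1_TRUTH["pa_cf1"] * pa
        + EQ1_TRUTH["rh"] * rh
        + rng.normal(0.0, sigma, n_hours)
    )
    return pd.DataFrame(
        {
            "hour": pd.date_range("2022-10-27", periods=n_hours, freq="h"),
            "pa_cf1": pa,
            "rh": rh,
            "temperature": temperature,
            "pressure": pressure,
            "dew_point": cal.dew_point(temperature, rh),
            "pm25_ref": ref,
        }
    )


def model3_recovery_experiment(
    n_hours: int = 5784,
    n_replicates: int = 100,
    seed: int = 1,
    sigma: float = RESIDUAL_SD,
) -> pd.DataFrame:
    """Fit the RH calibration model on seeded replicates of the relation.

    Returns one row per replicate with the fitted coefficients, their OLS
    standard errors and the residual SD.
    """
    spec = cal.ModelSpec.from_id("lin3")
    rows = []
    for r in range(n_replicates):
        rep_seed = (seed * 100_003 + r) % (2**31)
        data = generate_relation_dataset(n_hours, rep_seed, sigma=sigma)
        fit = cal.fit_model(spec, data)
        rows.append(
            {
                "replicate": r,
                "intercept": fit.coefficients["Intercept"],
                "slope_pa": fit.coefficients["pa_cf1"],
                "coef_rh": fit.coefficients["rh"],
                "se_intercept": fit.std_errors["Intercept"],
                "se_slope_pa": fit.std_errors["pa_cf1"],
                "se_coef_rh": fit.std_errors["rh"],
                "resid_sd": fit.resid_sd,
                "df_resid": fit.df_resid,
            }
        )
    return pd.DataFrame(rows)
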