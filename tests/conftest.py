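import numpy as np
import pandas as pd
import pytest

from pmcal import calibration as cal
from pmcal.gravimetric import gravimetric_reference
from pmcal.qc import qc_hourly
from pmcal.simulate import (
    default_truth_params,
    derive_raw_sensor,
    simulate_reference,
    simulate_rh,
    simulate_true_pm,
)

EQ1 = {"Intercept": 2.9271, "pa_cf1": 0.4994, "rh": -0.0675}


def make_exact_obs(n: int = 200, seed: int = 0, sigma: float = 0.0) -> pd.DataFrame:
    """Collocation rows generated exactly from the final calibration relation.

    ``pm25_ref = 2.9271 + 0.4994·pa_cf1 − 0.0675·rh (+ noise)`` with
    plausible covariates; used for noise-free coefficient recovery and
    oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    pa = rng.lognormal(np.log(30.0), 0.5, n)
    rh = rng.uniform(40.0, 95.0, n)
    temperature = rng.uniform(16.0, 30.0, n)
    pressure = rng.normal(1013.0, 2.0, n)
    ref = EQ1["Intercept"] + EQ1["pa_cf1"] * pa + EQ1["rh"] * rh
    if sigma > 0:
        ref = ref + rng.normal(0.0, sigma, n)
    return pd.DataFrame(
        {
            "hour": pd.date_range("2022-10-27", periods=n, freq="h"),
            "pa_cf1": pa,
            "rh": rh,
            "temperature": temperature,
            "pressure": pressure,
            "dew_point": cal.dew_point(temperature, rh),
            "pm25_ref": ref,
        }
    )


@pytest.fixture(scope="session")
def collocation_chain():
    """One small simulated collocation run through qc + gravimetric stages."""
    params = default_truth_params("rural")
    n = 24 * 60
    true_pm = simulate_true_pm(n, params, 42)
    rh = simulate_rh(n, 43)
    records, fault = derive_raw_sensor(true_pm, rh, params, 44)
    hourly, acct = qc_hourly(records)
    neph, filters, cf_true = simulate_reference(true_pm, 45, ref_sigma=params.sigma)
    reference, cfs = gravimetric_reference(neph, filters)
    return {
        "params": params,
        "true_pm": true_pm,
        "rh": rh,
        "records": records,
        "hourly": hourly,
        "acct": acct,
        "neph": neph,
        "filters": filters,
        "cf_true": cf_true,
        "reference": reference,
        "cfs": cfs,
    }
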