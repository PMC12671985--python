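"""Core domain records shared across pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError

#: Substitute applied to concentrations below the 1 µg/m³ floor.
FLOOR_SUBSTITUTE = 1.0 / math.sqrt(2.0)

VALID_SETTINGS = ("urban", "rural")


@dataclass(frozen=True)
class Site:
    """A monitor location.

    Parameters
    ----------
    site_id : str
        Unique identifier for the monitor.
    lat, lon : float
        WGS84 coordinates in decimal degrees.
    setting : str
        ``"urban"`` or ``"rural"``.
    city : str, optional
        City name for urban sites (e.g. ``"Kampala"``, ``"Masaka"``).
    """

    site_id: str
    lat: float
    lon: float
    setting: str
    city: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ConfigError(f"latitude {self.lat} outside [-90, 90] for {self.site_id}")
        if not -180.0 <= self.lon <= 180.0:
            raise ConfigError(f"longitude {self.lon} outside [-180, 180] for {self.site_id}")
        if self.setting not in VALID_SETTINGS:
            raise ConfigError(
                f"setting {self.setting!r} for {self.site_id} not one of {VALID_SETTINGS}"
            )


@dataclass
class TruthParams:
    """Ground-truth parameters of the synthetic collocation world.

    The reference concentration is linear in raw sensor PM and relative
    humidity, ``ref = beta0 + beta1 * raw + beta2 * rh + N(0, sigma)``;
    the generator inverts this relation so the fitted calibration model
    estimates exactly these coefficients.

    Units: ``beta0`` µg/m³; ``beta1`` dimensionless; ``beta2`` µg/m³ per %RH;
    ``sigma`` µg/m³ (additive noise SD); amplitudes µg/m³.
    """

    beta0: float = 2.9271
    beta1: float = 0.4994
    beta2: float = -0.0675
    sigma: float = 4.44

    baseline: float = 17.4          # rural-ish mean level, µg/m³
    seasonal_amp: float = 4.7       # dry-season excess half-amplitude
    diurnal_amps: tuple[float, float] = (4.0, 6.0)  # (morning, evening) peaks
    ar1_rho: float = 0.6
    ar1_sd: float = 3.0

    chan_sigma: float = 0.02        # lognormal SD of per-channel multiplicative noise
    jitter_sigma: float = 0.05      # 2-min within-hour multiplicative jitter
    fault_rate: float = 0.0         # fraction of hours with injected A/B disagreement
    missing_rate: float = 0.0       # fraction of hours dropped entirely

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ConfigError("beta1 must be > 0")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        for name in ("fault_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ModelMetrics:
    """Error/agreement bundle for one model on one dataset.

    ``bias`` and the Bland-Altman difference are both predicted − reference.
    Correlation fields are ``None`` when the reference is constant.
    """

    rmse: float
    bias: float
    mae: float
    mape: float
    r2_pearson: float | None
    spearman_rho: float | None
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "bias": self.bias,
            "mae": self.mae,
            "mape": self.mape,
            "r2_pearson": self.r2_pearson,
            "spearman_rho": self.spearman_rho,
            "ba_mean_diff": self.ba_mean_diff,
            "ba_loa_low": self.ba_loa_low,
            "ba_loa_high": self.ba_loa_high,
        }
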