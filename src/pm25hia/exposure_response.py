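"""Concentration-response functions and attributable-fraction calculus.

Two function families are supported:

* the Global Exposure Mortality Model (GEMM) for cause-specific adult
  mortality,

      RR(z) = exp( theta * log(1 + z/alpha) * w(z) ),
      w(z)  = 1 / (1 + exp(-(z - mu)/nu)),
      z     = max(0, PM2.5 - counterfactual),

  with the counterfactual concentration defaulting to 2.4 ug/m3 (the
  lowest exposure observed in the contributing cohorts); and

* a log-linear model for hospital-admission endpoints,

      RR(c) = exp( beta * max(0, c - z0) ),

  with threshold z0 = 0 by default (no safe level assumed).

The population attributable fraction is AF = (RR - 1)/RR; the burden
engine combines it with baseline rates and population at risk.

Parameter values are never hard-coded: they are loaded from a CSV
registry (see :class:`CRFRegistry`). The packaged default registry holds
age-pooled (25+) GEMM parameter sets from the published GEMM cohort
synthesis and admission coefficients from national time-series evidence,
and is intended to be replaced by study-specific files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

#: GEMM counterfactual concentration (ug/m3): exposures at or below this
#: level carry no attributable risk.
DEFAULT_COUNTERFACTUAL = 2.4

GEMM_CAUSES = ("NCD+LRI", "stroke", "IHD", "COPD", "LC", "LRI")
MORBIDITY_ENDPOINTS = ("cardiovascular", "respiratory")

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class GEMMParams:
    """Shape parameters of one GEMM concentration-response curve.

    theta scales the log-hazard, alpha (ug/m3) controls curvature near
    the counterfactual, and (mu, nu) place and widen the logistic weight
    that attenuates the slope at low concentrations. theta_se is the
    standard error of theta used for uncertainty propagation.
    """

    theta: float
    theta_se: float
    alpha: float
    mu: float
    nu: float
    cause: str = "NCD+LRI"
    age_group: str = "all-25plus"

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ConfigurationError(f"GEMM theta must be >= 0, got {self.theta}")
        if self.theta_se < 0:
            raise ConfigurationError(f"GEMM theta_se must be >= 0, got {self.theta_se}")
        if self.alpha <= 0:
            raise ConfigurationError(f"GEMM alpha must be > 0, got {self.alpha}")
        if self.nu <= 0:
            raise ConfigurationError(f"GEMM nu must be > 0, got {self.nu}")


@dataclass(frozen=True)
class LogLinearParams:
    """Log-linear exposure-response slope for an admission endpoint.

    beta is the log relative risk per ug/m3 above the threshold z0;
    (beta_low, beta_high) are its 95% CI bounds, from which a normal
    standard error is derived as (beta_high - beta_low) / (2 * 1.96).
    """

    beta: float
    beta_low: float
    beta_high: float
    z0: float = 0.0
    endpoint: str = "cardiovascular"

    def __post_init__(self) -> None:
        if not (self.beta_low <= self.beta <= self.beta_high):
            raise ConfigurationError(
                f"log-linear CI must bracket beta: {self.beta_low} <= "
                f"{self.beta} <= {self.beta_high} violated"
            )
        if self.z0 < 0:
            raise ConfigurationError(f"threshold z0 must be >= 0, got {self.z0}")

    @property
    def beta_se(self) -> float:
        return (self.beta_high - self.beta_low) / (2.0 * 1.959963984540054)


@dataclass(frozen=True)
class RelativeRisk:
    """A relative risk evaluated at one concentration for one cause."""

    value: float
    cause: str
    concentration: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InputError(f"relative risk must be nonnegative, got {self.value}")


def counterfactual_transform(
    concentration: ArrayLike, counterfactual: float = DEFAULT_COUNTERFACTUAL
) -> ArrayLike:
    """Excess exposure above the counterfactual, z = max(0, c - c0).

    Accepts scalars or arrays; negative concentrations are rejected.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise InputError("concentration must be >= 0")
    z = np.maximum(0.0, c - counterfactual)
    return float(z) if np.isscalar(concentration) or c.ndim == 0 else z


def gemm_log_hazard(z: ArrayLike, params: GEMMParams) -> ArrayLike:
    """Hazard shape h(z) = log(1 + z/alpha) * w(z), so that
    log RR = theta * h(z).

    Exposed separately because Monte Carlo propagation rescales the same
    shape by sampled theta values.
    """
    z = np.asarray(z, dtype=float)
    weight = 1.0 / (1.0 + np.exp(-(z - params.mu) / params.nu))
    h = np.log1p(z / params.alpha) * weight
    return float(h) if h.ndim == 0 else h


def gemm_relative_risk(
    concentration: float,
    params: GEMMParams,
    counterfactual: float = DEFAULT_COUNTERFACTUAL,
) -> RelativeRisk:
    """GEMM relative risk at an ambient concentration.

    Equals exactly 1 at or below the counterfactual and increases
    monotonically above it.
    """
    z = counterfactual_transform(concentration, counterfactual)
    value = math.exp(params.theta * gemm_log_hazard(z, params))
    return RelativeRisk(value=value, cause=params.cause, concentration=float(concentration))


def loglinear_relative_risk(concentration: float, params: LogLinearParams) -> RelativeRisk:
    """Log-linear relative risk RR = exp(beta * max(0, c - z0))."""
    c = float(concentration)
    if c < 0:
        raise InputError("concentration must be >= 0")
    value = math.exp(params.beta * max(0.0, c - params.z0))
    return RelativeRisk(value=value, cause=params.endpoint, concentration=c)


def attributable_fraction(rr: Union[RelativeRisk, float]) -> float:
    """Population attributable fraction (RR - 1)/RR, in [0, 1).

    Relative risks below 1 are out of domain: scenario concentrations
    never fall below the counterfactual handling, so an RR < 1 signals a
    configuration or bookkeeping mistake upstream.
    """
    value = rr.value if isinstance(rr, RelativeRisk) else float(rr)
    if value < 1.0:
        raise InputError(f"attributable fraction undefined for RR < 1 (got {value})")
    return (value - 1.0) / value


# ---------------------------------------------------------------------------
# Parameter registry

_REGISTRY_COLUMNS = [
    "function_family",
    "cause",
    "age_group",
    "theta",
    "theta_se",
    "alpha",
    "mu",
    "nu",
    "beta",
    "beta_low",
    "beta_high",
    "z0",
]


@dataclass
class CRFRegistry:
    """Data-driven collection of concentration-response parameter sets.

    One row per (function family, cause, age group). Loaded from CSV so
    revised supplementary tables can be dropped in without code changes.
    """

    gemm: list[GEMMParams] = field(default_factory=list)
    loglinear: list[LogLinearParams] = field(default_factory=list)

    @property
    def causes(self) -> list[str]:
        return sorted({p.cause for p in self.gemm})

    @property
    def endpoints(self) -> list[str]:
        return sorted({p.endpoint for p in self.loglinear})

    def gemm_for(self, cause: str) -> list[GEMMParams]:
        rows = [p for p in self.gemm if p.cause == cause]
        if not rows:
            raise ConfigurationError(
                f"CRF registry has no GEMM entry for cause {cause!r}; "
                f"available: {self.causes}"
            )
        return rows

    def loglinear_for(self, endpoint: str) -> LogLinearParams:
        rows = [p for p in self.loglinear if p.endpoint == endpoint]
        if not rows:
            raise ConfigurationError(
                f"CRF registry has no log-linear entry for endpoint {endpoint!r}; "
                f"available: {self.endpoints}"
            )
        return rows[0]

    def require(self, causes: Iterable[str], endpoints: Iterable[str] = ()) -> None:
        """Validate coverage, listing every gap at once."""
        missing = [c for c in causes if not any(p.cause == c for p in self.gemm)]
        missing += [e for e in endpoints if not any(p.endpoint == e for p in self.loglinear)]
        if missing:
            raise ConfigurationError(f"CRF registry missing entries for: {missing}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CRFRegistry":
        reg = cls()
        for _, row in frame.iterrows():
            family = str(row["function_family"]).strip().lower()
            if family == "gemm":
                reg.gemm.append(
                    GEMMParams(
                        theta=float(row["theta"]),
                        theta_se=float(row["theta_se"]),
                        alpha=float(row["alpha"]),
                        mu=float(row["mu"]),
                        nu=float(row["nu"]),
                        cause=str(row["cause"]),
                        age_group=str(row["age_group"]),
                    )
                )
            elif family == "loglinear":
                z0 = row.get("z0", 0.0)
                reg.loglinear.append(
                    LogLinearParams(
                        beta=float(row["beta"]),
                        beta_low=float(row["beta_low"]),
                        beta_high=float(row["beta_high"]),
                        z0=0.0 if pd.isna(z0) else float(z0),
                        endpoint=str(row["cause"]),
                    )
                )
            else:
                raise ConfigurationError(f"unknown function_family {family!r}")
        return reg

    @classmethod
    def from_csv(cls, path) -> "CRFRegistry":
        frame = pd.read_csv(path, comment="#")
        missing = set(_REGISTRY_COLUMNS) - set(frame.columns)
        if missing:
            raise ConfigurationError(f"CRF registry file missing columns: {sorted(missing)}")
        return cls.from_frame(frame)

    @classmethod
    def default(cls) -> "CRFRegistry":
        """Registry shipped with the package (age-pooled defaults)."""
        with resources.as_file(
            resources.files("pm25hia").joinpath("data/crf_default.csv")
        ) as path:
            return cls.from_csv(path)
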