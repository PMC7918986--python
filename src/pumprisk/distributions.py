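"""Exposure-factor distributions: fitting and seeded sampling.

The consumer scenario needs three fitted distributions:

* benzene concentration — lognormal, parameterized as the mean/SD of the
  natural log of the concentration in **ppm** (3.24 ppb -> mu ~= -5.73);
* fill time per event — a normal truncated to [0.5, 6] minutes, whose
  location/scale are the raw sample moments of the canister-derived fill
  times (not a truncated-likelihood fit — the bounds act at sampling time);
* fill-ups per month — a zero-truncated ("positive") Poisson with lambda set
  to the raw mean of the survey counts.

The occupational scenario replaces the two time factors with plain normals
(hours/day, workdays/year), resampling the negligible-probability
nonpositive draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

PPB_PER_PPM = 1000.0

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LogNormalParams:
    """Natural-log-scale parameters of a lognormal concentration in ppm."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")


@dataclass(frozen=True)
class TruncNormParams:
    """Pre-truncation normal moments plus hard sampling bounds (minutes)."""

    mean: float
    sd: float
    lower: float = 0.5
    upper: float = 6.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be >= 0")
        if not self.lower < self.upper:
            raise DomainError("lower bound must be below upper bound")


@dataclass(frozen=True)
class PositivePoissonParams:
    """Zero-truncated Poisson rate (mean of the raw counts)."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise DomainError("lam must be > 0")

    @property
    def truncated_mean(self) -> float:
        """E[X | X >= 1] = lam / (1 - exp(-lam))."""
        return self.lam / (1.0 - np.exp(-self.lam))


@dataclass(frozen=True)
class OccupationalParams:
    """Workday exposure-time factors: hours/day and workdays/year normals."""

    hours_mean: float = 7.0
    hours_sd: float = 0.5
    days_mean: float = 260.0
    days_sd: float = 10.0

    def __post_init__(self) -> None:
        if min(self.hours_mean, self.hours_sd, self.days_mean, self.days_sd) <= 0:
            raise DomainError("occupational parameters must be positive")


@dataclass(frozen=True)
class FittedDistributions:
    """The three consumer exposure-factor distributions (CA, ET, EF)."""

    concentration: LogNormalParams
    fill_time: TruncNormParams
    fill_frequency: PositivePoissonParams

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "concentration": asdict(self.concentration),
            "fill_time": asdict(self.fill_time),
            "fill_frequency": asdict(self.fill_frequency),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDistributions":
        return cls(
            concentration=LogNormalParams(**d["concentration"]),
            fill_time=TruncNormParams(**d["fill_time"]),
            fill_frequency=PositivePoissonParams(**d["fill_frequency"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FittedDistributions":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_lognormal(concentrations_ppb: Sequence[float]) -> LogNormalParams:
    """Fit the log-ppm normal: mu = mean(ln ppm), sigma = sd(ln ppm, n-1)."""
    vals = np.asarray(concentrations_ppb, dtype=float)
    if (vals <= 0).any():
        raise DomainError("concentrations must be positive to log-transform")
    logs = np.log(vals / PPB_PER_PPM)
    sigma = float(logs.std(ddof=1)) if len(logs) > 1 else 0.0
    return LogNormalParams(mu=float(logs.mean()), sigma=sigma)


def fit_truncnorm(
    fill_times_min: Sequence[float], lower: float = 0.5, upper: float = 6.0
) -> TruncNormParams:
    """Raw sample moments of the fill times; bounds apply at sampling only."""
    vals = np.asarray(fill_times_min, dtype=float)
    if len(vals) < 2:
        raise DomainError("need at least 2 fill times")
    return TruncNormParams(
        mean=float(vals.mean()), sd=float(vals.std(ddof=1)), lower=lower, upper=upper
    )


def fit_positive_poisson(
    counts: Sequence[int], method: str = "raw_mean"
) -> PositivePoissonParams:
    """Parameterize the zero-truncated Poisson from positive integer counts.

    ``method="raw_mean"`` (default) sets lambda to the arithmetic mean of
    the counts — the convention under which a mean count of 2 yields
    Pois(2). ``method="mle"`` instead solves the zero-truncated likelihood
    equation lambda / (1 - exp(-lambda)) = mean(counts), which recovers the
    underlying rate when the counts truly are zero-truncated draws.
    """
    vals = np.asarray(counts)
    if len(vals) == 0:
        raise DomainError("no counts")
    if (vals < 1).any() or not np.issubdtype(vals.dtype, np.integer):
        raise DomainError("counts must be integers >= 1")
    xbar = float(vals.mean())
    if method == "raw_mean":
        return PositivePoissonParams(lam=xbar)
    if method == "mle":
        if xbar <= 1.0:
            # truncated mean -> 1 as lam -> 0; all-ones data has no finite MLE
            raise DomainError("MLE requires mean count > 1")
        from scipy.optimize import brentq

        lam = brentq(lambda l: l / (1.0 - np.exp(-l)) - xbar, 1e-12, xbar)
        return PositivePoissonParams(lam=float(lam))
    raise DomainError(f"unknown method: {method!r}")


def sample_lognormal(
    params: LogNormalParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n concentration draws in ppm: exp(Normal(mu, sigma))."""
    _check_n(n)
    return np.exp(rng.normal(params.mu, params.sigma, n))


def sample_truncnorm(
    params: TruncNormParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n fill-time draws in minutes, via the inverse CDF on [lower, upper].

    A zero-sd distribution degenerates to the mean clipped to the bounds.
    """
    _check_n(n)
    if params.sd == 0:
        return np.full(n, np.clip(params.mean, params.lower, params.upper))
    a = (params.lower - params.mean) / params.sd
    b = (params.upper - params.mean) / params.sd
    return stats.truncnorm.rvs(
        a, b, loc=params.mean, scale=params.sd, size=n, random_state=rng
    )


def sample_positive_poisson(
    params: PositivePoissonParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n integer draws >= 1 by inverse CDF on the zero-truncated pmf.

    Uniforms are mapped into (P(X=0), 1) so the Poisson quantile function
    never lands on zero.
    """
    _check_n(n)
    p0 = np.exp(-params.lam)
    u = p0 + (1.0 - p0) * rng.random(n)
    draws = stats.poisson.ppf(u, params.lam).astype(np.int64)
    # guard the measure-zero event u == p0 from float underflow
    return np.maximum(draws, 1)


def sample_occupational(
    params: OccupationalParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n (hours/day, days/year) draw pairs; nonpositive draws are resampled.

    At the default parameters a nonpositive draw is a >10-sigma event, so
    the resampling loop virtually never iterates; it exists to keep the
    exposure-time product strictly positive for the log-scale summaries.
    """
    _check_n(n)
    hours = rng.normal(params.hours_mean, params.hours_sd, n)
    days = rng.normal(params.days_mean, params.days_sd, n)
    for arr, mean, sd in ((hours, params.hours_mean, params.hours_sd),
                          (days, params.days_mean, params.days_sd)):
        bad = arr <= 0
        while bad.any():
            arr[bad] = rng.normal(mean, sd, bad.sum())
            bad = arr <= 0
    return hours, days


def _check_n(n: int) -> None:
    if n < 1:
        raise DomainError("n must be >= 1")
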