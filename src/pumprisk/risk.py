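"""Excess cancer-risk computation: deterministic equation and Monte Carlo.

The core relation is the standard EPA/NIOSH linear inhalation model

    excess risk = scale * UR * CA * (ET / 8760) * (ED / AT)

where ``UR`` is the inhalation unit risk (per ug/m3 for benzene), ``CA`` the
exposure concentration, ``ET`` the exposure hours per year, and ``ED/AT``
the exposure-duration to averaging-time ratio. ``scale`` expresses the
result per 1,000,000 people (general population) or per 10,000
(occupational).

Two unit conventions are supported:

* ``as_printed`` — ED/AT = 15/70 with the per-ug/m3 unit risk; and
* ``calibrated`` — an explicit ED/AT override of 0.5, which is the
  convention under which the Monte Carlo percentiles line up with the
  published consumer and occupational distributions. The printed equation
  leaves its per-day/per-year normalizers implicit, so the exact authorial
  convention is not recoverable; the override is an empirical calibration,
  recorded in every result's provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import (
    FittedDistributions,
    LogNormalParams,
    OccupationalParams,
    sample_lognormal,
    sample_occupational,
    sample_positive_poisson,
    sample_truncnorm,
)
from .errors import DataError, DomainError

BENZENE_MOLAR_MASS = 78.11  # g/mol

#: Molar volume of an ideal gas (L/mol) at the two supported reference
#: temperatures for ppm <-> ug/m3 conversion.
MOLAR_VOLUME_L = {"25C": 24.45, "0C": 22.414}

HOURS_PER_YEAR = 8760.0

PER_MILLION = 1e6
PER_TEN_THOUSAND = 1e4

#: Calibrated ED/AT override reproducing the published percentiles.
CALIBRATED_ED_AT = 0.5

_UNIT_ALIASES = {
    "ppm": "ppm",
    "ppb": "ppb",
    "ug/m3": "ug/m3",
    "ug_m3": "ug/m3",
    "µg/m³": "ug/m3",
    "ug/m^3": "ug/m3",
}


def convert_concentration(
    value: float | np.ndarray,
    from_unit: str,
    to_unit: str,
    temperature: str = "25C",
) -> float | np.ndarray:
    """Convert benzene concentrations between ppm, ppb, and ug/m3.

    1 ppm = (78.11 / molar volume) mg/m3, ~= 3194.7 ug/m3 at 25 degC.
    """
    try:
        src = _UNIT_ALIASES[from_unit]
        dst = _UNIT_ALIASES[to_unit]
    except KeyError as exc:
        raise DomainError(f"unknown concentration unit: {exc.args[0]!r}")
    if temperature not in MOLAR_VOLUME_L:
        raise DomainError(f"unknown temperature convention: {temperature!r}")
    ug_per_ppm = BENZENE_MOLAR_MASS / MOLAR_VOLUME_L[temperature] * 1000.0
    to_ppm = {"ppm": 1.0, "ppb": 1e-3, "ug/m3": 1.0 / ug_per_ppm}
    return value * to_ppm[src] / to_ppm[dst]


@dataclass(frozen=True)
class RiskParams:
    """Scalar constants of the risk equation plus the unit convention.

    ``ur_basis`` names the concentration unit the unit risk applies to;
    simulated ppm concentrations are converted to that basis before the
    multiplication. ``ed_at_override``, when set, replaces ED/AT.
    """

    unit_risk: float = 2.2e-6
    ur_basis: str = "ug/m3"
    temperature: str = "25C"
    exposure_duration_years: float = 15.0
    averaging_time_years: float = 70.0
    ed_at_override: Optional[float] = None
    scale: float = PER_MILLION

    def __post_init__(self) -> None:
        if self.unit_risk <= 0:
            raise DomainError("unit risk must be positive")
        if not 0 < self.exposure_duration_years <= self.averaging_time_years:
            raise DomainError("require 0 < ED <= AT")
        if self.scale not in (PER_MILLION, PER_TEN_THOUSAND):
            raise DomainError("scale must be per-1M (1e6) or per-10K (1e4)")

    @property
    def ed_at(self) -> float:
        if self.ed_at_override is not None:
            return self.ed_at_override
        return self.exposure_duration_years / self.averaging_time_years

    @property
    def convention(self) -> str:
        return "calibrated" if self.ed_at_override is not None else "as_printed"

    @classmethod
    def consumer(cls, mode: str = "as_printed") -> "RiskParams":
        return cls(scale=PER_MILLION, ed_at_override=_override_for(mode))

    @classmethod
    def occupational(cls, mode: str = "as_printed") -> "RiskParams":
        return cls(scale=PER_TEN_THOUSAND, ed_at_override=_override_for(mode))


def _override_for(mode: str) -> Optional[float]:
    if mode == "calibrated":
        return CALIBRATED_ED_AT
    if mode == "as_printed":
        return None
    raise DomainError(f"unknown convention mode: {mode!r}")


@dataclass
class RiskDistribution:
    """Monte Carlo excess-risk draws on a declared scale."""

    draws: np.ndarray
    scale: float
    n_iter: int
    seed: int
    provenance: dict = field(default_factory=dict)

    def rescaled(self, new_scale: float) -> "RiskDistribution":
        """Re-express the draws on another risk scale (e.g. per-10K -> per-1M)."""
        if new_scale not in (PER_MILLION, PER_TEN_THOUSAND):
            raise DomainError("scale must be per-1M (1e6) or per-10K (1e4)")
        return RiskDistribution(
            draws=self.draws * (new_scale / self.scale),
            scale=new_scale,
            n_iter=self.n_iter,
            seed=self.seed,
            provenance=dict(self.provenance, rescaled_from=self.scale),
        )


def deterministic_risk(
    params: RiskParams,
    ca_ppm: float | np.ndarray,
    et_hours_per_year: float | np.ndarray,
) -> float | np.ndarray:
    """Excess risk on ``params.scale`` for a fixed concentration and time."""
    if np.any(np.asarray(ca_ppm) < 0) or np.any(np.asarray(et_hours_per_year) < 0):
        raise DomainError("concentration and exposure time must be nonnegative")
    ca = convert_concentration(ca_ppm, "ppm", params.ur_basis, params.temperature)
    return (
        params.scale
        * params.unit_risk
        * ca
        * (et_hours_per_year / HOURS_PER_YEAR)
        * params.ed_at
    )


def simulate_consumer_risk(
    dists: FittedDistributions,
    params: RiskParams,
    n_iter: int = 100_000,
    seed: int = 0,
) -> RiskDistribution:
    """Consumer Monte Carlo: per-fill exposure scaled to a year.

    Each iteration draws a concentration (ppm), a fill time (minutes) and a
    fills-per-month count; exposure hours/year = (minutes/60) * 12 * fills.
    """
    if params.scale != PER_MILLION:
        raise DataError("consumer risk is expressed per 1,000,000")
    rng = np.random.default_rng(seed)
    ca_ppm = sample_lognormal(dists.concentration, n_iter, rng)
    minutes = sample_truncnorm(dists.fill_time, n_iter, rng)
    fills = sample_positive_poisson(dists.fill_frequency, n_iter, rng)
    hours_per_year = minutes / 60.0 * 12.0 * fills
    draws = deterministic_risk(params, ca_ppm, hours_per_year)
    return RiskDistribution(
        draws=draws,
        scale=params.scale,
        n_iter=n_iter,
        seed=seed,
        provenance={
            "scenario": "consumer",
            "params": asdict(params),
            "convention": params.convention,
            "distributions": dists.to_dict(),
        },
    )


def simulate_occupational_risk(
    occ: OccupationalParams,
    conc: LogNormalParams,
    params: RiskParams,
    n_iter: int = 100_000,
    seed: int = 0,
) -> RiskDistribution:
    """Occupational Monte Carlo: hours/year = hours/day x workdays/year."""
    if params.scale != PER_TEN_THOUSAND:
        raise DataError("occupational risk is expressed per 10,000")
    rng = np.random.default_rng(seed)
    ca_ppm = sample_lognormal(conc, n_iter, rng)
    hours, days = sample_occupational(occ, n_iter, rng)
    draws = deterministic_risk(params, ca_ppm, hours * days)
    return RiskDistribution(
        draws=draws,
        scale=params.scale,
        n_iter=n_iter,
        seed=seed,
        provenance={
            "scenario": "occupational",
            "params": asdict(params),
            "convention": params.convention,
            "occupational": asdict(occ),
            "concentration": asdict(conc),
        },
    )


def summarize(
    dist: RiskDistribution,
    percentiles: Sequence[float] = (50, 75, 95),
    ndigits: Optional[int] = None,
) -> dict[float, float]:
    """log10 percentiles of the risk draws (linear interpolation)."""
    if len(dist.draws) == 0:
        raise DomainError("empty risk distribution")
    logs = np.log10(dist.draws)
    out = {}
    for p in percentiles:
        v = float(np.percentile(logs, p))
        out[p] = round(v, ndigits) if ndigits is not None else v
    return out


def exceedance_fraction(dist: RiskDistribution, threshold: float) -> float:
    """Fraction of draws strictly above ``threshold`` (same scale as draws).

    On the per-1M scale a threshold of 1.0 is the 1:1,000,000 risk
    management level; on per-10K, 1.0 is 1:10,000.
    """
    return float(np.mean(dist.draws > threshold))


def save_draws(dist: RiskDistribution, csv_path: str | Path, meta_path: str | Path) -> None:
    """Persist draws as a single-column CSV plus a JSON metadata sidecar."""
    pd.DataFrame({"risk": dist.draws}).to_csv(csv_path, index=False)
    meta = {
        "scale": dist.scale,
        "n_iter": dist.n_iter,
        "seed": dist.seed,
        "provenance": dist.provenance,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_draws(csv_path: str | Path, meta_path: str | Path) -> RiskDistribution:
    draws = pd.read_csv(csv_path)["risk"].to_numpy()
    meta = json.loads(Path(meta_path).read_text())
    return RiskDistribution(
        draws=draws,
        scale=meta["scale"],
        n_iter=meta["n_iter"],
        seed=meta["seed"],
        provenance=meta.get("provenance", {}),
    )
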