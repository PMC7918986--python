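"""Ambient (NATA-style) census-tract risk context for pumping risk.

EPA's National Air Toxics Assessment publishes excess cancer risk from
ambient benzene per census tract (per 1,000,000). To place fueling risk in
context, each Monte Carlo iteration draws a home tract (population-weighted)
and a work tract (uniform), combines their ambient risks with 0.8/0.2
home/work weights (an approximate 40-hour work week), and takes
log10(pumping risk / ambient risk). Ratios above zero mean pumping exceeds
ambient risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, SchemaError
from .risk import PER_MILLION, PER_TEN_THOUSAND, RiskDistribution

HOME_WEIGHT = 0.8
WORK_WEIGHT = 0.2

TRACT_COLUMNS = ("tract_id", "region", "population", "ambient_risk_per_1M")


def read_tracts(path: str | Path) -> pd.DataFrame:
    """Read and validate a census-tract ambient-risk table."""
    df = pd.read_csv(path)
    for col in TRACT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if len(df) == 0:
        raise DataError("tract table is empty")
    if (df["ambient_risk_per_1M"] <= 0).any():
        raise DataError("ambient risk must be positive")
    if (df["population"] < 0).any():
        raise DataError("population must be nonnegative")
    if df["tract_id"].duplicated().any():
        warnings.warn("duplicated tract_id values; all rows kept", stacklevel=2)
    return df


def draw_ambient(
    table: pd.DataFrame,
    rng: np.random.Generator,
    n: int = 1,
    home_weight: float = HOME_WEIGHT,
    work_weight: float = WORK_WEIGHT,
) -> np.ndarray:
    """n weighted home/work ambient risk draws (per 1M).

    The home tract is sampled with probability proportional to population,
    the work tract uniformly; both from the same pooled table.
    """
    if len(table) == 0:
        raise DataError("tract table is empty")
    risks = table["ambient_risk_per_1M"].to_numpy(dtype=float)
    pops = table["population"].to_numpy(dtype=float)
    if pops.sum() <= 0:
        raise DataError("all tract populations are zero")
    home = rng.choice(risks, size=n, p=pops / pops.sum())
    work = rng.choice(risks, size=n)
    return home_weight * home + work_weight * work


@dataclass
class RatioDistribution:
    """log10(pumping / ambient) draws for one scenario."""

    draws: np.ndarray
    n_iter: int
    seed: int
    scenario: str
    provenance: dict = field(default_factory=dict)


def ratio_simulation(
    table: pd.DataFrame,
    risk: RiskDistribution,
    n_iter: int = 100_000,
    seed: int = 0,
    orientation: str = "pumping_over_ambient",
) -> RatioDistribution:
    """Monte Carlo of the pumping-vs-ambient risk ratio (log10).

    Pumping draws are bootstrap-resampled from the stored risk distribution
    (equivalent in distribution to re-simulating, and cheaper). Occupational
    per-10K draws are rescaled x100 to per-1M so both sides share the NATA
    scale.
    """
    if risk.scale == PER_TEN_THOUSAND:
        risk = risk.rescaled(PER_MILLION)
    elif risk.scale != PER_MILLION:
        raise DataError(f"unsupported risk scale: {risk.scale}")
    if orientation not in ("pumping_over_ambient", "ambient_over_pumping"):
        raise DomainError(f"unknown orientation: {orientation!r}")
    rng = np.random.default_rng(seed)
    pumping = rng.choice(risk.draws, size=n_iter, replace=True)
    ambient = draw_ambient(table, rng, n=n_iter)
    logratio = np.log10(pumping / ambient)
    if orientation == "ambient_over_pumping":
        logratio = -logratio
    return RatioDistribution(
        draws=logratio,
        n_iter=n_iter,
        seed=seed,
        scenario=str(risk.provenance.get("scenario", "unknown")),
        provenance={
            "orientation": orientation,
            "risk_provenance": risk.provenance,
            "n_tracts": int(len(table)),
        },
    )


def ratio_summary(
    rd: RatioDistribution,
    percentiles: Sequence[float] = (50, 75, 95),
    threshold: float = 0.0,
) -> dict:
    """Percentile table of the log10 ratios plus exceedance above threshold."""
    if len(rd.draws) == 0:
        raise DomainError("empty ratio distribution")
    return {
        "percentiles": {p: float(np.percentile(rd.draws, p)) for p in percentiles},
        "exceedance": float(np.mean(rd.draws > threshold)),
        "threshold": threshold,
        "scenario": rd.scenario,
    }
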