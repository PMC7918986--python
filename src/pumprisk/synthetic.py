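"""Synthetic exposure-sample and census-tract generators.

The study's raw samples are not deposited, so the generators emulate their
published statistical structure: per-compound lognormal concentrations
(benzene GM 3.24 ppb / GSD 2.72, plus toluene/ethylbenzene/xylene/TVOC),
truncated-normal fill times encoded back into canister vacuum pairs,
zero-truncated Poisson fill frequencies, and City/County ambient tract
risks. Injected QC anomalies (leaks, contamination outliers) are recorded in
a truth sidecar so filter behaviour can be verified against ground truth.

Fill-time draws are quantized to 1/64 minute before vacuum encoding. Dyadic
values survive float arithmetic and CSV round trips exactly, so
``estimate_fill_time`` recovers the drawn minutes bit-for-bit; the <1 s
quantization is negligible against the 1.56 min spread.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import PositivePoissonParams, TruncNormParams, sample_positive_poisson, sample_truncnorm
from .errors import DomainError
from .exposure import LOD_SENTINEL, VACUUM_DECAY_PER_MIN

FILL_TIME_QUANTUM = 1.0 / 64.0  # minutes


@dataclass(frozen=True)
class CompoundSpec:
    """Lognormal concentration model for one compound, in ppb."""

    gm_ppb: float
    gsd: float
    lod_ppb: float


#: Published geometric summaries; LODs are unpublished and set just below
#: the observed minima so censoring is rare by default.
DEFAULT_COMPOUNDS: dict[str, CompoundSpec] = {
    "benzene": CompoundSpec(3.24, 2.72, 0.4),
    "toluene": CompoundSpec(9.50, 3.50, 1.0),
    "ethylbenzene": CompoundSpec(1.99, 2.80, 0.25),
    "xylene": CompoundSpec(7.32, 3.01, 1.0),
    "tvoc": CompoundSpec(487.0, 3.06, 50.0),
}


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort and tract table."""

    n_consumers: int = 32
    compounds: dict[str, CompoundSpec] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUNDS)
    )
    fill_mean: float = 3.08
    fill_sd: float = 1.56
    fill_lower: float = 0.5
    fill_upper: float = 6.0
    fills_lambda: float = 2.0
    initial_vacuum: float = 30.0
    temp_mean_c: float = 19.7
    temp_sd_c: float = 9.0
    # QC anomaly injection
    n_leaks: int = 0
    n_outliers: int = 0
    outlier_factor: float = 1000.0
    # census tracts
    n_city: int = 100
    n_county: int = 100
    city_mean: float = 4.4
    city_sd: float = 0.31
    county_mean: float = 3.76
    county_sd: float = 0.39
    population_model: str = "equal"  # "equal" | "lognormal"
    base_population: int = 4000

    def validate(self) -> None:
        if self.n_consumers < 2:
            raise DomainError("need at least 2 consumers")
        scales = [self.fill_mean, self.fills_lambda, self.city_mean, self.county_mean]
        scales += [s.gm_ppb for s in self.compounds.values()]
        if any(s <= 0 for s in scales):
            raise DomainError("all scale parameters must be positive")
        if min(self.fill_sd, self.city_sd, self.county_sd) < 0:
            raise DomainError("standard deviations must be >= 0")
        if any(s.gsd < 1 for s in self.compounds.values()):
            raise DomainError("GSD must be >= 1")
        if self.n_leaks + self.n_outliers > self.n_consumers:
            raise DomainError("more anomalies than consumers")
        if self.population_model not in ("equal", "lognormal"):
            raise DomainError(f"unknown population model: {self.population_model!r}")


def generate_samples(
    cfg: GeneratorConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate an exposure-sample table plus a ground-truth sidecar.

    Returns a DataFrame in the exact CSV schema ``exposure.read_samples``
    consumes, and a truth dict with injected anomaly ids, drawn fill
    minutes, and generator parameters.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n_consumers
    ids = [f"C{i + 1:03d}" for i in range(n)]

    conc = {
        name: np.exp(rng.normal(np.log(spec.gm_ppb), np.log(spec.gsd), n))
        for name, spec in cfg.compounds.items()
    }

    minutes = sample_truncnorm(
        TruncNormParams(cfg.fill_mean, cfg.fill_sd, cfg.fill_lower, cfg.fill_upper),
        n,
        rng,
    )
    minutes = np.round(minutes / FILL_TIME_QUANTUM) * FILL_TIME_QUANTUM
    fills = sample_positive_poisson(PositivePoissonParams(cfg.fills_lambda), n, rng)
    temps = rng.normal(cfg.temp_mean_c, cfg.temp_sd_c, n)

    anomaly_ids = rng.choice(n, size=cfg.n_leaks + cfg.n_outliers, replace=False)
    leak_idx = anomaly_ids[: cfg.n_leaks]
    outlier_idx = anomaly_ids[cfg.n_leaks :]
    leaked = np.zeros(n, dtype=int)
    leaked[leak_idx] = 1
    for name in ("benzene", "toluene", "ethylbenzene", "xylene"):
        if name in conc:
            conc[name][outlier_idx] *= cfg.outlier_factor

    rows: dict[str, list] = {"consumer_id": ids}
    for name, spec in cfg.compounds.items():
        cells = [
            LOD_SENTINEL if v < spec.lod_ppb else repr(float(v)) for v in conc[name]
        ]
        rows[f"{name}_ppb"] = cells
        rows[f"lod_{name}_ppb"] = [spec.lod_ppb] * n
    rows["initial_vacuum_mmHg"] = [cfg.initial_vacuum] * n
    rows["final_vacuum_mmHg"] = list(cfg.initial_vacuum - VACUUM_DECAY_PER_MIN * minutes)
    rows["fills_per_month"] = list(fills)
    rows["temperature_c"] = list(np.round(temps, 1))
    rows["leaked"] = list(leaked)
    df = pd.DataFrame(rows)

    truth = {
        "seed": seed,
        "leak_ids": [ids[i] for i in sorted(leak_idx)],
        "outlier_ids": [ids[i] for i in sorted(outlier_idx)],
        "fill_minutes": {ids[i]: float(minutes[i]) for i in range(n)},
        "fills_per_month": {ids[i]: int(fills[i]) for i in range(n)},
        "config": _config_dict(cfg),
    }
    return df, truth


def generate_tracts(cfg: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Generate a pooled City/County census-tract ambient-risk table.

    Ambient risks are normal per region, resampled while <= 0 (the published
    means are >9 sd from zero, so truncation is virtually inactive).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    records = []
    for region, n, mean, sd, prefix in (
        ("city", cfg.n_city, cfg.city_mean, cfg.city_sd, "24510"),
        ("county", cfg.n_county, cfg.county_mean, cfg.county_sd, "24005"),
    ):
        risks = rng.normal(mean, sd, n)
        bad = risks <= 0
        while bad.any():
            risks[bad] = rng.normal(mean, sd, bad.sum())
            bad = risks <= 0
        if cfg.population_model == "equal":
            pops = np.full(n, cfg.base_population)
        else:
            pops = np.round(
                rng.lognormal(np.log(cfg.base_population), 0.5, n)
            ).astype(int)
        for i in range(n):
            records.append(
                {
                    "tract_id": f"{prefix}{i + 1:06d}",
                    "region": region,
                    "population": int(pops[i]),
                    "ambient_risk_per_1M": float(risks[i]),
                }
            )
    return pd.DataFrame.from_records(records)


def write_dataset(
    cfg: GeneratorConfig, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Write samples CSV, tract CSV and truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sample_seed, tract_seed = (int(s) for s in ss.generate_state(2) % 2**31)
    samples, truth = generate_samples(cfg, seed=sample_seed)
    tracts = generate_tracts(cfg, seed=tract_seed)
    paths = {
        "samples": out / "samples.csv",
        "tracts": out / "tracts.csv",
        "truth": out / "truth.json",
    }
    samples.to_csv(paths["samples"], index=False)
    tracts.to_csv(paths["tracts"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["compounds"] = {k: asdict(v) for k, v in cfg.compounds.items()}
    return d
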