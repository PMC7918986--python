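"""Personal exposure samples: reading, QC, and descriptive summaries.

Each record is one consumer fueling event sampled with an evacuated whole-air
canister: BTEX/TVOC concentrations in ppb (possibly censored at the limit of
detection), the canister vacuum before and after use, and the consumer's
self-reported fill-ups per month.

The canister draws air at a constant rate, so its vacuum decays linearly
while open; the fill time in minutes is recovered as
``(initial_vacuum - final_vacuum) / 5`` with the default 5 vacuum-units/min
decay rate and a six-minute operational ceiling.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, SchemaError

#: Compounds carried by every sample. Only benzene enters risk math; the
#: others (IARC group 2B/3, no inhalation unit risk) are summarized only.
COMPOUNDS = ("benzene", "toluene", "ethylbenzene", "xylene", "tvoc")

#: Sentinel used in CSV cells for measurements below the limit of detection.
LOD_SENTINEL = "<LOD"

#: Canister vacuum decay per minute of active sampling (vacuum units/min).
VACUUM_DECAY_PER_MIN = 5.0

#: Operational sampling ceiling of the flow-regulated canister, minutes.
MAX_FILL_MINUTES = 6.0

#: Default CSV column names, keyed by logical field.
DEFAULT_SCHEMA: dict[str, str] = {
    "consumer_id": "consumer_id",
    **{c: f"{c}_ppb" for c in COMPOUNDS},
    **{f"lod_{c}": f"lod_{c}_ppb" for c in COMPOUNDS},
    "initial_vacuum": "initial_vacuum_mmHg",
    "final_vacuum": "final_vacuum_mmHg",
    "fills_per_month": "fills_per_month",
    "temperature_c": "temperature_c",
    "leaked": "leaked",
}

#: Schema columns that may be absent from an input file.
OPTIONAL_FIELDS = ("temperature_c", "leaked")


@dataclass(frozen=True)
class Measurement:
    """One compound concentration in ppb, possibly censored at its LOD."""

    value: Optional[float]
    censored: bool = False
    lod: Optional[float] = None

    def resolved(self) -> float:
        if self.value is None:
            raise DataError("censored measurement has not been substituted")
        return self.value


@dataclass(frozen=True)
class ExposureSample:
    """A single consumer fueling event."""

    consumer_id: str
    measurements: Mapping[str, Measurement]
    initial_vacuum: float
    final_vacuum: float
    fills_per_month: int
    temperature_c: Optional[float] = None
    leaked: bool = False

    def __post_init__(self) -> None:
        if self.final_vacuum < 0 or self.initial_vacuum < self.final_vacuum:
            raise DataError(
                f"sample {self.consumer_id}: vacuum must satisfy "
                f"initial >= final >= 0, got "
                f"({self.initial_vacuum}, {self.final_vacuum})"
            )
        if self.fills_per_month < 1:
            raise DataError(
                f"sample {self.consumer_id}: fills_per_month must be >= 1"
            )

    def concentration(self, compound: str) -> float:
        """Resolved concentration in ppb; raises if still censored."""
        return self.measurements[compound].resolved()


class QCReason(str, Enum):
    LEAK = "LEAK"
    CONTAMINATION_OUTLIER = "CONTAMINATION_OUTLIER"
    UNUSED = "UNUSED"


@dataclass(frozen=True)
class QCConfig:
    """Quality-control rules.

    ``outlier_factor`` is the multiplicative threshold above the per-compound
    geometric mean beyond which a sample is flagged as contaminated
    (default 100x, i.e. two orders of magnitude).
    """

    outlier_factor: float = 100.0
    outlier_compounds: Sequence[str] = ("benzene", "toluene", "ethylbenzene", "xylene")


@dataclass
class QCResult:
    kept: list[ExposureSample]
    excluded: list[tuple[ExposureSample, QCReason]]


@dataclass(frozen=True)
class GeoStats:
    """Geometric summary of a lognormal-ish concentration sample."""

    geometric_mean: float
    geometric_sd: float
    min: float
    max: float
    n: int


def read_samples(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[ExposureSample]:
    """Read exposure samples from CSV.

    Censored cells are encoded as ``"<LOD"``; the per-compound LOD column
    supplies the detection limit. Censored values are left unresolved (the
    flag is set); call :func:`substitute_lod` before analysis.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical, col in schema.items():
        if logical in OPTIONAL_FIELDS:
            continue
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")

    samples = []
    for idx, row in df.iterrows():
        measurements = {}
        for compound in COMPOUNDS:
            raw = row[schema[compound]].strip()
            lod_raw = row[schema[f"lod_{compound}"]].strip()
            lod = _parse_float(lod_raw, idx, schema[f"lod_{compound}"]) if lod_raw else None
            if raw == LOD_SENTINEL:
                measurements[compound] = Measurement(None, censored=True, lod=lod)
            else:
                measurements[compound] = Measurement(
                    _parse_float(raw, idx, schema[compound]), censored=False, lod=lod
                )
        temp_col = schema["temperature_c"]
        temp = None
        if temp_col in df.columns and row[temp_col].strip():
            temp = _parse_float(row[temp_col], idx, temp_col)
        leak_col = schema["leaked"]
        leaked = False
        if leak_col in df.columns and row[leak_col].strip():
            leaked = bool(int(row[leak_col]))
        samples.append(
            ExposureSample(
                consumer_id=str(row[schema["consumer_id"]]),
                measurements=measurements,
                initial_vacuum=_parse_float(
                    row[schema["initial_vacuum"]], idx, schema["initial_vacuum"]
                ),
                final_vacuum=_parse_float(
                    row[schema["final_vacuum"]], idx, schema["final_vacuum"]
                ),
                fills_per_month=int(
                    _parse_float(
                        row[schema["fills_per_month"]], idx, schema["fills_per_month"]
                    )
                ),
                temperature_c=temp,
                leaked=leaked,
            )
        )
    return samples


def _parse_float(raw: str, row_idx, col: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise DataError(f"row {row_idx}: non-numeric value {raw!r} in column {col!r}")


def substitute_lod(sample: ExposureSample) -> ExposureSample:
    """Replace censored concentrations by LOD/sqrt(2).

    The standard substitution for non-detects from a roughly lognormal
    population. Idempotent: the censored flag is retained for provenance and
    re-substitution reproduces the same value.
    """
    new = {}
    for compound, m in sample.measurements.items():
        if not m.censored:
            new[compound] = m
            continue
        if m.lod is None or m.lod <= 0:
            raise DataError(
                f"sample {sample.consumer_id}: censored {compound} without a "
                f"positive LOD"
            )
        new[compound] = Measurement(m.lod / math.sqrt(2.0), censored=True, lod=m.lod)
    return replace(sample, measurements=new)


def estimate_fill_time(
    initial_vacuum: float,
    final_vacuum: float,
    decay_per_min: float = VACUUM_DECAY_PER_MIN,
) -> float:
    """Fill time in minutes from the canister vacuum drop.

    Zero means the canister was never opened.
    """
    if final_vacuum > initial_vacuum:
        raise DataError(
            f"vacuum cannot increase during sampling: "
            f"({initial_vacuum}, {final_vacuum})"
        )
    return (initial_vacuum - final_vacuum) / decay_per_min


def qc_filter(
    samples: Sequence[ExposureSample], rules: QCConfig | None = None
) -> QCResult:
    """Partition samples into kept and excluded with reason codes.

    Exclusion rules, applied in order per sample:

    * ``LEAK`` — the canister is marked as having leaked in transport.
    * ``UNUSED`` — zero vacuum change (the canister was never opened).
    * ``CONTAMINATION_OUTLIER`` — any BTEX concentration more than
      ``rules.outlier_factor`` times that compound's geometric mean across
      the non-leaked, used samples.
    """
    rules = rules or QCConfig()
    kept: list[ExposureSample] = []
    excluded: list[tuple[ExposureSample, QCReason]] = []

    candidates = []
    for s in samples:
        if s.leaked:
            excluded.append((s, QCReason.LEAK))
        elif s.initial_vacuum == s.final_vacuum:
            excluded.append((s, QCReason.UNUSED))
        else:
            candidates.append(s)

    # GM computed over all candidates; a single extreme outlier shifts the
    # log-mean by only log(factor)/n so the threshold stays meaningful.
    gm = {}
    for compound in rules.outlier_compounds:
        vals = np.array([s.concentration(compound) for s in candidates])
        if len(vals) and (vals > 0).all():
            gm[compound] = float(np.exp(np.mean(np.log(vals))))

    for s in candidates:
        is_outlier = any(
            compound in gm
            and s.concentration(compound) > rules.outlier_factor * gm[compound]
            for compound in rules.outlier_compounds
        )
        if is_outlier:
            excluded.append((s, QCReason.CONTAMINATION_OUTLIER))
        else:
            kept.append(s)
    return QCResult(kept=kept, excluded=excluded)


def write_qc_report(result: QCResult, path: str | Path) -> None:
    """Write the exclusion table (consumer_id, reason) as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["consumer_id", "reason"])
        for sample, reason in result.excluded:
            writer.writerow([sample.consumer_id, reason.value])


def descriptive_stats(
    samples: Sequence[ExposureSample], compound: str
) -> GeoStats:
    """Geometric mean/SD (natural-log, n-1 denominator) plus range."""
    if len(samples) < 2:
        raise DomainError("descriptive_stats requires at least 2 samples")
    vals = np.array([s.concentration(compound) for s in samples], dtype=float)
    if (vals <= 0).any():
        raise DomainError(f"nonpositive {compound} concentration")
    logs = np.log(vals)
    return GeoStats(
        geometric_mean=float(np.exp(logs.mean())),
        geometric_sd=float(np.exp(logs.std(ddof=1))),
        min=float(vals.min()),
        max=float(vals.max()),
        n=len(vals),
    )


def compare_to_limits(
    samples: Sequence[ExposureSample],
    limits: Mapping[str, float] | None = None,
    compound: str = "benzene",
) -> dict[str, int]:
    """Count samples strictly below each exposure limit (ppb).

    Defaults are the benzene NIOSH REL (100 ppb) and OSHA PEL (1000 ppb),
    both 8-h TWAs; these short task samples are compared for context only.
    """
    limits = dict(limits) if limits is not None else {"REL": 100.0, "PEL": 1000.0}
    vals = [s.concentration(compound) for s in samples]
    return {name: sum(v < limit for v in vals) for name, limit in limits.items()}
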