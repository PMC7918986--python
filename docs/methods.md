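# Methods

## Scope and model

The package assesses incremental lifetime cancer risk from inhaled benzene
during gasoline-station fueling, for two populations: consumers (short,
infrequent fill-ups) and station attendants (full workdays near the pumps).
Risk is linear in exposure per the inhalation unit-risk model

    Risk = scale · UR · CA · (ET / 8760) · (ED / AT)

where UR = 2.2 × 10⁻⁶ per µg/m³ (the most conservative benzene inhalation
unit risk), CA is the benzene air concentration, ET the exposure hours per
year, ED the exposure duration (15 years, reflecting the 10–20-year latency
window for benzene-induced AML), and AT a 70-year lifetime. There is no
dose–response modeling beyond this linear term, no uncertainty on UR
itself, and no co-exposure (PM2.5, smoking) or dermal pathway. Toluene,
ethylbenzene and xylene are carried through QC and descriptive summaries
but never enter risk math: they lack inhalation unit risks (or, for
ethylbenzene, would require exposures orders of magnitude higher).

## Exposure factors

Consumer scenario (all fitted from the QC'd samples):

| factor | distribution | default parameters | units |
|---|---|---|---|
| CA | lognormal | exp(N(−5.73, 0.98)) | ppm |
| fill time | truncated normal | Ntrunc(3.08, 1.56, min 0.5, max 6) | min |
| fill-ups/month | zero-truncated Poisson | λ = 2 | count |

- **CA** is parameterized as the mean and n−1 standard deviation of the
  natural log of the concentration in ppm (3.24 ppb ↦ ln 0.00324 ≈ −5.73).
- **Fill times** come from canister vacuum decay: the flow-regulated
  canister loses 5 vacuum units per minute while open, so minutes =
  (initial − final)/5, with a 6-minute operational ceiling and 0 meaning
  the canister was never used. The stated decay constant is read as
  5 mmHg/min (the vacuum columns are in mmHg); only the ratio drop/rate
  matters, so vacuum units are otherwise treated as opaque. The
  truncated-normal location/scale are the **raw sample moments** of the
  estimated fill times, not a truncated-likelihood fit; the 0.5/6 bounds
  act only at sampling time (inverse-CDF sampling via scipy.stats.truncnorm).
- **Fill frequency** uses the convention λ = arithmetic mean of the survey
  counts. Because the counts are strictly positive, that mean estimates the
  *truncated* mean, so refitting draws from a zero-truncated Pois(λ) does
  not return λ (a ZTP(2) has mean 2/(1−e⁻²) ≈ 2.31). A zero-truncated MLE
  (`fit_positive_poisson(..., method="mle")`, solving λ/(1−e⁻λ) = x̄) is
  provided for genuine rate recovery; the raw-mean rule stays the default.
  Sampling is by inverse CDF on uniforms mapped into (P(X=0), 1), so a draw
  of zero is impossible.

Occupational scenario: the consumer concentration distribution is reused
with N(7, 0.5) work hours/day × N(260, 10) workdays/year (nonpositive
draws — a >10 σ event — are resampled to keep the log-scale summaries
defined). Results are expressed per 10,000 and rescaled ×100 to per
1,000,000 for ambient comparison.

## Unit convention and calibration

The printed risk equations omit per-day/per-year normalizers, so the exact
convention behind the published percentiles is not recoverable from the
text. The package exposes a convention catalog on `RiskParams`:

- UR basis: per-µg/m³ (default; ppm→µg/m³ via 78.11/24.45 ≈ 3194.7 µg/m³
  per ppm at 25 °C, with a 0 °C option), per-ppb, or per-ppm;
- ED/AT: 15/70 (`as_printed`, the default) or an explicit override
  (`calibrated`, which sets ED/AT = 0.5).

Under `as_printed` the simulated medians sit ≈0.37 log₁₀ below the
published ones; under `calibrated` all eight published percentiles
(consumer −2.8/−2.5/−2.0 per 1M; occupational −1.6/−1.3/−0.9 per 10K) are
jointly reproduced within ±0.05 log₁₀ at 10⁵ iterations. The override is an
empirical calibration finding, not a claim about authorial intent, and the
convention used is stamped into every result's provenance.

## QC and censoring

- Non-detects are substituted as LOD/√2 (idempotent; the censored flag is
  retained for provenance).
- Exclusion rules: `LEAK` (canister marked leaked in transport), `UNUSED`
  (zero vacuum change), `CONTAMINATION_OUTLIER` (any BTEX concentration
  above a configurable multiple — default 100×, i.e. two orders of
  magnitude — of that compound's geometric mean across the used,
  non-leaked samples). The GM is computed including the suspect sample;
  a single 1000× outlier in ~30 samples shifts the log-mean by only
  log(1000)/30, so the rule remains stable.
- Limit comparisons (NIOSH REL 100 ppb, OSHA PEL 1000 ppb benzene) use
  strict `<`, matching "below".

## Ambient contextualization

Census-tract ambient excess risk (per 1,000,000) is compared with pumping
risk via a two-tract Monte Carlo: a home tract drawn with probability
proportional to population, a work tract drawn uniformly, combined as
0.8·home + 0.2·work (≈40-hour work week out of 168). Pumping draws are
bootstrap-resampled from the stored risk distribution — equivalent in
distribution to re-simulating and much cheaper. The ratio is reported as
log₁₀(pumping/ambient): the published percentiles and figure orientation
(e.g. consumer median −3.44 ≈ −2.8 − log₁₀(ambient ≈ 4.4)) are consistent
only with this orientation, although the prose describes the reciprocal;
an `ambient_over_pumping` flag flips it.

## Synthetic data

The generator emulates the study conditions: 32 consumers by default
(34 with two injected anomalies when exercising QC); per-compound lognormal
concentrations at the published GM/GSD (benzene 3.24 ppb / 2.72, toluene
9.50/3.50, ethylbenzene 1.99/2.80, xylene 7.32/3.01, TVOC 487/3.06);
truncated-normal fill times encoded back into (30.00, 30 − 5·min) vacuum
pairs; zero-truncated Pois(2) fill counts; tract risks N(4.4, 0.31) per 1M
(City) and N(3.76, 0.39) per 1M (County), truncated positive.

Choices where the source data are unpublished:

- **LODs** are set just below the published minima (benzene 0.4 ppb, etc.)
  so censoring is rare unless configured.
- **Tract table composition**: 100 City + 100 County tracts with equal
  populations. Baltimore City and County have nearly equal tract counts in
  reality, and this balanced pool gives a mean weighted ambient draw of
  ≈4.05 per 1M, which simultaneously reproduces the published consumer
  ratio median (−3.44), occupational ratio median (−0.24) and occupational
  ratio exceedance (≈29%). A population-skew knob (`population_model:
  lognormal`) exists because real tract populations are not uniform.
- **Fill-time quantization**: drawn minutes are rounded to 1/64 min (<1 s)
  before vacuum encoding. Dyadic values are exact in binary floating point
  and survive CSV round trips, so `estimate_fill_time` recovers the drawn
  minutes bit-for-bit; the quantization is negligible against the 1.56 min
  spread.

What passing tests on synthetic data do **not** show: the generator draws
factors independently (no correlation between fill time, frequency and
concentration), has no seasonal or station covariates, no temperature
effect, and lognormality is exact by construction — real exposure data
would stress all of these.

## Numerical choices

- Percentiles: linear interpolation between order statistics on log₁₀
  draws; exceedance fractions use strict `>`.
- Monte Carlo size: 100,000 iterations (seconds on one CPU); the acceptance
  script and acceptance tests use this size, module tests use smaller n.
- Reproducibility: every simulation takes an explicit seed; the CLI splits
  one root seed into per-stage child seeds via `SeedSequence`, so identical
  config + seed gives identical reports. Reports embed a config fingerprint
  (SHA-256 prefix) for audit.
- Degenerate inputs: zero-σ distributions collapse exactly to the
  deterministic equation; a zero-sd truncated normal returns the mean
  clipped to its bounds; all-ones count data has no finite ZTP MLE and is
  rejected for that method.

## Known limitations

- The ED/AT = 0.5 calibration is a reproduction device; risk estimates for
  new data should use the printed 15/70 unless the user has reason to do
  otherwise.
- The published consumer 95th−50th spread (0.8) is a difference of two
  values each rounded to 0.1; the exact-model spread under the published
  parameters is ≈0.86.
- Occupational exceedance of the 1:10,000 level is a ~7-in-100,000 event,
  so its Monte Carlo estimate at n = 10⁵ carries a few-thousandths-of-a-
  percent sampling noise.
- No spatial modeling of stations versus roadways; the tract-table schema
  accepts real NATA extracts when available.
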