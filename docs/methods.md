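# Methods

`fermfuse` re-creates, as a library plus CLI, the computational core of a
fermentation data-fusion platform: it takes the three stream classes a
bioprocess lab produces — per-minute bioreactor sensors (*online*),
~20-minute off-gas mass-spectrometry compositions (*at-line*), and 2–4-hour
manual assays (*offline*) — and turns them into one rectangular, per-minute
record per batch, from which physiological parameters, fault verdicts,
multi-batch comparisons and soft-sensor predictions are computed.

## Stream model and fusion

Each batch is a directory of delimited tables (`online.csv`, `atline.csv`,
`offline.csv`) plus `meta.yaml`.  Time is elapsed hours since inoculation;
wall-clock timestamps are converted at load using the metadata `start_time`
(we require it explicitly rather than inferring it from file contents).
Missing values are explicit (`NA` or empty cell) so every filling step is
auditable.

Fusion targets the online grid, in three steps:

1. **Section averaging.** An off-gas spectrometer serves channels in
   measurement cycles (default 20 min); readings within one cycle are
   replaced by their mean.  The averaged value is placed at the *centroid*
   of the cycle's reading times — not the geometric cycle midpoint — so a
   single reading keeps its own timestamp and affine signals survive
   averaging exactly for any within-cycle reading layout.  Cycle boundary
   assignment carries a 1e-6-cycle tolerance so readings that land exactly
   on a boundary (common with regular instrument clocks stored as decimal
   hours) are not merged into the preceding cycle.
2. **Alignment.** "Lagrange linear" interpolation is read as degree-1
   Lagrange between bracketing observations, i.e. piecewise-linear;
   higher-degree Lagrange polynomials oscillate on irregular grids and are
   deliberately not offered.  Nearest-time alignment is available per
   variable; equidistant ties resolve to the *earlier* observation so no
   future data leaks into a grid point.
3. **Offline anchoring.** Manual-sample timestamps are first snapped to the
   nearest grid time, then interpolated between anchors.  Beyond the
   observed span of an at-line/offline series the default is hold-nearest,
   recorded in the column provenance; an error mode exists for strict runs.

Per-series cleaning before fusion: a moving-median filter (default window 5,
online streams only — robust to the single-point spikes sensors produce),
three gap fills (adjacent-neighbour mean, linear-in-time interpolation, zero),
and z-score/min-max normalization with stored statistics so analytics can
always invert back to engineering units.  Mean filling uses the two values
flanking a gap, not the series mean (a global-mean variant is a flag).

## Register codec

Instruments transmitting over Modbus-style registers scale a measurement
linearly from its detection range `[scale_lo, scale_hi]` onto integer counts
`[0, full_scale]`.  Encoding rounds half-up (deterministic, standard for
register encoding); the round-trip error is bounded by one quantization step
`(scale_hi − scale_lo)/full_scale`.  Out-of-range values raise instead of
clamping so saturation reaches the fault rules rather than being hidden.

## Off-gas balances and rate algebra

With inlet air flow `F_air_in` (ml/min), broth mass `m` (kg) and percent
mole fractions, nitrogen is treated as inert and the outlet flow corrected
by the N₂ ratio:

    CER = F/m · (y_N2_in·y_CO2_out/y_N2_out − y_CO2_in)/100 · 60/22.4
    OUR = F/m · (y_O2_in − y_N2_in·y_O2_out/y_N2_out)/100 · 60/22.4
    RQ  = CER/OUR

in mmol·kg⁻¹·h⁻¹.  The /100 percent-to-fraction conversion is required for
the units to close (22.4 L/mol at STP; ml·min⁻¹ → mmol·h⁻¹ needs fractional
composition); a `percent=False` flag accepts fractions of one, and the
computation is invariant between the two provided the flag matches the
data.  The molar volume is fixed at 22.4 L/mol and not temperature-corrected.
RQ is a missing marker (NaN), not an exception, where OUR = 0.

Component balances `dM/dt = F_in·c_in − F_out·c_out + R + T` yield the
process rate `R`; `r = R/m_avg` and `q = R/(OD·m)_avg` scale it to reactor
and cell level, and yields `Y_i/j = R_i/R_j` are checked to agree across all
three levels to 1e-9 whenever the averaged denominators are shared.  `dM/dt`
uses central differences (one-sided, first order at the ends); the transfer
term `T` defaults to zero unless a transfer series is supplied.

## Fault rules

Two rules over a rolling, centred, time-based window (default 1 h),
instantiated for the CO₂-in-air reference channel of the off-gas
spectrometer (percent units):

* rolling mean outside [0.02, 0.05] → anomalous;
* rolling coefficient of variation (sample sd / mean) above 0.1 → anomalous.

Sample (n−1) standard deviation is used for the CV.  Flagged points merge
into maximal intervals; intervals separated by less than one window are
joined, sub-window excursions are tagged `transient`, and zero-mean windows
(CV undefined) are reported `indeterminate`, never anomalous.  The CV rule
is invariant to positive rescaling; the mean band is not.  An episode mode
(one statistic for the whole series, matching discrete calibration
episodes) is available as a flag; rolling is the default.

## Multi-batch analytics

The Spearman screen rank-correlates targets (titer, biomass, …) with
process factors over paired observations, average ranks for ties, with
two-sided p-values from the large-sample t approximation — exact
permutation enumeration below n = 9, where full enumeration (≤ 40,320
permutations) is affordable; the implementation's rho is cross-checked in
the tests against an independent rank-then-Pearson oracle.  No
multiple-testing correction is applied by default; Benjamini–Hochberg is a
flag.

Both PCA procedures z-score columns first (variables span incommensurate
units) and fix component signs so each loading vector's largest-magnitude
element is positive:

* **flat** — one row per batch, (variable × grid time) columns; batches
  become (PC1, PC2) points and outlier batches (contamination, stunted
  growth) separate from the stable cluster;
* **time** — (batch, time) rows over process variables; PC1/PC2 become
  per-batch trajectories, smoothed *after* reduction with a Savitzky–Golay
  filter (window 11, order 3 by default), with per-variable loadings for
  attributing excursions.

Feed the PCA informative process variables only: a constant-valued channel
(set-point temperature, fixed air flow) is pure sensor noise after
z-scoring and will otherwise claim an entire principal component of its
own.  The shared grid is the intersection of batch spans at the online
cadence, capped at 2,000 points for the flat method to bound column count.

## Soft sensing

One sample per fused grid point: the online/derived feature vector
(stirring speed, DO, feed rate, pH, temperature, broth weight, airflow,
acid/inspection pump speeds, CER, OUR) paired with the offline-anchored
biomass value.  Samples inside fault-flagged intervals can be excluded via
a fault report.  The 8:2 train/validation split is random over samples
(|train| = round(0.8·n) exactly); a batch-blocked mode exists for the
methodologically safer variant when batches are strongly autocorrelated.
Features and target are z-scored with training-set statistics only.  The
regressor is a contract (fit/predict/serialize); the reference
implementation is a small MLP — hidden layers (64, 64, 32, 16), i.e. six
layers counting input and output — next to a transparent linear baseline
used in tests.  Models serialize with their standardization statistics
embedded, so a reloaded model predicts bitwise identically.

## Synthetic generator

The generator is the package's test bed and defines its study conditions:

* lagged logistic biomass `X(t) = K/(1 + (K/X0 − 1)e^(−μ(t−lag)))`
  (defaults X0 = 0.2, K = 40 OD600, μ = 0.35 h⁻¹, lag = 2 h — a realistic
  24 h fed-batch); richer substrate kinetics are deliberately avoided, the
  pipeline rather than the biology being under test;
* respiration `OUR = a·dX/dt + m_O2·X` (a = 3 mmol/OD, m_O2 = 1.2
  mmol/OD/h), `CER = RQ·OUR` with constant target RQ = 1.05;
* outlet gas fractions obtained by *inverting* the inert-gas balance under
  N₂ closure to 100%, so running the forward equations on noiseless data
  recovers the ground-truth CER/OUR exactly at the sampled points — the
  only error left in the full round trip is interpolation between at-line
  samples (measured ≈ 0.17% worst-case at default cadences);
* inlet fixed at dry air (CO₂ 0.04, O₂ 20.96, N₂ 79.00%), consistent with
  the 0.02–0.05% CO₂-in-air fault band;
* streams sampled at 1 min / 20 min / uniform 2–4 h cadences with
  per-variable Gaussian noise; DO, agitation and base pump are coupled to
  OUR the way cascade control couples them;
* fault injection: steps, linear drifts, and variance bursts.  A variance
  burst is a *sustained alternating oscillation* of relative amplitude
  equal to the requested CV (±15% amplitude jitter), not iid Gaussian
  draws: with only ~12 at-line points in a burst, a Gaussian draw regularly
  realizes far less variance than requested, which would make the injected
  "anomalous" label contradict the generated data;
* multi-batch studies add small relative jitter (default 5%) to growth
  parameters, with designated outlier modes (`stunted`, `contaminated`).

Everything is deterministic given the seed, and each batch ships with a
ground-truth sidecar so tests never re-derive the truth they check.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: substrate/product inhibition, gas-phase dynamics
and probe lag, autocorrelated (non-Gaussian) sensor noise, missing-at-random
dropout, OD600 overestimating viable biomass late in fermentation, and
cross-channel fault propagation.

## Problem sizes and numerical choices

Tests and the acceptance script run 12–33 h batches at the native 1-min
cadence (721–2,001 grid points), 6-batch studies for the PCA checks, 50
seeded simulations for fault recall, and n = 2,000 samples for soft-sensor
recovery — sizes chosen so the full suite completes in seconds while every
check still operates at the pipeline's real cadence structure.  Float CSVs
are written at full precision and re-read with round-trip parsing, which is
what makes byte-identical reruns and exact export/import checks possible.
Tie-breaks, extrapolation policies and degenerate-input behaviour (empty
rule lists, all-missing series, zero-variance normalization, RQ at OUR = 0)
are each pinned by a test rather than left to library defaults.

## Known limitations

One-process batch semantics: the original platform's continuous real-time
service loop is replaced by idempotent re-runs over growing files.  No live
transport protocols (only the register payload codec), no kLa estimation or
elemental reconciliation, no temperature correction of the molar volume,
and the soft-sensor reference network makes no claim to any particular
published accuracy — the pipeline, not the regressor, is the contribution.
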