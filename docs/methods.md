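# Methods

## The model

The analysis treats a monthly disease-count series y(t) and a monthly
solar-activity series s(t) as superpositions of components living on
different time scales:

    log y(t) = a + b·t  +  seasonal(t)  +  β·s(t − L)  +  noise,

with b the exponential growth trend on the log scale, seasonal(t) an annual
cycle, β a small linear "coefficient of influence" (log-cases per unit of
solar activity) and L a latency of possibly several decades.  The
long-term solar signal is weak relative to trend and season, so each is
removed on its own time scale: the trend by OLS on the log series, the
seasonal component (and sub-annual noise) by low-pass KZ filtering, after
which the lagged association is estimated by cross-correlation and simple
linear regression.  All frequencies in the package are cycles per month;
period in years = 1/(12·f).  Month indexing is 0-based from a series'
calendar anchor; all lags are integer months; day-of-month is ignored.

### KZ filtering

KZ(k, m) is k passes of an m-point centred moving average; its amplitude
gain is |D_m(f)|^k with D_m the normalised Dirichlet kernel, so iterating
drives the sidelobes down geometrically.  Because an even 12-month window
has no centre month, the seasonal filter is the *modified 13-month window*:
weights proportional to (½, 1, …, 1, ½)/12 — algebraically the convolution
of a 12-point and a 2-point uniform window — whose gain

    G(f) = ( |sin(12πf) / (12 sin(πf))| · |cos(πf)| )^k

is exactly zero at f = h/12 for h = 1..6 (the annual cycle and every
harmonic) and 0.973 at f = 1/132 for k = 2.  `kz_gain` evaluates this
analytically and serves as the oracle for the numerical filter tests.

Boundary handling: the default policy is **trim** — only output months
whose window lies fully inside the series are kept, shrinking the series by
k·(m−1)/2 months per end.  The alternative **shrink** policy renormalises
the weights over the available (and non-missing) points and keeps full
length.  Trim is the default because the latency analysis concerns interior
long-term structure and edge-renormalised values would leak into the
cross-correlation; shrink is provided for users needing full length.  Under
trim a gap (NaN) anywhere in a window yields a gap in the output; under
shrink the weights renormalise over the non-missing points.

### Spectral diagnostics

`raw_periodogram` is |DFT|²/N at Fourier frequencies j/N after mean
removal (one-sided, not doubled; Parseval: twice the sum over interior bins
plus the Nyquist bin equals N times the biased variance).
`kz_periodogram(series, m, k)` averages the periodograms of all N−m+1
maximally overlapping sub-windows of length m, each demeaned individually
so local trend leakage is bounded by the sub-window; frequencies are j/m.
This is a stride-1 Welch-type estimator: resolution 1/m, variance reduced
by averaging.  k = 1 is the plain average; k > 1 applies extra 3-bin
moving-average passes on log power and is flagged experimental, because the
iteration count of the averaged periodogram beyond the first is not a
well-defined part of the published algorithm.

Adaptive smoothing (`dz_smooth`) follows the principle that the averaging
span should vary inversely with local spectral concentration: at each bin
the half-span h(i) is the largest h for which the power enclosed in
[i−h, i+h] stays ≤ c × total power (truncated at boundaries; h = 0 where
a single bin already exceeds the budget, so dominant peaks pass through
unchanged).  This concrete span rule is our interpretation of adaptive
spectral smoothing — the original algorithm is only cited, not specified,
in the source material — and it is documented and tested as such.  The
published smoothing percentages map to c = percentage/100.  The rule
guarantees min(input) ≤ output ≤ max(input) and spans nondecreasing in c.

### Latency search and regression

Positive lag t means the solar series leads: outcome month s is paired with
predictor month s − t over their calendar overlap (no padding or taper; the
overlap count n is reported per lag so edge lags can be judged).  Negative
lags are out of scope — causality runs one way.  Candidate latencies are
strict local maxima of r within [12·min_years, 12·max_years] (plateaus
collapse to their first lag; ties in `best_latency` resolve to the smallest
lag and are recorded).  The default window 0–70 years spans disease onset
to human lifespan.  For quasi-periodic signals the profile echoes the true
latency at ± whole cycles; maximisation selects among the echoes, and it is
the cycle-to-cycle irregularity of the solar series that makes the true lag
the maximiser.

R² is reported as the squared Pearson correlation at the chosen lag.  With
moving-average-filtered series consecutive points are strongly
autocorrelated, so this is a quality-of-fit summary, not an inferential
statistic; no standard errors or p-values are produced for the lagged
regression.  Report rounding: slopes 4 decimals, r 2, percentages 1–2,
lag-years 1; full precision is kept internally.

The percentage conversion 100·(e^(β·ΔSN) − 1) is exact on the log scale and
multiplicative across increments.  A separately measured irradiance slope
(0.0081 W/m² per sunspot) converts sunspot differences to W/m²; the
analysis relies on SN rather than TSI because only the sunspot record is
long enough to cover multidecade latencies.

A note on published arithmetic: the source analysis prints r = 0.63 with
R² = 0.3911 at the 42.2-year latency (0.63² = 0.3969) and elsewhere pairs
r = 0.68 with R² = 0.39 (0.68² = 0.4624).  These printed values are
mutually inconsistent; this package always computes r² exactly.

## The synthetic scenario

`scenario_paper_default()` mirrors the real study design: a 1200-month
solar record (1910-01..2009-12) against a 312-month case record
(1984-01..2009-12, a 26-year registry window), embedded latency 506 months
(42.2 years), monthly log-trend 0.0034 (≈4.2 %/yr), coupling β = 0.0003
log-cases per sunspot, baseline 500 cases/month, Poisson count noise, and
an annual cycle of amplitude 0.2 on the log scale.

The solar generator produces s(i) = max(0, a(i)·A·(1 + sin θ(i)) + ε_i):

* amplitude A = 100, so a mean cycle swings 0–200 SN (typical observed
  maxima run 150–250);
* a(i): one amplitude factor per cycle (relative sd 0.15), interpolated
  smoothly between cycle midpoints;
* θ(i): piecewise-linear phase, one full turn per cycle with per-cycle
  durations of mean 132 months and relative sd 0.18 (observed cycles run
  roughly 9–14 years);
* ε: AR(1) with coefficient 0.9 and marginal sd 40 SN — monthly sunspot
  departures from the cycle persist across solar rotations, they are not
  white.

The irregularity parameters matter: with an exactly periodic sinusoid,
every lag a whole number of cycles from the truth is a statistical clone of
it and no method can prefer the true latency.  Amplitude/length variation
plus the persistence of the monthly noise (which the coupling imprints on
the case series at the true lag only) are precisely the features of the
real record that make maximisation work.  The noise magnitudes are
calibration choices, not estimates — they were fixed once so that the
scenario exhibits the documented recovery behaviour (latency within ±6
months in ≥18 of 20 seeds, trend within 3 SE, coupling sign always
correct) and then frozen.

What the generator does **not** emulate: secular (multi-century) solar
modulation; the pre-1984 growth-rate regime of the case record and the
regime change itself; registry artefacts (reporting delays, coding changes,
site accession); population-structure drift; per-cancer-type heterogeneity;
any latitude or regional structure.  Passing tests therefore show that the
pipeline recovers the generating parameters under the stated stochastic
structure — not that the corresponding real-data estimates are unbiased in
the presence of the un-modelled features.

Two measured caveats, documented rather than patched:

* **Detrending asymmetry.** OLS trend removal on the log outcome absorbs
  whatever part of the lagged solar component drifts linearly across the
  window, while the predictor keeps that drift.  For epochs where the
  amplitude envelope produces a strong drift this structurally lowers the
  true-lag correlation (the residual ~2/20 recovery failures), and also
  shaves ~2.5 % off an embedded 132-month cycle's amplitude on a 312-month
  span.  This asymmetry is inherent to the published stage order
  (outcome-only detrending), which the pipeline deliberately does not
  auto-correct.
* **Null scenario.** With the coupling set to zero, the best correlation
  over ~840 lags of two smooth series is not guaranteed small: filtered
  noise is heavily autocorrelated, so best-r values well above 0.3 occur
  for many seeds.  The documented scenario seed shows best r < 0.3; the
  pipeline's defence against such chance maxima in practice is the
  epidemiological latency bound plus inspection of the full profile, not a
  significance claim (which the method deliberately does not make).

## Problem sizes and numerics

The test suite and acceptance script run entirely on generated data: series
of 312–1200 months, 20-seed recovery sweeps, 100-replicate spectral
variance comparisons and 100 random oracle instances; the whole suite
completes in a few seconds on one CPU.  Filter weights are validated to sum
to 1 within 1e-12; oracle equivalences are asserted at 1e-10..1e-12;
empirical-vs-analytic gain at 1e-6; seasonal annihilation at 1e-8.  Ties in
`dominant_frequency` and `best_latency` break toward the lower
frequency/lag, and plateau local maxima collapse to their first lag, so all
selections are deterministic.  Generation is bit-reproducible from the
config seed via per-product seed streams; no global random state is used.
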