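# Methods

## Micro-movement spikes

A kinematic series (angular speed in rad/s, acceleration in m/s², or the
Euclidean norm of a 3-D position/velocity channel) is reduced to its local
peaks. A peak is a sign change of the first difference from positive to
negative; plateaus count once, at their first sample (a deterministic
tie-break), and a flanking minimum that would fall off the series uses the
boundary sample. Each peak V is normalized by the mean of its two flanking
minima,

    N = peakV / (peakV + (min_before + min_after) / 2),

which is invariant under any positive rescaling of the signal — the sense
in which the representation "scales out" anatomy. Because a peak strictly
exceeds both flanking minima, N always lies in (1/2, 1]. Values are
reported at a fixed 1e-9 resolution (nine decimals on a quantity of order
one), which makes the scale cancellation exact in floating point as well;
the discarded precision is far below the sampling noise of any real
recording. No minimum-prominence filter is applied before normalization:
every strict local maximum is a spike, which is what makes the series
sensitive to micro-fluctuations (and, deliberately, to tremor-band
contamination).

Centering subtracts the mean of a maximum-likelihood gamma fit
(location pinned at zero); the fitted shape and scale are retained. A fit
is attempted only with at least 20 spikes — below that the signature is
reported missing rather than fitted.

## Single-delay causal model

For a directed pair with target x and source y (both mean-centered spike
series, truncated to the shorter length), the models

    x_n = a1 x_{n-l} + w1_n          (non-causal)
    x_n = a2 x_{n-l} + b y_{n-l} + w2_n   (causal)

are solved at one internal delay l, and GC = log(sigma1^2 / sigma2^2).
Lags are counted in spike-index units by default (one lag = one inter-peak
step); a sample-indexed convention is available by running the sweep on
sample-indexed series instead.

Two estimators are shipped:

* `mode="paper"` solves the classical pencil-and-paper moment equations
  in closed form: a1 = Rxx(0)/Rxx(l); the 2x2 system
  Rxx(0) = a2 Rxx(l) + b Rxy(l), Rxx(l) = a2 Rxx(0) + b Rxy(0);
  sigma1^2 = (1 - a1^2) Rxx(0); sigma2^2 = (1 - a2^2) Rxx(0)
  - b^2 Ryy(0) - 2 a2 b Rxy(0). These equations drop noise-process cross
  terms that are nonzero under the generative model; in particular
  |a1| = Rxx(0)/|Rxx(l)| >= 1 for any real series, so sigma1^2 <= 0 at
  every lag. The `strict` validity policy marks such lags invalid and
  makes the pathology visible; the `permissive` policy returns the GC
  whenever the variance ratio is positive (the log of a ratio of two
  negative variances is what the closed forms produce on real data).
* `mode="ols"` solves the least-squares normal equations using
  Gram-consistent moments (every expectation taken over the same index
  window t in [l, n)), so the residual variances are true projections and
  nonnegative by construction. This estimator recovers planted
  coefficients and delays and is the default of the orchestrated pipeline.

The optimal lag is the smallest lag attaining the maximal valid GC over
the sweep grid (default 1..50, capped at n/4); force = max GC / optimal
lag, defined only for a positive optimal lag.

### Significance

The surrogate null circularly shifts the source and recomputes the sweep's
max GC; p = (1 + #{surrogate >= observed}) / (1 + B), B >= 99 (199 by
default). Offsets keep a circular distance of at least twice the maximum
candidate lag from zero: a shift of n - 3 is a 3-step shift backwards in
time, and shifts barely beyond the lag grid let the source's serial
dependence leak the true coupling into the null from either time
direction. Two finite-sample facts matter for interpretation: the max-over-
lags statistic has roughly n / L independent placements on a length-n
series (L = number of swept lags), so the extreme tail of the test is only
trustworthy when n is a couple of orders of magnitude above L — at the
1% level this means on the order of a thousand spikes. On a single
three-minute walk (~180 spikes) the 1% test is usable but its tail is
coarse, and occasional spurious edges are expected.

A feedback loop between two nodes is declared when both directions are
significant with positive max GC. The per-group feedback map is the
percentage of subjects with a loop per unordered node pair. The network
asymmetry index is the normalized L1 directional difference
sum |GC(i->j) - GC(j->i)| / sum (GC(i->j) + GC(j->i)) over pairs with
both directions valid and positive (a design choice — no canonical
formula exists for this quantity; any monotone alternative can be
substituted through configuration).

## Spectral measures

Cross-coherence is the magnitude-squared coherence of two sample-indexed
series on Hann-tapered Welch segments (default 4 s, 50% overlap — at
least eight segments on a three-minute walk while resolving the gait
band). MMS series enter as zero-filled spike trains (normalized values at
their peak samples). The coupling frequency is the argmax over non-DC
bins; a node's coupling strength is the mean of its maximal coherences
over all partners. The mean frequency of a spectrum is sum(f P) / sum(P);
when applied to a time series the series is demeaned first so the DC term
does not drag the mean toward zero.

The band-stop probe removes a frequency band by exact zero-phase spectral
surgery (the band's FFT coefficients are zeroed) and re-runs the MMS +
gamma pipeline. The filtered signal is quantized at 1e-4 of the signal's
range: an IIR filter's (or any filter's) sub-resolution ripple would
otherwise be counted as micro-movement — every numerical wiggle is a
strict local maximum — and dominate the NSR comparison. With this
hygiene, removing a band far from all signal content leaves the NSR
unchanged, while removing an injected tremor band reverts the NSR toward
its clean value.

## Stochastic signatures

* **Gamma NSR.** MLE gamma fit with location zero; the scale parameter is
  the noise-to-signal ratio (variance/mean of a gamma variate). Adjusted
  Fisher-Pearson skewness is reported alongside.
* **Dip statistic.** The sup-norm distance between the empirical CDF and
  the nearest unimodal CDF, computed exactly. For each candidate mode
  block (the optimal unimodal CDF may carry an atom at its mode), the
  best convex fit left of the mode and concave fit right of it reduce to
  greatest-convex-minorant / least-concave-majorant constructions on the
  ECDF's step corners; where the two sides' reachable values at the mode
  fail to order, the exact threshold is found by bisection on the tube
  width. The implementation is validated against an independent
  linear-programming oracle (direct minimization over piecewise-linear
  unimodal CDFs) to below 1e-12 on random small samples with ties; the
  same experiments show that mode positions between data points never
  improve on mode-at-a-block positions. Values lie in (0, 0.25]; a sample
  of n distinct points compatible with unimodality has dip 1/(2n), and
  two equal point masses approach 0.25. The p-value is a bootstrap from
  uniform samples of the same size (B = 2000 by default; Hartigan's
  asymptotic tables are avoided for small n). A precomputed null table
  can be supplied to amortize repeated tests at one sample size.
* **Mode decomposition.** A two-component mixture — an exponential mode
  anchored at the sample minimum (the low-amplitude, memoryless mode) and
  a Gaussian mode — fitted by EM with a deterministic quantile-based
  initialization and a seeded tie-break jitter. Points are assigned by
  maximum posterior responsibility; mode1_fraction is the exponential
  share of points (share-of-points was chosen over summed amplitude for
  "where activity is highest"; the alternative is a one-line change). A
  mixture weight pinned below 0.1 (or above 0.9) flags the sample as
  effectively unimodal. The EM log-likelihood is monotone and asserted so
  in tests.
* **Amplitude-timing histogram.** Joint histogram of spike amplitude vs
  preceding inter-peak interval with a chi-square independence diagnostic
  (reported for exploration, not formal inference).

## Stratification

The stride proxy divides mean speed of the lower-body COM (length-weighted
per-node average; equal weights with a logged warning when segment lengths
are not supplied) by the mean frequency of the demeaned speed spectrum —
meters per stride. Feature normalization is min-max by default (z-score
optional); constant features are flagged, not divided by zero. Clustering
is seeded Euclidean k-means with restarts; k is configured per group and a
silhouette scan is advisory only. Group difference maps use Welch's
unequal-variance t-test per node at alpha = 0.05 with no multiple-testing
correction by default (mirroring per-node maps; Benjamini-Hochberg is
available off by default); entries are zeroed where non-significant and
signed mean differences elsewhere.

## Synthetic generator

Each subject is a jittered cycle grid (cadence 1 Hz by default; lognormal
cycle-period factors, 5% sd) shared by all nodes, one movement cycle per
period rising from a baseline trough to a peak and back (raised-cosine
bump, so the first derivative is continuous). The planted truth lives at
the spike level: the *normalized* amplitude g of every cycle is drawn
first — by default gamma with mean 0.72 and sd 0.08 (shape 81, scale
0.0089), comfortably inside the representable (0.5, 1) band, clipped to
(0.505, 0.98) — and the waveform peak is built as m·g/(1−g) over baseline
m so that MMS extraction returns exactly the planted values up to sampling
discretization (~1e-4 at 100 Hz). Directed couplings add
gain · (source amplitude, lagged, centered) at the spike level, so the
downstream causal analysis sees exactly the single-delay structure it
estimates; bidirectional pairs are generated jointly, index by index.
Mode-mixture amplitudes (exponential above 0.52 at rate 25 plus a
Gaussian at 0.78 ± 0.04) emulate the two-mode amplitude distributions.
Tremor is an additive sinusoid; at ~1% of the baseline it contaminates
each cycle with a sub-population of low-amplitude spikes and raises the
fitted NSR, which the band-stop probe then reverts. Large tremor
amplitudes instead make sub-cycle spikes dominate the distribution and
*lower* the fitted scale — an instructive failure of the NSR as a tremor
index, not a bug in either piece.

What the generator does not emulate: broadband sensor noise, nonstationary
cadence drift, amplitude-timing dependence, device-specific artifacts, or
biomechanically coupled multi-joint dynamics. Tests passing on this
generator therefore establish that the estimators recover what they claim
to measure under the model's own assumptions — not that real recordings
satisfy those assumptions.

The bundled demo cohort has two groups of planted, opposing signatures:
control-like (exponential-mode weight 0.2; bidirectional foot coupling,
gain 0.5, lag 2) and impaired-like (weight 0.6; gain 0.25, lag 4 — hence
lower force on both foot axes). Per-subject parameters are drawn around
group means (cadence ± 0.05 Hz, lognormal gain jitter, mixture weight
± 0.03).

## Problem sizes and numerical choices

Verification experiments are sized so the full suite runs in a few minutes
on one CPU: estimator exactness on 1000 random moment sets (tolerances
scaled by the magnitude of the summed terms, so ill-conditioned systems
are compared meaningfully); delay recovery on 100 runs of 5·10^4 points;
surrogate calibration on 500 replicates of length 1000 (see the tail
granularity note above); feedback detection on 200 pairs of 400 spikes;
dip-null calibration on 500 replicates at n = 200 against a shared
1500-draw null table; cohort separation over 20 seeded pipeline runs with
three subjects per group and two-minute walks. The gamma-scale check at
~150 spikes uses the mean over ten seeded walks because a single MLE scale
at that size has ~12% sampling error. Degenerate inputs (constant series,
all-zero power, singular 2x2 systems, zero-length bands, groups of one)
raise errors or are flagged rather than silently propagated; argmax ties
resolve to the smallest lag / lowest frequency.
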