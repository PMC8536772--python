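# mmsgait

Directed causal networks and stochastic signatures from multi-node
wearable gait recordings.

Clinicians and movement scientists who record natural walking with a grid
of body-worn sensors (angular speed, linear acceleration, 3-D position at
60–500 Hz) face two recurring problems: kinematic amplitudes scale with
anatomy, so raw signals are not comparable across people, and summary
averages throw away the moment-to-moment fluctuation structure that
carries the clinically interesting signal. `mmsgait` implements a
fluctuation-first analysis chain:

1. **Micro-movement spikes (MMS).** Every local peak *V* of a kinematic
   series is normalized by its flanking local minima,
   `N = peakV / (peakV + mean(min_before, min_after))`,
   giving a unitless spike series in (½, 1] that cancels amplitude scale.
   The MLE-fitted gamma mean can be subtracted to center the series, and
   the inter-peak intervals form a companion timing series.
2. **Single-delay Granger causality.** For a directed node pair the
   non-causal model `x_n = a₁ x_{n−l} + w₁` is compared with the causal
   model `x_n = a₂ x_{n−l} + b y_{n−l} + w₂` at one internal delay *l*;
   `GC = log(σ₁²/σ₂²)`. Sweeping *l* yields the **optimal lag** (the
   pair's internal motor timing) and the **force** `max GC / optimal lag`,
   a proxy for the speed of information transfer. Two estimators are
   provided: a pencil-and-paper closed-form moment solver (`mode="paper"`) and a
   Gram-consistent least-squares solver (`mode="ols"`). Significance comes
   from circular-shift surrogates; causality detected in both directions
   of a pair is a **feedback loop**.
3. **Networks.** Per-subject directed graphs with out-degree, maximum
   outward GC/lag, a normalized asymmetry index and feedback pairs;
   per-group feedback-prevalence maps.
4. **Spectral coupling.** Magnitude-squared cross-coherence between
   sample-indexed MMS trains, the coupling frequency that maximizes it,
   power-weighted mean frequency, and a band-stop probe that measures how
   removing a tremor band changes the noise-to-signal ratio (NSR).
5. **Stochastic signatures.** MLE gamma fit (the scale is the NSR),
   skewness, an exact Hartigan dip statistic of unimodality with a
   bootstrap p-value, and an EM decomposition of the amplitude
   distribution into a low exponential mode and a higher Gaussian mode.
6. **Stratification.** Per-subject feature vectors (mode-1 share, dip,
   stride proxy `mean speed / mean frequency` in meters, pelvic NSR,
   network asymmetry, foot forces, mean timings), min-max/z-score
   normalization, seeded k-means, and per-node Welch-test group difference
   maps.
7. **Synthetic cohorts.** A seeded generator of gait-like recordings with
   known ground truth (cadence, planted spike amplitudes, directed lagged
   couplings, tremor), so every stage of the chain can be verified against
   what was planted.

## Worked example

`examples/02_causal_network.py` simulates a three-minute walk in which
the left foot drives the right foot with gain 0.5 at a delay of two
spikes, then recovers the network:

```
significant directed edges (source -> target, GC @ lag, force):
  foot_l -> foot_r: GC=0.307 @ lag 2, force=0.153, p=0.005
out-degrees: {'pelvis': 0, 'foot_l': 1, 'foot_r': 0}
feedback pairs: []
```

The single significant edge points in the planted direction, the optimal
lag equals the planted two-spike delay, and no feedback loop is reported
because the reverse direction is not significant. The other examples
(`examples/01…04`) walk through MMS extraction, stochastic signatures and
cohort stratification the same way; each prints the quantity it recovers
next to the planted truth.

A command-line interface mirrors the library:

```bash
mmsgait simulate --seed 7 --out runs/demo
mmsgait all --seed 7 --out runs/full     # simulate + every analysis stage
```

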