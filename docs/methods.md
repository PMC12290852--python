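# Methods

This note documents the models and estimators implemented in `neurofei`,
the defaults they ship with, the reasoning behind the genuinely open design
choices, and what the synthetic benchmarks do and do not establish about
real recordings.

## Frequency binning

The default scheme covers 1–150 Hz with 16 contiguous bins: one wide delta
bin (1–4 Hz) and 15 bins whose widths grow geometrically (ratio ≈ 1.27) up
to 150 Hz.  The edges are pinned as a canonical table at 0.5-Hz resolution

```
1 | 4 | 5 | 6.5 | 8 | 10.5 | 13 | 17 | 22 | 28 | 35.5 | 45 | 57.5 | 73 | 93 | 118 | 150
```

rather than produced by rounding a geometric sequence: no single geometric
ratio rounds to all of these edges, because the scheme is ultimately
calibrated against the spectral overlap of adjacent filters, which bends a
few edges (8, 13, 22, 28) off the pure geometric grid.  The generic
constructor `make_frequency_bins` builds geometric schemes with nearest-0.5
rounding for other spans and resolutions.

## Band-pass filtering and envelopes

Each bin is extracted with a windowed-sinc (Hamming) linear-phase FIR
applied forward–backward (zero net phase; a band-limited pulse keeps its
peak latency to within one sample).  The number of taps is the larger of
two constraints: the impulse response spans at least `n_cycles = 2` cycles
of the bin's lower edge, and at least `transition_factor = 1` period of the
bin bandwidth.  Both shrink with frequency, so the filter transient — and
with it the smallest trustworthy DFA window — shortens as frequency grows.
The cutoffs are widened by half the Hamming transition width on each side,
keeping the passband flat (< 1 dB ripple) across the nominal bin at the
price of leakage of order half a transition band into the neighbours; that
overlap is what the geometric bin widths are sized against.  Keeping the
filters short is deliberate: their autocorrelation must die out well below
the 5-s fE/I window.  The amplitude envelope is the magnitude of the
analytic signal (FFT Hilbert transform), with one full filter transient
trimmed from each edge before any statistic is computed.

## DFA and the adaptive fitting range

DFA follows the standard recipe: cumulative sum of the demeaned envelope,
sliding windows (50% overlap) on a log-spaced grid of 10 sizes per decade
from 0.1 s, least-squares line removed per window, RMS residual averaged
arithmetically across windows, and an unweighted OLS fit of log₁₀F against
log₁₀t inside the fitting range.  The upper bound defaults to 30 s and is
additionally capped at one sixth of the envelope duration so the longest
scale retains several independent windows.

Narrow-band filtering makes even white noise locally correlated, which
inflates F(t) at small t.  For an envelope that is uncorrelated beyond the
filter's reach, the squared fluctuation follows F²(t) = a²t − c, so the
local log-log slope approaches 0.5 from above as 0.5 + 0.5·c/(a²t).
`calibrate_lower_bound` estimates (a², c) by least squares on the averaged
fluctuation curve of 20 band-limited white-noise simulations (600 s each)
beyond twice the filter transient, and returns the window size where the
analytic slope deviation falls to the tolerance (default 0.02), snapped to
the DFA grid.  Fitting this two-parameter crossover is far more stable
across random seeds than thresholding noisy finite-difference slopes.  With
the default filters the calibrated bounds fall from ≈ 20 s in the delta bin
through ≈ 8 s in the alpha bins to ≈ 1 s above 60 Hz; they are cached per
(bin, sampling rate, filter, tolerance, seed).

The calibrated delta-bin bound is intentionally conservative: at tolerance
0.02 the 1–4 Hz envelope only reaches the white-noise slope near 20 s, so
its fitting range [20, 30] s holds just three grid sizes.  Loosening the
tolerance or shortening the delta filter shifts this bound down at the cost
of residual filter bias; both are exposed as parameters.

## fE/I

The signal profile is computed once over the whole envelope; within 5-s
windows (80% overlap — the overlap is a convention carried over from the
original algorithm, not a printed value) the mean amplitude and the
amplitude-normalized detrended fluctuation nF (window RMS residual of the
profile divided by the window mean amplitude, stored as log₁₀) are
collected, windows with zero mean amplitude excluded, and

    fE/I = 1 − Pearson r(amplitude, nF)

Since r ∈ [−1, 1], fE/I ∈ [0, 2] whenever defined, and the construction is
exactly invariant under rescaling the input signal.  fE/I is reported as
missing — with the reason recorded, never silently dropped — when the DFA
exponent of the same envelope is ≤ 0.6 (no reliable temporal structure to
correlate with), when fewer than 10 windows exist, or when either series is
degenerate.  A Spearman variant is available for robustness checks.

## The critical-oscillations network

The simulator places 2,500 probabilistic integrate-and-fire neurons (75%
excitatory) on an open 50 × 50 grid.  Each excitatory neuron sends synapses
to C_E% of the neurons within Chebyshev distance 4, each inhibitory neuron
to C_I% within distance 2; connections are drawn independently per
candidate (binomial out-degrees), so different seeds give different
topologies at the same (C_E, C_I).  Per 1-ms step, each neuron carries an
excitatory and an inhibitory input trace decaying with τ = 9 ms,
incremented by the signed weights of the previous step's presynaptic
spikes; the firing probability is `p_spont + clip(vE − vI, 0, 1)`; firing
resets the excitatory trace (inhibition persists), and is followed by a
10-ms absolute refractory period.  The EEG-like network signal adds
i.i.d. Gaussian noise (SD 3) to the per-step population spike count, which
guarantees a time-varying phase during silent periods.  Topology, dynamics
and measurement noise use three independently seeded random streams, and a
(config, seed) pair reproduces a raster bit for bit.

The dynamics equations and constants are this package's own
parameterization of the model family (the documented topology and signal
construction are fixed; published parameter tables for the adapted dynamics
were not available), with every constant exposed through `NetworkConfig` so
an alternative table can be dropped in without code changes.  The synaptic
weights (w_EE = w_EI = 0.008, w_IE = w_II = −0.05), spontaneous rate
(10⁻⁵/ms) and refractory period were calibrated once, against the model's
own avalanche statistics, so that along the printed validation diagonal
(C_E from 30% to 42% with C_E + C_I = 80%) the size-based k-index crosses 1
near the middle: mean activity and alpha-band power rise monotonically with
C_E, k runs from ≈ 0.84 (sub-critical) to ≈ 1.13 (super-critical), and the
DFA of narrow-band envelopes is elevated around the crossing.  An optional
multi-timescale short-term synaptic depression (resource pools recovering
over 0.5–32 s) is implemented and exposed in the config but disabled by
default: it injects seconds-scale gain memory at the cost of visibly
homeostating away the k gradient the validation depends on.

Known limitation: the reconstructed dynamics underproduce long-range
temporal correlations at the 8–30 s scales of the calibrated alpha fitting
range.  Near the critical crossing the envelope DFA reaches only ≈ 0.55–0.7
rather than approaching 1, so the 0.6 gate passes a minority of signals and
the fE/I-versus-k discrimination across the diagonal is much weaker than
the k gradient itself.  The desk-scale validation reports exactly what the
model delivers; see the validation section below for what is and is not
established.

## Avalanches and the k-index

Avalanches are maximal runs of population activity strictly above half the
median per-step activity; the size is the summed activity in the run, the
duration its length.  The k-index evaluates the reference power-law CDF
(density exponent −1.5 for sizes, −2.0 for durations), normalized over the
empirical support [min, max], and the empirical CDF (step form by default;
an interpolated variant is provided) at 10 points equally spaced in log₁₀
between the smallest and largest observed size, inclusive:
k = mean(P − A) + 1.  Networks are labelled near-critical for
k ∈ [0.87, 1.14].  Doubling the activity doubles the threshold and leaves
the segmentation invariant; k is invariant under reordering avalanches.
On 10⁵ inverse-CDF samples from the reference law itself k = 1.00 within
Monte-Carlo error.

## Validation experiment

`run_diagonal_validation` simulates each (C_E, C_I) combination along the
diagonal for a number of realizations, computes k on the raster and
spectral DFA/fE/I on the noise-added signal, and scores per frequency bin:
the percentage of signals with a computed fE/I, the Spearman correlation of
fE/I with k, and the normalized mean absolute rank difference (average
ranks on ties, ranks divided by the number of signals with computed fE/I,
missing pairs excluded first).  Identical orderings score 0%; independent
orderings average (n² − 1)/(3n²) ≈ 33.3% (both the closed form and a
Monte-Carlo path are provided); exactly reversed orderings 50%.

Two presets are shipped.  The `paper` preset is the full experiment — 25
combinations at 0.5% steps, 20 realizations, 1000-s signals — a multi-hour
single-CPU batch exposed via the CLI.  The `desk` preset (9 combinations at
1% steps over C_E 32–40%, 3 realizations, 300-s signals) preserves the
sub → critical → super transition at a few minutes per sweep and is the
scale used in the test suite; problem sizes were chosen so a full test run
stays within routine development budgets.  With the default network, the
desk sweep reproduces the monotone k gradient across the transition
(per-combo mean k ≈ 0.90 → 1.06, crossing 1 near C_E = 37%), but the 0.6
gate passes only about one alpha-bin signal in nine — sporadically and
mostly toward the sub-critical end rather than peaked at the crossing — so
the fE/I–k rank statistics rest on very few signals and do not reach a
strong agreement (see the limitation above).  The accuracy table reports
whatever the model yields rather than a curated subset.

## Synthetic generators

* `synth_lrtc_signal` amplitude-modulates a sinusoid at a bin's center
  frequency with fractional Gaussian noise (exact Davies–Harte circulant
  embedding) offset to stay positive (modulation depth 0.25, clipped at
  0.05), so the band envelope's DFA exponent targets the requested Hurst
  value; at 1000 s the estimator recovers H ∈ {0.55, 0.7, 0.85} within
  0.05.  It emulates a stationary oscillation with known LRTC; it has no
  1/f background, no artifacts, and a single oscillatory component, so
  passing on it shows estimator correctness, not robustness to real EEG.
* `simulate_twins` draws twin pairs from the ACE path model: the genetic
  factor is shared within MZ pairs and correlated 0.5 within DZ pairs, the
  common-environment factor shared within every pair, ages uniform over
  16.5–19.5 years and sex shared within a pair, with optional linear
  age/sex effects on the mean.  Defaults mirror an adolescent twin-cohort
  design; the generator produces exact bivariate-normal pairs, so it tests
  the likelihood machinery, not robustness to non-normal phenotypes.

## ACE model

The ACE likelihood is the product of bivariate-normal pair densities with
mean Xβ (intercept, age, sex per twin) and covariance
[[a²+c²+e², rA·a²+c²], [rA·a²+c², a²+c²+e²]], rA = 1 (MZ) or 0.5 (DZ).
Loadings enter squared, so optimization is unconstrained; Nelder–Mead from
four spread starting points (boundary solutions such as c → 0 are common)
is polished by BFGS.  Dropping A or C and refitting gives likelihood-ratio
tests against χ²(1), as is conventional in twin modelling; because the null
value lies on the variance boundary this is conservative in one direction,
and a 50:50 χ²(0):χ²(1) mixture is available as an option.  Reported
heritability follows the twin-literature convention — a²/(a²+c²+e²) from
the full model, simplified to the AE submodel's a²/(a²+e²) when the C
component is non-significant at α = 0.05 — while `heritability_full`
always exposes the full-model share (the quantity used in parameter-recovery
checks, since the convention switch changes the estimand).  Pairs with a
missing phenotype in either twin are dropped per phenotype, with effective
counts reported.  At 500 + 500 pairs the full-model heritability is
recovered within ±0.08 of the generating value.

## Numerical choices

* Fluctuation functions are computed on float64 sliding-window views with
  closed-form linear detrending; they agree with a naive double-loop
  implementation to better than 10⁻⁹ relative error.
* Window sizes are deduplicated after rounding to whole samples, and sizes
  under 4 samples or longer than the profile are skipped (recorded, with a
  warning for the latter).
* The forward–backward FIR is applied as a single FFT convolution with the
  kernel's autocorrelation; edges are zero-padded and the transient
  trimmed, so results do not depend on scipy's `filtfilt` padding policy.
* Degenerate inputs have defined behavior: constant envelopes flag
  `degenerate` windowed statistics, zero-variance series yield missing
  fE/I with a reason, an all-zero raster yields an empty avalanche set
  with a warning, and a singular ACE covariance scores −∞ likelihood.
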