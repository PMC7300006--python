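# Methods

This note documents the models and procedures implemented in troopkit,
the defaults chosen where the underlying field protocols leave freedom,
and what the synthetic generators do and do not emulate.

## Acoustic analysis

Call units are mono RIFF WAV at 44.1 kHz (integer PCM rescaled to
[-1, 1]; multichannel input averaged to mono). Spectrograms use a
512-point FFT, Hamming window and 95% overlap; frames are half-open
`[start, start + 512)` with hop `round(512 × 0.05)` samples and the
trailing partial frame dropped, so the bin width is 44100/512 ≈ 86.13 Hz.

The five per-unit parameters:

* **duration** = sample count / rate, in ms — exact by construction.
* **PF** — frequency of the global maximum of the frame-averaged
  magnitude spectrum.
* **FR** — high edge minus low edge of the set of bins whose
  frame-averaged amplitude exceeds a threshold relative to the peak.
  The threshold defaults to −20 dB and is configurable
  (`band_threshold_db`); a *relative* threshold makes FR and DFB1
  invariant to recording gain. Note that for a pure tone not centred on
  a bin, the −20 dB band of a Hamming-windowed sinusoid spans 3–4 bins,
  so FR has a floor of a few bin widths even for a line spectrum.
* **DFB1** — centre frequency of the lowest contiguous run of
  above-threshold bins (the first dominant frequency band).
* **DFA2** — per frame, the frequency at which the cumulative spectral
  energy (squared magnitude) first reaches 50%, averaged over frames.
  The 50% point is configurable (`dfa2_quantile`); the spectral-median
  reading is one of several possible formalisations of "the frequency at
  which the mean energy distribution is reached" and is therefore
  exposed as a config choice and validated only on synthetic signals
  with known spectra.

Feature normalisation optionally log-transforms a column and then
z-scores it (population sd by default). `log_rule="auto"` logs a feature
when a Shapiro–Wilk test rejects normality at 0.05 *and* the logged
column is less skewed; explicit per-feature flags are accepted, since
"transform when necessary" is a judgement call in the original
workflows. Whether duration should be logged is left to the flag.

Stimulus assembly sums two calls with synchronous onsets, cuts/pads to
exactly 4.000 s, applies a zero-phase Butterworth high-pass at 1 kHz
(order 4 per pass, i.e. ≥ 45 dB attenuation one octave down after
forward–backward filtering) and peak-normalises to 0.95 full scale.
Only the cut-off frequency is dictated by the protocol; the filter
family and order are implementation choices exposed as parameters.

## pDFA

The classifier is the pooled-covariance Gaussian discriminant (equal
covariance across callers, empirical priors). A ridge of
`1e-8 × mean total variance` is added to the covariance diagonal: with
five features and the small classes that arise under permutation, the
pooled covariance can be near-singular, and scaling the ridge by the
data variance keeps it effective regardless of units. Ties in the
discriminant score resolve to the lowest caller id.

The permutation engine shuffles the bout→caller assignment vector
uniformly; units inherit their bout's new caller. This preserves the
multiset of bouts per caller exactly (class sizes in *bouts* are
conserved; unit counts vary with bout sizes). The p-value uses the
add-one formula `(r + 1)/(m + 1)`, which is never 0 and is exact for
permutation tests. Per-caller accuracies are compared against their own
permuted distributions the same way.

The cross-validated variant scores leave-one-out accuracy, refitting
without the held-out unit via rank-one downdates of the class sums and
scatter. Unit-level holdout matches the classical procedure but leaks
bout information (other units of the same bout remain in training), so
a bout-level holdout is offered and demonstrated in the tests; the
default stays unit-level. The inclusion rule admits a caller only when
its unit count strictly exceeds the number of features.

A K-fold variant other than leave-one-out is deliberately not
implemented: with bout nesting, honest folds should be bout-stratified,
and the bout-holdout option already covers that need.

## Social metrics

* **Friendship score**: co-occurrence count over scans, pooled
  symmetrically over which member was focal. A `rate` mode divides by
  the dyad's combined scan effort for unbalanced designs; the default is
  the raw count, appropriate when effort is balanced by protocol
  (e.g. a fixed number of scans per focal).
* **Dyadic z-scoring** uses the population sd (ddof = 0) over
  off-diagonal entries; configurable.
* **Elo**: sequential updates in event order; expected winner
  probability `1/(1 + 10^(−Δ/400))`, winner gains `k(1 − E)`, loser
  loses the same, so the rating sum is invariant. Defaults k = 100,
  start 1000 — the conventional defaults of the standard animal-
  behaviour implementations. The logistic (rather than Gaussian) curve
  is the classic closed form; at these k the induced orders are
  near-identical.
* **Eigenvector centrality**: dominant eigenvector of the symmetric
  weighted association matrix via power iteration on `A + λ_max-shift·I`
  (the identity shift leaves the eigenvector unchanged and prevents
  oscillation on bipartite graphs), max-normalised to 1. The central set
  is the top ⌈n/2⌉ (ties by id), reproducing a 10/9 split on 19 adults.
* **Mantel test**: Pearson r over upper-triangle dyads; null formed by
  jointly permuting rows and columns of one matrix; one-tailed
  (greater), since only positive matrix agreement is of interest here.
  Split-half network stability builds per-block association matrices
  after splitting each focal's scans chronologically at the given
  fraction.
* **Kinship** is binary shared-matriline membership; paternal kinship is
  out of scope.

### Condition dyad selection

Callers are always female and never the subject. "Friend" and
"non-friend" need a cut-off the field protocol does not state; the
selector uses the median of the reference individual's friendship scores
with the eligible females: below median = low. Conditions:

1. A = subject's top-scoring female; B = A's top associate among females
   below the subject's median.
2. A as in 1; B = the weakest associate of A among females low with
   both A and the subject.
3. Two females below the subject's median who are above-median
   associates of each other (strongest such pair).
4. As 3 but below-median associates of each other (weakest pair).
5. A = a matriline's matriarch, B = a female of the same matriline.
6. A = a matriarch, B = a female of a different matriline.

Conditions 3–4 return *infeasible* for central subjects: this mirrors the
experimental design, where well-connected subjects have no qualifying
dyads, and makes the skip deterministic rather than dependent on the
realised score pattern. Matriarch identification needs rank information
that is not part of the dyadic inputs, so the selector takes an optional
`ranks` mapping (top-ranked female of the matriline); without it the
lexicographically first female stands in. All ties break by id, making
the selector a pure function of its inputs.

## Looking-time models

Look time in seconds over a 30-s window is modelled on the identity
scale. Three condition models (1 vs 2–4; 3 vs 4; 5 vs 6) are Gaussian
fixed-effects fits with treatment contrasts (reference = first-listed
condition) plus trial order and conflict intensity as controls; the
dyadic-relationship model adds a random subject intercept and drops
conflict intensity. Everything is fitted by maximum likelihood, not
REML, so likelihood-ratio tests across fixed-effect structures are
valid; the LRT statistic is `2(ℓ_full − ℓ_null)` against χ² with df =
number of added fixed effects. The condition models carry no random
intercept by default (each subject contributes one trial per condition
in the relevant subset); a singular random-intercept fit in the
relationship model is flagged and refit as a fixed-effects model with a
warning. Skipped/infeasible trials are excluded listwise, and no
multiple-testing correction is applied across the three condition
models.

Limitations: a Gaussian identity-link model can predict outside [0, 30];
a `log(y+1)` transform is available but not default, because estimates
in seconds are the quantity of interest. VIF is `1/(1 − R²_j)` per
predictor; residual checks report QQ data, skewness, kurtosis and a
Shapiro–Wilk statistic (the underlying protocols treat normality as a
visual check, so no automatic refusal is attached).

## Synthetic generators

All generators are pure functions of their spec, including the seed.

* **Call features**: unit vector = caller mean + bout effect + unit
  noise, all additive Gaussian — deliberately matching the equal-
  covariance Gaussian model the LDA assumes, so that classification
  performance reflects the planted effect and not model mismatch.
  Defaults: 9 callers × 6 bouts × 2–12 units (≈ study scale: ~400 units
  from ~52 bouts averaging ~8 units each), between-caller sd twice the
  within-caller sd. Per-caller bout counts are uniform because the
  source protocols do not report their distribution.
* **Call waveforms**: Hann-enveloped harmonic bursts (fundamental drawn
  per caller in 2–6 kHz, 3 harmonics at −6 dB/step, 150–400 ms),
  16-bit PCM at 44.1 kHz — enough structure for the extractor's
  frequency features to have known ground truth, and concentrating
  energy in the 2–10 kHz band typical of tonal agonistic calls. They do
  *not* emulate real spectro-temporal fine structure (jitter, noise,
  amplitude modulation), so acoustic tests certify the extractor, not
  field robustness.
* **Troop observations**: scans draw each neighbour as an independent
  Bernoulli with the planted dyadic probability (160 scans per focal,
  19 individuals, 5 matrilines by default); conflicts (145 by default)
  pit uniform random dyads, won by the higher latent rank with
  probability `rank_steepness` (a fixed Bernoulli rather than a
  rating-dependent curve — the simplest tunable hierarchy signal);
  grooming is Poisson with mean proportional to affinity, i.e. a
  monotone noisy image of the same network. The default planted
  affinity is matriline-structured *with log-normal dyad-level
  heterogeneity* (sd 0.6 of the log factor): without it, friendship
  would be an exact function of kinship and the two covariates would be
  collinear in the response models, which no real group exhibits.
* **Trials**: for each of 16 subjects, dyads come from the condition
  selector (infeasible combinations emitted as skipped, mirroring the
  exclusion of central subjects from conditions 3–4); look time =
  condition mean + subject intercept + order slope × order + optional
  planted covariate slopes + noise, truncated (not censored) to
  [0, 30] s since the protocol records total duration within a fixed
  window. Default condition means (9.5, 4.3, 7.9, 5.4, 6.5, 5.1 s)
  reproduce the qualitative ordering reported for such experiments,
  with subject sd 1.5 s and residual sd 3 s.

Because trials reuse the dyads the selector returns for a fixed troop,
covariates vary across replicates only through regenerated troops or
noise — recovery experiments therefore regenerate trials (and noise) on
a fixed troop, which is the repeated-measures structure the mixed model
is meant for.

## Validation experiment sizes

The standard experiments in `troopkit.validation` (used by the test
suite and the acceptance script) run at: 200 replicate datasets with a
999-draw permutation null for the pDFA, Mantel and LRT calibrations;
10,000 draws for permutation exactness; 50 random 30-unit tables for the
LDA oracle; 100 random graphs for the centrality oracle; 2000 conflicts
at steepness 0.95 for hierarchy recovery; 200 replicates for model
recovery; 100 waveform fixtures for the acoustic round-trip. These sizes
give binomial standard errors of ~1.5 percentage points on the
calibration rates while keeping a full run to a couple of minutes.
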