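# Methods

`oxiwave` implements an oximetry-only screening pipeline for
moderate-to-severe pediatric sleep apnea-hypopnea syndrome (SAHS): from a
single-channel SpO2 recording it computes wavelet and conventional
oximetry features, selects a non-redundant feature subset, and evaluates
binary classifiers of the AHI >= 5 events/hour criterion under a
split-and-cross-validate protocol. A synthetic cohort generator with
known ground truth stands in for clinical data throughout the test suite.

## Preprocessing

Artifact rules: saturation values below 50% and endpoints of
first-difference slopes above 4 %/s are physiologically implausible
(probe drop-off, motion). Flagged samples are masked and bridged by
linear interpolation between flanking valid samples rather than deleted,
so that downstream fixed-length segmentation and spectral analysis keep
their time base; the mask is carried forward and masked samples are
excluded from time-domain statistics and from the valid-time denominator
of ODI3. Because an interpolated bridge must itself satisfy the artifact
rules, masking and bridging are iterated to a fixed point, which makes
the operation idempotent. Recordings with more than 50% masked samples
are rejected.

Recordings are then brought to a common 25 Hz rate by polyphase FIR
resampling (identity when already at 25 Hz; line-extension padding avoids
edge sag) and rounded to two decimals, half away from zero, matching the
0.01% display resolution of clinical oximeters. Order: artifacts, then
resample, then quantize.

## Dyadic Haar analysis

The discrete wavelet transform is the textbook subband-coding filter
bank: per level, convolve the running approximation with the high-pass
filter g and low-pass filter h and downsample by two,

    D_i[k] = sum_n A_{i-1}[n] g[2k - n],    A_i[k] = sum_n A_{i-1}[n] h[2k - n],

with the quadrature-mirror relation g[L-1-n] = (-1)^n h[n] and the
orthonormal Haar pair h = [1, 1]/sqrt(2), g = [-1, 1]/sqrt(2). Boundary
handling is periodic, which makes the transform exactly orthonormal on
power-of-two lengths; energy conservation (Parseval) is verified to
1e-9 relative in the tests. The global sign of g is immaterial because
all features use absolute coefficient values. Note one indexing subtlety:
the `2k - n` convention pairs samples (2k-1, 2k), whereas PyWavelets'
periodization mode pairs (2k, 2k+1); the test suite cross-checks our
transform against PyWavelets through the resulting circular-shift
identity rather than by changing the convention.

Analysis windows are 2^13 = 8192 samples (5.46 min, the smallest power of
two covering 5 min at 25 Hz), giving a maximum depth N = 13; trailing
partial windows are dropped, not zero-padded, because padding would leak
into the low-frequency levels the features live in. Detail level i covers
[fs/2^(i+1), fs/2^i]; level 9 at 25 Hz covers 0.0244-0.0488 Hz, the band
associated with the recurrence of apneic events.

Seven wavelet features summarize one recording: mean, variance, skewness,
kurtosis and maximum of the absolute level-9 coefficients; the level-9
energy `en_d9`; and the wavelet entropy `we`, the Shannon entropy (nats)
of the relative energy distribution across detail levels 1..N (the final
approximation is excluded; 0*ln 0 := 0; bounded by ln 13). Per-recording
aggregation pools absolute coefficients across segments for the moments
and maximum, sums level energies across segments before normalizing for
the entropy, and averages the per-segment level-9 energy so `en_d9` does
not scale with recording duration. Moment conventions everywhere:
population variance, skewness as the standardized third central moment,
kurtosis as the raw (non-excess) standardized fourth moment.

## Conventional features

`odi3` counts desaturations of at least 3% below a running baseline per
hour of artifact-free recording. The baseline at time t is the maximum of
the preceding 100 s of signal; an event is a maximal run at least 1%
below baseline that dips at least 3% below it somewhere, with duration
gates of 5-180 s against noise spikes and drifts. All thresholds are
keyword parameters. Note the baseline tracker itself truncates events
longer than the 100 s window, since the baseline decays onto the event.
Hour-based indices are denominated in valid recording time (sleep staging
is out of scope).

Time-domain features are the four moments of the valid samples. Spectral
features come from Welch's method (8192-sample Hamming window, 50%
overlap, 2^14-point DFT, one-sided density): the four moments and the
maximum of the PSD over bins whose centers lie in the closed band
[0.018, 0.050] Hz, plus the spectral entropy of the full one-sided
spectrum. The signal mean is retained before the PSD and the 0 Hz bin
participates in the entropy normalization; both behaviors are exposed as
toggles (`remove_mean`, `exclude_dc_from_entropy`). With the mean
retained, DC leakage through the Hamming window's sidelobes puts about
1e-4 of the DC peak into neighboring bins of the zero-padded grid — the
in-band power of a constant signal is "approximately zero" only in that
relative sense.

## Feature selection

Symmetrical uncertainty between discrete vectors,
SU = 2 IG(x|y) / (H(x) + H(y)) with IG(x|y) = H(x) - H(x|y), uses Shannon
entropies in nats from empirical joint frequencies; SU is defined as 0
when both entropies vanish. Continuous features are discretized into 10
equal-frequency bins (ties share the bin of their first occurrence),
re-estimated on each replicate's own data. The SU target is the binary
group (AHI >= 5), matching what the classifiers consume.

FCBF ranks features by SU with the target (ties broken by name for
determinism), then scans from the top, discarding any lower-ranked
feature that shares more information with a surviving higher-ranked one
than with the target; features with zero SU are never selected. The
bootstrap layer reruns FCBF on replicates resampled with replacement at
the subject level (one master seed spawns a substream per replicate);
features selected in strictly more than 50% of replicates form the
consensus subset.

**Consensus on synthetic cohorts.** On cohorts from this generator the
consensus subset is typically *empty*: one latent quantity (the planted
event rate) drives every informative feature, so pairwise SU among them
(0.5-0.9) always exceeds their SU with the binary target (capped at
2 ln2 / (ln10 + ln2) ≈ 0.47 by the entropy mismatch), FCBF keeps exactly
one survivor per replicate, and the survivor's identity jitters across
replicates. This is a property of single-latent synthetic data, not of
the algorithm; real cohorts, where features carry genuinely complementary
noise-limited information, yield stable multi-feature subsets. The
selection result reports the honest (possibly empty) subset; the study
driver then falls back to a single FCBF run on the whole optimization set
— the base method without its bootstrap stabilizer — so the classifier
stage always has features. Alternatives examined and rejected: fewer bins
(2-5) and a discretized-AHI target do not stabilize the consensus, and
2-bin discretization starts admitting pure-noise features.

## Classification and evaluation

Subjects are split 60/40 (stratified) into an optimization set — feature
selection and hyperparameter tuning via 10-fold stratified CV — and a
cross-validation set on which performance is estimated by stratified
5-fold CV: train on four folds (including any ROC cutoff estimation),
test on the held-out fold, average ± across-fold standard deviation.
Anything data-driven (z-scoring statistics, cutoffs, hyperparameters) is
computed from training-side data only; a sentinel test verifies that
corrupting held-out labels leaves fitted models bit-identical.

Models: logistic regression fitted by maximum likelihood (no penalty;
Newton-Cholesky, i.e. IRLS — on linearly separable synthetic folds the ML
optimum diverges and the solver falls back internally, which is expected
and harmless for prediction); soft-margin linear-kernel SVM with
regularization C; and a one-hidden-layer MLP with hyperbolic-tangent
hidden units, logistic outputs and weight-decay alpha, trained by L-BFGS
(any gradient-based optimizer with weight decay satisfies the contract;
500-iteration cap) from a seeded random initialization. Default tuning
grids: C over decades 1e-5..1e5; N_H in {2,3,5,8,12,20,30,50} and alpha
in {0, 0.5, 1, 2, 5, 10} sampling the ranges [2,50] and [0,10], with each
MLP grid point averaged over 10 initializations; ties resolve to the
smallest C, then smallest N_H, then smallest alpha. The study driver's
default operating point (SVM C = 1e3, MLP N_H = 5, alpha = 1) is the one
the original clinical study selected.

Single features are evaluated through the cutoff maximizing Youden's
J = Se + Sp - 1 over midpoints of distinct scores (ties to the lower
threshold; the direction — whether high values indicate disease — is
learned from training folds). Metrics: Se, Sp, PPV, NPV, Acc in percent;
LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp as ratios, reported infinite when a
denominator vanishes. Group differences use the two-sided tie-corrected
Mann-Whitney U test.

## Synthetic generator

Each recording is baseline + drift + noise - events, clipped to
[70, 100] and quantized to 0.01%:

- baseline: uniform 95-99% per subject;
- drift: 1% amplitude sinusoid, one cycle per hour, random phase;
- noise: Gaussian, sd 0.15%, drawn at 1 Hz and interpolated to 25 Hz —
  true white noise at 25 Hz would violate the 4 %/s artifact rule at
  almost every sample, which real (internally averaged) oximeters do not;
- events: a Poisson process at the subject's true rate places
  non-overlapping raised-cosine dips (fall over 30% of the duration,
  recovery over 70%), durations uniform 10-60 s, depths uniform 3-15%
  capped at 0.6 x duration so peak event slopes (~3.1 %/s) stay under the
  artifact threshold and preprocessing cannot erase planted truth.

Cohorts draw true rates log-uniformly: 0.5-4.5 e/h for the AHI < 5 group
and 5-30 e/h for the AHI >= 5 group (balanced by default), and label each
subject with the planted rate as its AHI — an idealization that equates
every respiratory event with a >= 3% desaturation, which real physiology
does not (ODI3 systematically undercounts AHI).

What the generator does *not* emulate, and the consequences: there is no
low-frequency physiological wander inside the detail bands — the drift
sits below the D13 band, in the final approximation, which the wavelet
entropy excludes. The no-event detail-energy base is therefore broadband
sensor noise (WE ≈ 1.7-2.0 nats), and planted events *concentrate* the
distribution into levels 8-11, so WE *decreases* with event rate here. On
clinical recordings the opposite holds: near-DC wander dominates a single
low level (WE of order 1e-4) and events spread energy upward, raising WE
in the diseased group. Passing tests on this generator therefore
demonstrate correct mechanics of the entropy, not its clinical
direction; the level-9 features (`m1_d9`, `max_d9`, `en_d9`) do
reproduce the clinical direction. Likewise the single-latent structure
makes all informative features near-redundant, which is what empties the
bootstrap consensus (above) and lets several single features classify
near-perfectly — so classifier-vs-single-feature comparisons on this
generator are much tighter than on real data.

## Numerical choices and degenerate inputs

Rounding is half away from zero (clinical display convention) for
bit-reproducibility. Zero-variance inputs make skewness/kurtosis NaN with
a warning; an all-constant signal makes WE undefined (error); SU of two
constant vectors is 0; an all-identical score vector yields a degenerate
ROC cutoff with a warning; division by zero in LR+/LR- reports infinity
with a `degenerate` flag. All stochastic steps (splits, folds, bootstrap,
MLP initialization, the generator) run from explicit seeds;
SeedSequence spawning keeps per-subject and per-replicate streams
independent and reproducible.

## Problem sizes used in the tests

ODI3 parameter recovery uses 20 seeded 8 h recordings per rate in
{2, 5, 10, 20} e/h (mean absolute recovery error ~0.1-0.4 e/h). The
end-to-end study uses 120 subjects at 8 h with 20 pure-noise decoy
features and 200 bootstrap replicates. The wavelet-energy monotonicity
property uses 2 h recordings, five seeds per rate. The whole suite runs
in about a minute on one CPU.

## Known limitations

EDF support is read-only and single-channel (the label containing "SpO2",
or an explicit channel); sleep staging, pulse-rate channels and
continuous-AHI regression are out of scope. ODI3's baseline and
termination rules follow the standard running-max convention but are one
of several in circulation; they are configurable. The synthetic cohort is
a mechanistic stand-in: it validates plumbing, invariants and parameter
recovery, not clinical performance.
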