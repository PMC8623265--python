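# Methods

`semgbench` implements an offline surface-EMG (sEMG) gesture-decoding
study on synthetic data: a generator that emulates the statistical
structure of a multi-day, multi-condition recording protocol, the
classic time-domain decoding pipeline, and an evaluation design that
quantifies how muscle fatigue, forearm angle and acquisition day
degrade decoding accuracy.

## The decoding pipeline

**Signals.** Four bipolar channels over the forearm muscles SFD, FCU,
ECRL and FE, sampled at 2000 Hz, bandpass filtered 20–500 Hz with a
4th-order Butterworth filter applied forward–backward (zero phase; the
analysis is offline, so no causality constraint applies and features
see no phase distortion). Each gesture trial is trimmed to its valid
interval before windowing: rested (class *a*) 5 s trials keep the
middle three seconds [1 s, 4 s); sustained fatigue (class *b*) 15 s
trials keep [12 s, 14 s), where fatigue is established. The wording
"12–14 s" admits a three-second reading; the half-open two-second
interval is the default and `trim_valid(class_b_window=(12, 15))`
selects the other. Windows are 400 ms long with a 50 ms step, indices
0-based, intervals half-open; windows never span a trim boundary.

**Features.** Per window and channel: root mean square (RMS), waveform
length (WL), thresholded zero crossings (ZC) and slope-sign changes
(SSC), giving 16 dimensions channel-major. ZC counts sample pairs with
a sign change whose amplitude step exceeds ε; SSC counts slope
reversals where at least one adjacent slope exceeds ε. ε = 20 in
signal units (mV-scale), an absolute noise guard: the generator's
amplitudes are calibrated so active channels sit well above it and the
rest gesture below it. Feature columns are min–max normalized with
parameters fit on training rows only; training columns land exactly in
[0, 1], test rows may fall outside; a constant training column maps to
0. Spectral fatigue indicators use a Welch PSD (Hann window, 512
samples, 50% overlap) and the mean power frequency
MPF = Σ f·P(f) / Σ P(f).

**Classifiers.** Both are implemented from first principles.

*LDA*: within-class scatter `Sw = Σ_i Σ_{x∈X_i} (x−μ_i)(x−μ_i)ᵀ` and
between-class scatter `Sb = Σ_i m_i (μ_i−μ)(μ_i−μ)ᵀ` define the
generalized eigenproblem `Sb w = λ Sw w`, solved on the symmetric pair
with a ridge `λI` on Sw (λ = 1e-6·trace(Sw)/d) for numerical safety.
The projection keeps eigenvectors of the largest non-zero eigenvalues
(relative threshold 1e-3 of the largest, at most n_classes − 1):
near-zero directions carry no class information and only inject noise.
Eigenvector signs are fixed (largest-magnitude component positive) so
fits are deterministic. Classification assigns the nearest projected
class mean (Euclidean); ties break to the first class in sorted label
order.

*PNN*: the radial layer stores every training row; a query's Euclidean
distances are scaled by the polarization factor b = 0.8326/σ (a query
at distance σ activates 0.5) and passed through exp(−(d·b)²); the
competition layer sums activations per class through the one-hot
indicator matrix T and takes the argmax. Activations are rescaled per
query by the nearest-exemplar distance before exponentiating — a
positive common factor that cannot change the argmax but keeps the
kernel finite at tiny σ, making the σ→0⁺ limit exactly
one-nearest-neighbour. Default σ = 0.3 on normalized features; 0.1 is
effectively 1-NN and noticeably less robust on this task, 1.0 tends
toward majority voting (small σ ⇔ large b ⇔ overfitting).

## The synthetic generator

No public recordings exist for this protocol, so the generator is a
first-class, tested component. The model is stationary bandlimited
Gaussian noise per channel — amplitude and spectrum fully determine
every statistic the pipeline consumes (RMS, WL, ZC, SSC, PSD, MPF),
so richer physiology (motor-unit action potentials, electrode
geometry, force levels) is deliberately out of scope.

**Gestures.** Eleven analyzed gestures plus a rest reference (RE,
excluded from classification). Each gesture is a fixed recruitment
pattern: a sparse 4-vector of per-channel gains (Dirichlet(0.8) draws,
unit-normalized, best-spread of 200 candidate sets by maximin pairwise
distance) scaled to a 250-unit amplitude, floor 8% of scale; RE sits
at 4% of scale per channel, strictly the smallest total. Spectral
bands are muscle-specific (centers ~100–140 Hz, widths ~55–75 Hz) with
only ±4 Hz / ±3 Hz gesture offsets: discrimination rests on *which
muscles* are recruited, as in real multi-muscle montages, not on
per-gesture spectra. A `separation` dial scales every template's
distance from the across-gesture mean; downstream accuracy increases
monotonically in it. Subjects add small deterministic jitter (5%
gains, 5 Hz centers) derived from their own seed.

**Trial-to-trial variability** (within a condition): common-mode
effort gain (lognormal, sd 0.08 — pressing harder raises all muscles
together), per-channel gain residual (0.04), common-mode spectral
scale (0.06 — conduction-velocity variation moves the whole spectrum),
per-channel center wobble (6 Hz), and a muscle-state depth *v* along
the fatigue axis: rested trials draw v ~ N(0, 0.18), sustained trials
v ~ N(1, 0.20), each clipped symmetrically about its mean. The
effective per-trial amplitude gain is 1 + (α−1)v and frequency
compression 1 − (1−κ)v, so across-trial means are exactly α and κ for
class b and exactly 1 for class a. This common-mode structure is what
makes the classifiers realistically fatigue-tolerant: the within-class
scatter spans the directions fatigue shifts along, so LDA's whitening
discounts them.

**Condition effects** (all zero at zero condition gap):

- *Fatigue* (class b): amplitude × α, spectral band × κ. Defaults
  α = 1.4, κ = 0.7, calibrated so the synthetic RMS increase and MPF
  decrease fall inside the range real fatigue comparisons span. The
  generator reproduces only this dominant direction; occasional
  per-gesture sign reversals seen in real data are not modeled.
- *Forearm angle*: per-gesture gain perturbation 0.008/degree from the
  45° reference, plus channel cross-talk applied as the orthogonal
  rotation expm(c·A) with c = 0.016/degree above 30°. Rotations
  accumulate one-directionally with angle so the mismatch between two
  angles grows with their angular distance (a signed rotation about
  45° would make 30° and 75° near-transposes in energy space and break
  monotonicity).
- *Acquisition day*: gain drift 0.30 and rotation 0.65 per day gap
  (electrode repositioning between sessions is a spatial/gain
  phenomenon, so day effects act on gains and cross-talk, not on
  spectra). Day is deliberately the strongest factor, angle second,
  fatigue mildest — the default condition ordering of the study.

A bandlimited 20–500 Hz noise floor of 3 units is added per channel;
>95% of generated power lies inside 20–500 Hz, so the analysis
bandpass is nearly transparent.

**Determinism.** Every recording's randomness flows from one integer
seed through a `SeedSequence` spawn key on (subject, gesture, day,
fatigue, angle, group); identical arguments give bit-identical
signals, and any recording is reproducible in isolation. The gesture
templates and shift directions use fixed internal entropy independent
of the user seed — they are the study's stable "anatomy".

## Evaluation design

Eighteen dataset classes (3 days × 2 fatigue classes × 3 angles),
named `A_a_30` … `C_b_75`, each with five recording groups holding one
trial per gesture. No cross-validation: train and test are strictly
separated at the group level, asserted structurally on every run. Each
pairing is repeated (default 10×) with reshuffled group assignments —
train on the first ⌈n/2⌉ permuted groups, test on the rest — and the
mean over repetitions is the headline accuracy, computed per window
over the 11 analyzed gestures.

The four designs: MF (4 fatigue pairings at fixed day/angle), FA
(same-day 3×3 angle matrix, rested trials), AT (3×3 day matrix at
fixed angle, rested trials), and the combined design of 18 fixed
three-key models in categories AB_C / BC_A / CA_B (two training days,
one held-out test day). Non-varied factors are fixed at class a, 45°,
day A. For the combined design each model draws two of five groups
from each training key and tests each group of the test key in turn,
ten points per subject; with five or more subjects the best and worst
subjects by overall mean are dropped, leaving 30 points per model.
The published 18-row model table is reproduced verbatim, including its
sixth CA_B row which repeats `A_b_30` where the rotation pattern
suggests `A_a_30`; the row carries an `irregular` flag.

Per-subject consistency is summarized by a Pearson correlation between
each subject's accuracy vector over a design's pairings and the mean
vector of the remaining subjects (the exact variate behind the
published per-subject correlations is not specified; this convention
is ours). Degradation is reported as matched-condition minus
mismatched-condition mean accuracy.

## Problem sizes and numerical choices

Tests and the acceptance script run the study at reduced scale — one
subject with 2–4 groups for the single-factor designs, five subjects
with two groups for the combined design — chosen so the full suite
completes in a few minutes on one core while every qualitative
property (diagonal dominance, gap monotonicity, the day > angle >
fatigue ordering, chance-level nulls) is measured, not assumed. At
this scale a training split can contain a single trial per class, so
small-gap accuracy margins are noisy; the monotonicity checks
therefore use the train-anchored comparisons (30→75 vs 30→45, A→C vs
A→B) and aggregate diagonal dominance rather than a strict chain over
all gap means.

Other numerics: min–max rather than z-score normalization (bounded
inputs suit both the scatter estimation and the kernel distances);
window counts follow ⌊(T−L)/S⌋+1 with only complete windows emitted; a
recording shorter than one window yields an empty window list with a
logged warning rather than an error; degenerate spectral bands after
strong compression are clamped to [21, 499] Hz.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the analysis
assumes — amplitudes, spectra, their fatigue/angle/day shifts, and
trial-to-trial variability — so green tests demonstrate that the
pipeline is correct and that the study design behaves as described
under those assumptions. They do not certify performance on real
recordings: real sEMG is nonstationary within trials, fatigue can
reverse direction for individual gestures, electrode shifts are not
exactly orthogonal rotations, and between-subject variability is far
richer than seeded template jitter. Quantitative accuracies from the
original human study are functions of unreleased data and are not
reproduction targets; only their directions and orderings are.
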