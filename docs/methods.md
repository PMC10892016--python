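# Methods

`dmdgait` implements a single-sensor gait analysis for distinguishing
children with Duchenne muscular dystrophy (DMD) from typically
developing (TD) peers. The instrument is one triaxial accelerometer
worn at the waist near the body's center of mass, sampled at 100 Hz,
with axes x = vertical, y = mediolateral, z = anteroposterior. Each
child performs timed walking/running activities: five 25 m
speed-calibration efforts from slowest walk to run (SC-L1..SC-L5), a
six-minute walk test (6MWT), a 100 m fast walk/jog/run (100MRW), and a
free walk (FW).

## Gait clinical features

Eight scalar features are extracted per (participant, activity) session.
With course distance d (m), effort duration t (s), step count n,
standing height h (m), and body mass w (kg):

- **SP** (speed) = (d/t)/h, in fractions of height per second.
- **SF** (step frequency) = n/t, steps per second.
- **SL** (step length) = (d/n)/h, fraction of standing height.
- **TP** (total power) = Σ_axes ∫ S_a(f) df / w, where S_a is the
  one-sided PSD of the mean-removed acceleration of axis a over the
  full band [0, 50] Hz.
- **VP, MP, AP** = 100 · (∫ S_axis / w) / TP for the vertical,
  mediolateral, and anteroposterior axis respectively; they sum to 100
  whenever TP > 0.
- **FI** (force index) = (∫ S_z / w) / v̄, where v̄ = d/t is the
  *un-normalized* mean speed in m/s (FI is not height-normalized).

TP and FI are conventionally labeled W/kg and N/kg and printed with
1e-6 / 1e-3 scalings in cohort tables; internally both are exactly the
PSD-integral expressions above in (m/s²)² units divided by mass (and
speed). The scaling is presentation only.

Step counts come either from the accelerometer (peak detection) or from
the evaluator's manual count when recorded; the detector is the default
so the pipeline is self-contained.

### Step detection

The anteroposterior axis is mean-removed, low-pass filtered with a
4th-order Butterworth at 5 Hz applied forward-backward (zero phase,
unit DC gain), and peaks are counted — one peak per step, two steps per
gait cycle. Accepted peaks must be ≥ 0.2 s apart (cadence ceiling
5 steps/s, above the ~4.5 steps/s of the fastest runs) with prominence
≥ 0.3× the filtered signal's standard deviation. A flat signal yields
zero steps. On clean periodic signals the count is exact across
cadences 0.8–4.5 steps/s.

### Spectral estimation

One full-length boxcar periodogram of the mean-removed signal per axis
per activity (no Welch averaging — one spectrum per activity), one-sided,
normalized so the trapezoidal band integral over [0, Nyquist] equals the
time-domain variance (Parseval, verified to <1%). Mean removal takes out
the gravity bias on the vertical axis, so the features are insensitive
to whether the device reports raw or gravity-compensated acceleration.
The working band is [0, 50] Hz, the Nyquist limit at 100 Hz sampling.

## Classification

Both branches are evaluated with leave-one-subject-out (LOSO)
cross-validation: every fold fits *everything* — feature scaler,
projection, classifier, CNN normalization statistics — on the other
participants only and predicts the held-out child. The training-fold
membership of every fold is recorded on the result object and asserted
disjoint from the held-out subject.

### CML-CF branch

Six classical classifiers (random forest with 100 trees, decision tree,
RBF SVM, 5-nearest-neighbors, Gaussian naive Bayes, L2 logistic
regression) operate on the eight features, optionally after projection
to two principal components (PCA) or one discriminant coordinate (LDA).
Choices worth noting:

- **Standardization** (z-score, training statistics only) precedes
  everything: the features span six orders of magnitude and the
  scale-sensitive classifiers and PCA need commensurate inputs.
- **Balanced class handling.** The cohort is a balanced 15+15 design,
  but a LOSO training fold is always 14-vs-15. Class priors/weights are
  therefore pinned to 0.5 everywhere (LDA and GNB priors, balanced class
  weights elsewhere). Without this, the fold imbalance alone tilts
  predictions *against* the held-out subject's class and drags
  null-data accuracy measurably below chance.
- **LDA regularization**: within-class scatter is ridge-shrunk
  (coefficient 1e-4) for stability on 29-row folds; constant features
  are dropped before projection (they make the scatter spuriously
  invertible along null directions).
- **Sign convention**: the 1-D LDA axis is oriented so the DMD class
  mean is positive.
- **Pooled ("ALL") mode**: each participant contributes one row per
  activity; the subject-level call is the majority vote over their row
  predictions (ties to DMD).
- Hyperparameters are library defaults, declared in the configuration;
  no tuning is performed.

### DL-RAW branch

The raw triaxial signal is sliced into fixed, non-overlapping time
windows (0.3/0.5/1/1.5/2/2.5 s = 30–250 samples at 100 Hz; trailing
remainder discarded). A small 1-D CNN classifies each window; the
subject-level label is the majority vote over the subject's windows,
with frac_DMD ≥ 0.5 resolving to DMD (a screening posture favors
sensitivity).

The network is implemented directly in numpy: two convolution blocks
(16 then 32 filters, kernel 5, ReLU, max-pool 2), global average
pooling, and a 2-way softmax, trained with Adam (lr 1e-3, batch 64,
≤ 30 epochs with early stop on a training-loss plateau). Inputs are
standardized per channel with training-fold statistics. Training is
deterministic given the seed. The architecture is deliberately tiny —
a few thousand parameters — sized for CPU training on cohort-scale
window sets (hundreds of windows per fold) in seconds.

## Cohort statistics

- Group means per feature per activity are compared with plain
  two-tailed Student t-tests (Welch available via flag), flagged at
  p < 0.05 with *no* multiplicity adjustment — descriptive reporting,
  not model selection. Two identical constant groups return p = 1 by
  convention.
- Projection scores (PC1/PC2/LDA) are correlated with the eight
  features (Pearson) and with the ordinal NSAA score (Spearman);
  p-values are Bonferroni-multiplied by the family size of one
  component-activity row (8 features + NSAA, m = 9) and capped at 1.
  The per-row family is a declared choice; constant series yield
  flagged NaN cells rather than spurious values.
- NSAA severity bands: near-TD ≥ 30, mild 20–29, moderate 10–19,
  severe < 10 — an exhaustive, disjoint partition of 0–34.
- The community-mobility projection turns a daily step count, height,
  and relative step length into daily distance:
  step_length_cm = sl_fraction × height_cm,
  daily_distance_m = steps × step_length_cm / 100. Reduction
  percentages versus a reference scenario are *truncated* to one
  decimal, matching the conventional presentation of these numbers
  (704/4928 → 14.2%, not 14.3%).

## Synthetic cohorts

Human gait recordings from clinical cohorts are access-restricted, so
the package ships a generator that reproduces exactly the statistical
structure this analysis consumes — peak trains and power spectra — and
nothing more.

**Signal model.** Each axis is a sum of a few cosine harmonics of the
step frequency with 1/k² amplitude decay and aligned phases (the sum is
then single-peaked per period, so step counts on clean signals are
exact). The anteroposterior and vertical axes carry their fundamental
at the step frequency; the mediolateral axis has a half-cadence
fundamental, mimicking side-to-side sway that alternates with each
step. Axis amplitudes are solved so noise-free per-axis variance shares
equal the prescribed (VP, MP, AP) targets; white Gaussian noise
(default SD 0.1 m/s²) is added on top. Sessions span a whole number of
steps (duration snapped to the step period; distance = steps × step
length), so cadence and step-length identities hold exactly.

**Presets.** Per-activity, per-group (mean, SD) anchors for cadence,
step-length fraction, and axial shares are taken cell-by-cell from
published DMD/TD cohort summaries of these eight activities; base
amplitudes are plausible waist-level accelerations growing with gait
speed, with the between-group amplitude ratio anchored to the published
total-power ratios (the absolute printed power scale is not recoverable
into m/s² because its normalization is undocumented). Anthropometrics
are drawn uniformly from the published min–max ranges per group.

**Severity coupling.** DMD parameter draws are tied to the child's NSAA
score: severity s = (34 − NSAA)/26, contrast multiplier 0.6 + 0.8·s.
The multiplier averages 1 over the modeled NSAA range (8–34), so group
means match the anchors, while near-ceiling children retain 60% of the
mean contrast — consistent with the clinical observation that even
near-TD DMD children show measurably shortened steps. The preset SD is
treated as a marginal: the severity axis absorbs its share and the rest
is residual between-subject variation (floored at 30% of the preset
SD). This makes severity-band step-length summaries come out ordered,
as they do clinically.

**What the generator does not model** — and hence what passing tests do
not show about real data: gait-event sub-phases (heel strike/toe off,
double support), stride-to-stride variability and fatigue drift,
orientation error and sensor placement variation, non-harmonic
transients (turns at course ends), and any within-subject
session-to-session variability beyond white noise. Classification
results on synthetic cohorts validate the pipeline's mechanics, not the
clinical effect size.

**Null and strong-contrast presets.** The null preset equalizes both
gait parameters and anthropometric ranges across groups (body mass
divides the power features, so distinct weight ranges would be a real
label signal); only the labels differ. The strong-contrast preset sets
widely separated cadence and axial mixes with tight spreads, as a
sanity condition for the window-level CNN.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run cohorts of 15+15
subjects (single activity) or 2+2 subjects (all eight activities),
50-signal Parseval sweeps, 200-case step-detector sweeps, 20-replicate
null-cohort sweeps, and one 30-fold CNN LOSO at 1 s windows — the
package's own choice of desk-scale problem sizes. Degenerate inputs are
handled explicitly: all-constant signals count zero steps; zero total
power flags the axial percentages as undefined (NaN) rather than zero;
ties in majority votes go to DMD; sub-band PSD integrals interpolate
the density at band edges so band power is exactly additive.

## Known limitations

- The CNN architecture and optimizer settings are declared choices, not
  reconstructions of any reference network; no architecture search is
  performed.
- With Gaussian draws around the published group means/SDs, the two
  groups genuinely overlap; LOSO accuracy on default-preset cohorts
  plateaus around the low 0.9s at walking paces. Perfect separation
  requires either a stronger contrast or heavier-than-printed tails —
  see the strong-contrast preset.
- Pearson/Spearman p-values assume independent subject rows; the pooled
  "All" activity block violates this and is reported descriptively only.
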