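# Methods

`mentalload` classifies a driver's mental-workload state from two
psychophysiological channels recorded during simulated driving: facial
infrared thermography (mean intensity of the nose-tip and glabella regions
of interest, 10 Hz) and single-lead ECG (256 Hz). The workload state is
operationalised as the sub-phase of a cognitive test performed while
driving: Digit Span Test Forward vs. Backward (a 2-class problem) and Rey
Auditory Verbal Learning Test Immediate Recall / Delayed Recall /
Recognition (a 3-class problem). This note records the model, the
processing choices, and what the synthetic benchmark does and does not
establish.

## Signal processing

**Thermal chain.** Each ROI trace is despiked with a Hampel filter: for
every sample, the median and the scaled median absolute deviation
(1.4826 × MAD, the Gaussian-consistent dispersion) are computed over a
centred window of 15 s total width (150 samples at 10 Hz, truncated at the
series edges); samples deviating from the local median by more than 2
dispersions are replaced by it. Despiking runs *before* baseline
subtraction — the two commute up to a constant, but despiking first keeps
the baseline mean itself robust. The mean of the final 60 s before the
first task phase is then subtracted from every phase of the same channel
(one anchor per recording; no per-phase re-baselining). Nine descriptors
are computed per ROI per phase: mean, sample SD (n−1), non-excess kurtosis
and skewness as biased moment ratios (Gaussian kurtosis → 3), 90th
percentile (linear interpolation), sample entropy, and LF/HF band powers
plus their ratio.

The Hampel filter is not strictly idempotent on noisy data: replacing an
outlier shrinks the local MAD, so a second pass can flag points the first
did not. On smooth signals with isolated spikes it is a fixed point, and
the property tests exercise exactly that regime.

**Sample entropy.** SampEn(m, r) = −ln(A/B), with B the number of template
pairs of length m within Chebyshev distance r and A the corresponding count
at length m+1, self-matches excluded. Parameters are the field convention
m = 2, r = 0.2 × SD of the analysed segment. A constant segment returns 0
by convention; B = 0 yields a missing value rather than an error.

**Spectral estimation.** Power spectral density is a Welch averaged
periodogram: Hamming taper, segments of min(N, 60 s × fs) samples, 50%
overlap, per-segment linear detrend. LF = [0.04, 0.15] Hz and
HF = [0.15, 0.40] Hz band values are trapezoidal integrals divided by band
width (mean densities), with the band edges inserted into the integration
grid so coarse frequency grids cannot miss a band. When the post-detrend
power is at floating-point roundoff scale (integrated RMS below 1e−10 of
the signal scale) the spectrum is collapsed to exactly zero so LF/HF is
flagged undefined instead of being a ratio of machine noise.

**Cardiac chain.** ECG is band-pass filtered 0.05 Hz to min(150, 0.45·fs)
Hz — the upper edge is capped because 150 Hz exceeds the 128 Hz Nyquist
limit of 256 Hz sampling — plus a mains notch at 50 Hz (Q = 30), all
zero-phase. Because the 0.05 Hz corner period (20 s) dwarfs the reflective
padding of standard forward–backward filtering, the signal is demeaned and
zero-padded by two corner periods before filtering; without this, edge
transients of order the signal amplitude leak into the record. R peaks are
local maxima above mean + 2 SD of the whole-phase conditioned signal (a
global, per-phase threshold, which makes detection invariant to amplitude
scaling) separated by a 250 ms refractory period; positive R-wave polarity
is assumed. Six HRV descriptors per phase: RRmean, SDNN (sample SD of RR),
RMSSD, and LF/HF band powers of the tachogram after cubic-spline
resampling onto a uniform 4 Hz grid. Every task-phase HRV feature enters
the models as the ratio to the same feature over the baseline drive;
thermal features enter as baseline-subtracted values (two different
normalisations, each matched to its channel's drift structure).

## Feature tables and evaluation protocol

Each (subject, task phase) contributes one row; the class label is the
phase (Forward = 0 / Backward = 1; ImmR = 0 / DelR = 1 / Rec = 2), so a
complete cohort is exactly class-balanced. Three modality views are
assembled: unimodal IR (18 columns = 9 descriptors × 2 ROIs), unimodal HRV
(6), multimodal (24). Rows with any undefined value are dropped, never
imputed.

Sixteen classifier presets in six families (decision trees with max
4/20/100 splits; linear and pseudo-inverse quadratic discriminants;
logistic regression, 2-class only; SVM with linear/quadratic/cubic
polynomial kernels at box constraint 1; kNN with 100/10/1 neighbours;
ensembles of 30 learners — bagged trees, random-subspace discriminant,
random-subspace kNN, and boosted trees after random under-sampling) share
one train/predict/score contract. Scale-sensitive families are z-scored
inside the fit, on training rows only; tree ensembles are left unscaled.
The quadratic discriminant uses eigendecomposition pseudo-inverses for the
class covariances so tables wider than the per-class sample count still
fit. Whether the original analysis environment standardised features is
unknown; standardisation is this package's assumption and is confined to
the estimator pipeline so it cannot leak across CV folds.

Evaluation is subject-grouped k-fold CV (k = 5): subjects are shuffled and
dealt into k nearly equal test sets, so all rows of a subject are on one
side of every split and identity leakage is impossible (26 subjects give
test sets of 5–6 subjects, hence 21 training subjects for the 5-subject
folds). The protocol is repeated over independently shuffled fold plans
(default 20 repetitions) and the reported accuracy is the mean of the
pooled per-repetition accuracies. Wrapper feature selection draws 50
distinct random feature subsets (subset size uniform on 1..d, then uniform
within the size), scores each by grouped CV, and keeps the best; ties
prefer smaller subsets, then lexicographic order. Selection runs once per
model on the whole table (the flat scheme); a nested variant is possible
with the same machinery but flat is the default to mirror the original
protocol, and its known optimism is the user's to weigh.

Metrics are one-vs-rest per class: sensitivity, specificity, precision,
F1, ROC by threshold sweep, and AUC equal to the normalised Mann–Whitney
statistic (half credit for ties). Paired two-sided t-tests compare
behavioural scores between sub-phases and every feature between phase
pairs; feature comparisons are starred at raw p < 0.05 and p < 0.01, with
a Holm-adjusted column emitted separately because the raw two-level stars
perform no family-wise control.

## Synthetic cohort generator

The generator is the package's benchmark instrument, not a fixture. Per
subject it draws a thermal offset (SD 0.3 °C) and an RR offset (SD 40 ms),
then per phase builds:

* **thermal traces** = subject offset + phase level shift + LF (0.10 Hz)
  and HF (0.25 Hz) sinusoids + AR(1) noise (coefficient 0.9, innovation SD
  0.08 °C) + Poisson spike artifacts (2 per minute, amplitude 2 °C). The
  LF/HF modulation frequencies sit at the band centres so band-power
  recovery is analytically checkable. Default phase effects impose a
  nose-tip temperature *drop* under load, deeper for more demanding
  sub-phases (Forward −0.3, Backward −0.6, ImmR −0.3, DelR −0.7,
  Rec −0.15 °C; glabella roughly half), with LF amplitude rising and HF
  falling under load.
* **ECG** = Gaussian R waves (20 ms SD, unit amplitude) at beat times
  integrated from an RR train rr(t) = rr_mean(phase) + LF/HF sinusoids +
  per-beat jitter (SD 10 ms, floored at 250 ms), over AR(1) measurement
  noise with marginal SD 0.05. The noise is band-limited (coefficient
  0.99, i.e. baseline-wander-like) rather than white: white noise of that
  SD would make the R-wave apex ambiguous at the ±1-sample level, which no
  plain amplitude detector could resolve. Records start mid-cycle, as real
  recordings do. RR means shorten under load (BL 900 → DelR 780 ms).

Phase durations default to 900 s baseline and 120 s per task sub-phase —
each analysis window holds at least two LF cycles. One master seed spawns
independent per-subject, per-signal streams (keyed by channel and phase),
so enlarging a cohort never perturbs existing subjects. `null_mode`
replaces every per-phase parameter by its baseline value, making phases
exchangeable: the exact null for type-I-error and chance-level checks.
Behavioural scores are correlated Gaussians (correlation 0.6) with
normative-range means (DST span 6.5/5.5; RAVLT 50/11/13).

**What passing tests show — and what they do not.** The synthetic cohort
has Gaussian, stationary noise, perfectly synchronised channels, no motion
artifacts beyond isolated spikes, no ectopic beats, and phase effects that
are exact level/amplitude shifts. High classification accuracy on it
demonstrates that the pipeline recovers the structure it is designed to
recover and that the evaluation protocol is leak-free — not that real
drivers are classifiable at any particular accuracy. Chance-level results
on `null_mode` cohorts bound the protocol's optimism, not the field
difficulty of the task.

## Numerical and design choices

* Hampel window semantics: 15 s is the *total* centred window; dispersion
  is 1.4826 × MAD.
* R-peak thresholding uses the global per-phase SD (not a running SD).
* Tachogram resampling: cubic spline at 4 Hz, interval timed at its
  closing beat.
* Degenerate inputs produce missing values, not silent zeros: zero-variance
  skewness/kurtosis, SampEn with no template matches, LF/HF with zero HF,
  ratios over a zero baseline.
* Score ties in `predict_scores` break toward the lowest class index;
  wrapper ties toward smaller subsets, then lexicographic feature order.
* All randomness flows from explicit integer seeds (numpy `SeedSequence`
  spawning); two runs with the same configuration are bit-identical.
* Under a free label permutation, grouped CV on this balanced design is
  *negatively* biased (train/test imbalances anti-correlate), so the
  permutation null used in testing permutes labels within subject, which
  preserves fold balance and is the null matched to the protocol.

## Problem sizes used in the checked runs

Tests and the acceptance script run cohorts of 26 subjects at the default
durations; oracle-equivalence checks use 50 seeded series of up to a few
hundred samples; chance-level checks use 20 null-mode cohorts with 3
repetitions of 5-fold grouped CV per cohort; the R-peak recovery check
spans 20 cohort seeds (≈ 45,000 beats per cohort batch). These sizes give
sub-percent Monte-Carlo error on every asserted quantity.

## Known limitations

* No facial-landmark tracking or visible↔thermal registration: the
  pipeline starts from ROI traces (or ROI masks applied to frame stacks).
* No ectopic-beat correction; the 2-SD amplitude detector assumes a
  dominant positive R wave.
* No probability calibration; SVM multiclass scores are one-vs-rest vote
  margins, adequate for ranking (ROC) but not probabilistic.
* Flat wrapper selection reuses the same folds as evaluation and is
  therefore optimistic for the selected subset's reported accuracy.
* Logistic regression is restricted to 2-class tasks by design.
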