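# Methods

This note records the models, conventions, and design choices behind
`gammashift`, and what the synthetic-data studies do and do not
demonstrate about real recordings.

## Signal model and preprocessing

The recorded LFP is treated as a broadband 1/f-like voltage trace sampled
at 2000 Hz, contaminated by 60-Hz mains pickup and sparse high-amplitude
mechanical artifacts, with task-related oscillatory structure riding on
top. Preprocessing runs in a fixed order:

1. **Notch filter.** A zero-phase second-order IIR notch at 60 Hz
   (forward-backward application, −3 dB bandwidth 2 Hz per pass). This is
   a deliberate simplification of moving-window spectral line regression:
   it is deterministic, has no window-length parameters, and honors the
   same contract — a 60-Hz tone is attenuated by far more than 20 dB while
   50- and 70-Hz tones lose less than 1 dB and a 65-Hz tone less than 5%
   RMS (both properties are asserted by the test suite).
2. **Artifact masking.** Samples with |V − mean| > 3 SD, where mean and SD
   are computed once over the entire recording (not per trial, not
   iteratively). Flagged samples are *masked*, never deleted: deletion
   would shift sample indices relative to event timestamps. Masked samples
   are excluded from the RMS denominator and from every window average.
   On pure Gaussian noise the mask flags 2·Φ(−3) ≈ 0.27% of samples.
3. **RMS normalization.** The trace is divided by the RMS of its unmasked
   samples, making the unmasked RMS exactly 1. "Root-mean-square cleaning"
   could alternatively be read as rectification; that reading would
   destroy the oscillatory sign structure the wavelet transform needs, so
   normalization is the default and rectification is available as a flag
   (`preprocess(..., rectify=True)`), off by default.

Time is in seconds relative to the first LFP sample; all analysis windows
are half-open `[a, b)`.

## Wavelet power

Time-frequency power uses an analytic Morlet wavelet applied in the
frequency domain: H(f) = 2·exp(−(f−f₀)²/(2σ_f²)) on positive frequencies,
σ_f = f₀/n_cycles. The transform is **L1 (amplitude) normalized**: the
response of a unit-amplitude sinusoid at f₀ has magnitude 1, and its power
peaks exactly at f₀. This matters: L2-normalized constant-Q transforms
(the convention in several Python wavelet implementations) tilt the
response so the power peak of a pure tone lands ~1–1.5% below its true
frequency — a one-bin error on the 1-Hz grid used for band discovery. The
L1 convention matches the default of the MATLAB-family CWT tools common in
electrophysiology.

* **Cycles.** n_cycles(f) = clip(f/2, 3, 7). Above 14 Hz this is the
  classic 7-cycle Morlet (σ_f ≈ 9 Hz at 65 Hz — wide enough for robust
  single-trial power, narrow enough to separate 62–67 Hz from its
  neighbors). Below 14 Hz the count shrinks to 3 so that the wavelet
  support stays short at low frequencies.
* **Frequency grid.** Band analyses use a linear 1-Hz grid (1–200 Hz).
  A logarithmic grid (12 voices/octave) is available for heat maps, but
  it resolves only a single bin inside 62–67 Hz and cannot represent
  integer-Hz band edges, so it is not used for quantitative band power.
* **Edge handling.** Per-trial windows are extracted with symmetric
  padding chosen as max(0.25 s, 3σ_t at the lowest analysis frequency),
  so the wavelet support at every frequency fits inside the pad and no
  cone-of-influence bookkeeping is needed; segments at the recording edge
  are reflection-padded. The batched window engine works in single
  precision (power is averaged over thousands of samples; it agrees with
  the float64 full-session route to ~0.03%, asserted in tests).

**Normalization to A.U.** Every spectrum is divided, per frequency, by
the session-wide mean power in the baseline windows of all trials. This
makes baseline power ≈ 1 by construction and removes the 1/f background
from contrasts. Absolute A.U. values are not comparable across different
normalization conventions; only contrasts (choice vs baseline, correct vs
incorrect) are meaningful.

**Trial exclusion.** A trial is kept only if its start-to-dig latency
strictly exceeds 6 s; at exactly 6 s the baseline `[t_start, t_start+3)`
and choice `[t_dig−3, t_dig)` windows would abut with any jitter making
them overlap; the strict inequality avoids the overlap exactly. Excluded
trials stay in the table flagged `duration<6s` because the outcome
decoder deliberately uses all trials — it never compares against the
baseline window.

## Band discovery

For each correct trial, the peak frequency is the argmax over the 30–120
Hz gamma span of (trial choice-window power − mean incorrect choice-window
power), with ties broken toward the lower frequency. The comparison is
against the *mean* incorrect spectrum (trial-paired comparison would
require an arbitrary pairing). Frequencies strictly inside 58–62 Hz are
ineligible — the zone's endpoints remain eligible, since trials peaking
exactly at 58 Hz are informative — and candidate bands are integer-Hz
windows of 6 frequencies (e.g. [62, 67]) wholly outside the zone. The
selected band maximizes the count of per-trial peaks it contains, with the
integrated mean difference as tie-break, then the lower band; on fully
flat input the lowest admissible window is returned.

A caveat established during testing: the per-trial peak distribution under
the null is uniform only against a *noiseless* comparison spectrum. A
finite-sample incorrect mean is shared across all correct trials, so its
fluctuations bias every trial's argmax toward the same frequencies. The
selection step is therefore validated two ways: uniformity against the
exact null mean, and end-to-end recovery on simulated cohorts.

## Outcome decoder

Any monotone linear classifier on a single scalar feature is equivalent to
a direction and a threshold, so the decoder is exactly that: direction =
sign(mean correct − mean incorrect) on the training features; threshold =
the accuracy-maximizing cut on the projected feature, placed at the
midpoint of the optimal gap, lowest such threshold on ties. This replaces
a regularized linear-SVM fit with a deterministic, dependency-free
equivalent over the same hypothesis class. Training uses one random
class-balanced draw (5 + 5 by default); all remaining trials are tested.
If all training features coincide, the model degenerates to a seeded coin
flip (with a logged warning).

Significance is the one-sided upper-tail exact binomial probability
P(X ≥ k) with X ~ Bin(n, ½) — one-sided because a decoder performing
*below* chance (e.g. 31% accuracy, p ≈ 0.999) is reported as
non-significant rather than significant-in-reverse.

**Calibration caveat.** The Bin(n, ½) reference assumes each tested trial
is an independent fair coin. When the test set is class-imbalanced this
fails under the null: the trained threshold predicts "correct" with a
seed-dependent probability q, and accuracy ≈ p_maj·q + (1−p_maj)·(1−q)
is overdispersed across splits, making small p-values too frequent (with
a 62/17 class mix, the measured excess of the p-value ECDF over uniform
is ~0.45 across 500 null replicates). With a balanced test set, accuracy
is ½ regardless of q and the p-values are conservative, as the discrete
binomial tail should be. The calibration study therefore uses balanced
null cohorts; users applying the decoder to heavily imbalanced cohorts
should treat borderline p-values with caution.

## Behavioral scoring

A phase's criterion is met at the first trial t ≥ 10 such that at least 8
of trials t−9 … t are correct; the earliest possible completion is trial
10, and the count includes every trial up to and including the completing
one. An ED error is perseverative iff the chosen stimulus on the *old*
(IA) rule's dimension is the previously rewarded one; all other errors —
including 10-minute timeouts, where no choice exists — are random. Mean
latency averages over completed (non-timeout) trials. A session that hits
the configurable trial cap before criterion is flagged censored, not an
error.

## Group statistics

* **Unpaired t-tests** use pooled variance (not Welch). The pooled
  statistic depends on the data only through (mean, SEM, n) per group, so
  the summary-based and raw-data routes agree to machine precision; the
  reference behavioral p-values the acceptance suite recomputes (0.0021,
  0.0007) are reproduced by the pooled form and not by Welch.
* **Mixed model.** power ~ C(trial_type, baseline reference) [+ group]
  with a random intercept per animal, fit by REML (statsmodels MixedLM);
  contrasts (correct−baseline, incorrect−baseline, correct−incorrect) are
  Wald z tests from the fixed-effect covariance. The z reference (rather
  than a Satterthwaite t) is a choice; with ≥ 8 animals × 20 trials the
  simulation study measures ~95.5% CI coverage and |bias| < 0.01, so the
  large-sample approximation is adequate at these sizes. A singular fit
  (zero between-animal variance) falls back to OLS with a warning — in
  that limit the fixed-effect estimates coincide anyway.
* **Power analysis.** Smallest integer n per group reaching the target
  power of a two-sample t-test (noncentral-t, upward scan from n = 2).
  Sidedness is explicit: for the observed behavioral effect
  (Δ = 9.4 trials, SD 4.29) the one-sided convention gives 4 animals per
  group and the two-sided gives 5; the package reports the convention
  with the result rather than hiding it.

## Synthetic data

`generate_lfp_session` emulates exactly the statistical structure the
analysis assumes: 1/f^α background (spectral shaping of white noise,
α = 1 default, session SD 50 µV), a 60-Hz sinusoid (20 µV), Poisson
biphasic artifacts (2/min, 400 µV peak, 5–20 ms width — built to trip the
3-SD mask), and per-trial gamma bursts confined to [t_dig−3, t_dig):
amplitude-modulated band-limited noise in 62–67 Hz by default (a pure-tone
mode exists for oracle tests), scaled so the burst RMS equals amp/√2 with
amp = 30 µV for correct trials and 0 for incorrect. All draws flow from
one seeded generator, so identical configs are bit-identical. The default
trial latency distribution is uniform 8–60 s, typical of the task; the
recovery studies use 8–12 s latencies (the latency does not enter the
choice-window signal-to-noise ratio) and 100 trials per session to keep 50
replicates within a few CPU-minutes.

The in-band burst SNR of the default configuration — burst RMS over
background RMS inside 62–67 Hz, computed analytically from the pink
spectrum by `synth.band_snr` — is ≈ 5. Band recovery remains reliable in
single sessions down to SNR ≈ 1 (amp ≈ 6 µV at the default background)
with 100 trials; the recovery studies run well above that threshold.

What the generator does **not** model: spike trains, multi-channel
structure, non-stationary background (drowsiness, movement), harmonics of
line noise, or any coupling between behavior and LFP beyond the injected
burst. Passing recovery tests therefore show that the pipeline detects the
effect it targets under its own assumptions — not that real recordings
satisfy those assumptions.

The feature-level cohort generators (`generate_decoder_cohort`,
`generate_lmm_cohort`) sample band-power features and trial-level model
rows directly — Gaussian around known effects — because decoder
calibration and mixed-model recovery are properties of the statistics, not
of the voltage-domain simulation.

## Known limitations

* Absolute A.U. power is convention-dependent; only contrasts transfer
  across implementations.
* The binomial decoder test is anticonservative for imbalanced test sets
  (see above).
* The band search is not an oscillation detector: it has no 1/f-corrected
  peak fitting and will happily report a band on broadband power shifts.
* Wavelet power at frequencies below ~3 Hz inside 3-s windows averages
  less than one full cycle and should not be over-interpreted.
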