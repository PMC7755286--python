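# Methods

`freesacc` implements a single-trial decoding analysis for a delayed
oculomotor decision task recorded with stereotactic EEG (SEEG), together
with a synthetic-data generator that reproduces the task's statistical
structure. This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the simulation-based tests do and
do not establish about real data.

## Task model

Each trial presents a central cue for 250 ms: *Free* (choose a left or
right saccade target), *Instructed* (the cue dictates the direction), or
*Control* (no direction information until the go signal). The three types
are interleaved with equal probability (1/3). A delay of 3,750, 5,750 or
7,750 ms (equiprobable) separates the cue from the go signal (Cue 2), after
which the participant saccades; 1,500 ms of intertrial interval and 500 ms
of fixation precede the next cue. Trials are laid out on a sample clock
(default 1,024 Hz), so Cue 2 is exactly `250 ms + delay` after Cue 1 in
samples.

## Synthetic recordings

Each channel is

```
x(t) = b * n_1/f(t)  +  sum_k a_k * c_k(t) * g_k(t)
```

* `n_1/f` — Gaussian noise with power spectrum ~ 1/f^beta (beta = 1 by
  default), unit RMS, scaled by `broadband_scale` (default 1.0 a.u.). The
  source data place no constraints on the background model, so this is an
  assumption, exposed in `NoiseSpec`.
* `c_k` — band-limited Gaussian noise ("oscillation"/carrier) per
  configured band, unit RMS, amplitude `a_k` (defaults: alpha 0.5, high
  gamma 0.5). A broadband stochastic carrier, rather than a sinusoid, keeps
  the high-gamma (HG, 60–140 Hz) envelope realistic.
* `g_k` — multiplicative gain `1 + sum_e a_e * s_e(t)` from the effects
  configured on that channel, time-locked per trial to Cue 1 or Cue 2.

Effect shapes `s_e` (unit amplitude): **transient** — Gaussian bump
centered at the peak latency with sigma = duration/4; **sustained** —
plateau from onset for the stated duration with 100 ms raised-cosine edges;
**persistent** — plateau from onset to the go signal regardless of the
delay length; **execution** — go-locked ramp-plus-plateau whose per-trial
onset equals the trial's saccade latency plus N(0, 30 ms) jitter when
latencies exist (fixed onset otherwise). Because modulation is
multiplicative on the band carrier, the baseline-normalized envelope
recovered downstream equals the injected relative amplitude at high SNR,
which is what makes the generator usable as a parameter-recovery oracle.

The default effect map (8 channels) encodes the qualitative HG physiology
the analysis is designed to detect: five effect sites carrying an
Instructed transient (+39% peaking 475 ms after Cue 1, duration 600 ms) and
a Free sustained response (+24%, onset 400 ms, duration 1,100 ms); one of
the five is instead *persistent* in Free trials through the whole delay, so
the early/late conjunction finds many early-only sites and few
early-and-late sites. Channels 0–4 also carry a go-locked execution
response in all conditions. Three channels are null.

EOG synthesis draws per-trial saccade latencies from condition-specific
normals truncated at zero — Control 466 ± 66 ms, Free 334 ± 36 ms,
Instructed 321 ± 33 ms — and writes a ramp-then-plateau horizontal
deflection at Cue 2 + latency, signed by direction (L negative, R
positive). A configurable fraction of trials (default 25%) receives a
spontaneous delay-period deflection; together with the 750 ms
reaction-time cutoff this calibrates behavioral screening to retain roughly
75% of trials. Free-trial directions are drawn i.i.d. fair, so the
trial-history null holds by construction.

## Feature extraction

Bands: theta 4–8, alpha 8–15, beta 16–30, low gamma 30–60, HG 60–140 Hz.
Per band: zero-phase FIR band-pass, then the magnitude of the Hilbert
analytic signal, then mean envelope in sliding windows — 400 ms length,
50 ms step for classification; 60 ms / 10 ms for single-trial display
grids. Numerical decisions:

* The FIR order is "3 cycles of the band's lower edge" (a common
  toolbox convention for an order parameter of 3; a literal 3-tap band-pass
  cannot exist), applied forward–backward. One filter length at each edge
  is unreliable; the generator leaves 1 s of margin around the schedule.
* A stated window "overlap of 50 ms" is read as a 50 ms *hop* (windows
  overlap by 350 ms), which produces the smooth time-resolved decoding
  curves the analysis expects; a literal 50 ms overlap (350 ms hop) is
  available through the window parameters.
* "Power" is the envelope magnitude (matching relative-% scales);
  squared magnitude changes nothing downstream except scale.
* Windows are half-open `[t, t+L)` ms; the center is `t + L/2`; the
  window count over a span is `floor((span - L)/step) + 1`.
* Baseline normalization is `(x - b)/b` with `b` the mean over the
  [-500, -100) ms pre-cue rest window; trials with a degenerate baseline
  are flagged and set to NaN, never silently divided. Classification uses
  non-normalized power; normalized power serves visualization and dynamics
  metrics only.

## Decoding and inference

The classifier is a two-class linear discriminant with shrinkage-regularized
covariance. Univariate cells (one site x band x window) use a closed-form
implementation vectorized across all cells — for d = 1 the shrinkage target
equals the variance, so this is exactly the scikit-learn `lsqr`/Ledoit-Wolf
solution, and a test asserts prediction-level agreement. Multivariate cells
(multisite feature spaces, band subsets) call scikit-learn directly.
Shrinkage matters because the multisite feature dimension can approach the
trial count.

Cross-validation is stratified 10-fold (folds reduced, with a log note,
when a class has fewer than 10 trials); every trial is tested exactly once
and DA is the overall fraction correct. All cells share one seed-fixed fold
assignment, so window-to-window comparisons are paired.

Family-wise inference uses maximum statistics: each of the `n_perm = 100`
permutations shuffles the labels once, re-derives stratified folds, and
recomputes the complete (site x band x window) DA array; the null
distribution of the *global maximum* yields the threshold at its
`ceil((1-alpha)(n_perm+1))`-th order statistic (with alpha = 0.01 and 100
permutations: the largest null maximum). Reusing one shuffled labeling
across all cells is required for the maximum distribution to be valid.

Cross-temporal generalization fits per-fold classifiers at each training
window and applies them to that fold's *held-out* trials at every test
window, so off-diagonal cells are leakage-free and the diagonal equals the
multisite decoding of the same sites/band under the same seed. Each cell
aggregates one prediction per trial; significance uses the binomial
cumulative distribution at the total trial count: the threshold is the
smallest `k/n` with `P(X >= k) < alpha`, X ~ Binomial(n, 1/2).

Exhaustive band selection scores all 31 nonempty subsets of the five bands
per site, fitting on two thirds of trials and scoring on the stratified
held-out third, over the three disjoint validation thirds; one feature per
band (its mean power over the analysis span). Ties prefer the smaller
subset, then the earlier band order.

## Dynamics and behavior

Decoding onset is the first significant window center; duration is the
step times the *total* number of significant windows (non-contiguity
counts); the peak-DA latency is the argmax window. HG peak metrics take
the maximum of the baseline-normalized, trial-averaged envelope within a
search span (ties to the earliest window).

Per-trial HG onsets use the rule "first window starting a run of >= 2
consecutive bins more than 2 SD above baseline", with baseline statistics
from the same trial's pre-event rest window. The onset is reported at the
window's *start* when the window length is supplied — the crossing
happened somewhere inside the window, so the start is the only grid point
that bounds it — which is what makes one-step agreement with ground truth
attainable on a non-overlapping grid. Single-trial thresholding with a
same-trial SD estimate (~16 effective samples) occasionally false-alarms
early; this is an inherent cost of the per-trial rule and is quantified,
not hidden, by the onset study.

The saccade detector thresholds the causally smoothed EOG derivative at 3x
the SD of the pre-go derivative, sustained for 10 ms (the field's
"semiautomatic" practice is made fully automatic; there is no manual
adjustment step). Causal smoothing guarantees the detection is never
earlier than the event. RT comparisons equalize trial counts by
bootstrapping (n = 100) down to the smallest condition, applying an
unpaired two-tailed t test per bootstrap and reporting the median p
(mean available); across participants a paired t on participant means is
used. "Pearson's rank correlation" being self-contradictory, the
onset-latency correlation defaults to Pearson on raw values with Spearman
behind a flag.

The trial-history test computes the four n-1 conditional probabilities
P(L|L), P(L|R), P(R|L), P(R|R) and compares each against the permutation
null (n = 1,000 label permutations) at two-sided empirical quantiles of
alpha/2 per tail (alpha = 0.001); a preceding state that never occurs
yields missing conditionals.

Conjunction analysis flags sites significant in two contrasts with the
required effect directions (sign of the mean power difference over the
window) — significance anywhere within the interval counts, as the window
of first significance is not constrained to match across contrasts. The
early window is [0, 2000) ms after Cue 1 and the late window [-2000, 0) ms
before Cue 2, both configurable.

## Study conditions for the reproduction studies

`freesacc.studies` runs the acceptance-style end-to-end checks at problem
sizes chosen to complete in minutes on one CPU: 512 Hz sampling (valid for
the HG band), single short delays where the quantity under study does not
depend on delay length, 120–400 trials per corpus, 100 permutations, and
20 no-effect datasets for the family-wise-error calibration. Amplitude
recovery reads the group-average envelope normalized by the pooled
baseline (per-trial division adds a small Jensen bias) and searches the
peak near the injected latency (a global max over a long noisy curve is
biased upward by extreme-value selection).

## What the tests do and do not show

The generator reproduces the *statistical* structure the analysis assumes:
trial interleaving, condition-specific envelope dynamics on a 1/f
background, latency-locked execution responses, and behavioral screening
rates. It does not model epileptic waveforms, electrode geometry, volume
conduction, non-stationary noise, line artifacts, or inter-site
correlation structure. Passing the simulation studies therefore
demonstrates that the machinery is calibrated (correct false-positive
rates), unbiased where it claims to be (parameter recovery), and sensitive
to the designed effect dynamics — not that real SEEG data would yield any
particular effect sizes. Patient-level results depend on data that is not
publicly deposited, so printed group values serve here only as simulator
calibration defaults and direction checks.

## Known limitations

* The exact FIR design of the original analysis chain is not recoverable;
  only envelope-level behavior is testable, and the band filters at 512 Hz
  are broad enough that a strong HG effect can leak detectably into the
  low-gamma band's envelope.
* Whether trial counts were equalized between classes before LDA is
  unspecified; stratification alone is implemented.
* The binomial threshold uses the total held-out trial count (the
  per-fold alternative is not distinguishable from the source material).
* EDF export is not provided; the documented HDF5 container
  (`/signal`, `/fs`, `/labels`) is the interchange format, and EDF files
  can be read through `mne` when available.
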