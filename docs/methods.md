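# Methods

## Scope and model

`glomkit` analyzes odor-evoked calcium signals recorded from olfactory
receptor neuron (ORN) axon terminals in olfactory-bulb glomeruli, together
with the accompanying respiration and open-arena odor-localization
measurements. The imaging unit is the glomerulus: a region of interest
(ROI) whose pixel-averaged fluorescence F(t) reports the summed activity of
the ORN axons converging on it through a genetically encoded calcium
indicator (GCaMP-class, slow kinetics).

The analysis chain is:

1. **dF/F** — (F − F₀)/F₀ with F₀ the mean raw fluorescence over a
   pre-stimulus baseline window, computed per ROI and per trial.
2. **Bleach correction** — a single exponential a·exp(−t/τ) + c is fitted
   to a signal-free segment (blank-odor trials for multiphoton recordings,
   the baseline period for epifluorescence) and divided out after
   normalizing to its initial value. Division rather than subtraction keeps
   fractional signals unchanged. A non-convergent or non-physical fit
   (τ ≤ 0, decay crossing zero) leaves the trace uncorrected with a flagged
   status; a constant segment is recognized as the τ → ∞ branch and passes
   through untouched.
3. **Response amplitude** — the mean dF/F over the half-open window
   [onset, onset + 5 s), averaged (unweighted) over the 3–5 repeats of each
   odor. The glomerulus × odor matrix of these amplitudes feeds the
   threshold and sparseness stages.
4. **Responsiveness threshold** — candidate thresholds are the pooled
   unique amplitudes of glomerulus-odor pairs and blank-trial pairs; the
   selected threshold is the lowest candidate at which responses outnumber
   blank responses at least `target_ratio` : 1 (default 10:1), counting
   strictly above the candidate. Zero blanks above a candidate satisfies
   the criterion whenever at least one response remains. The full ROC curve
   and its trapezoidal area are computed and reported but play no role in
   selection. Strict inequality makes "lowest" well defined on tied data;
   multiplying all amplitudes by c > 0 scales the threshold by c.
5. **Kinetics** — per individual trial, never on repeat averages (repeat
   averaging blurs the respiration-locked onset). Rise time: first frame in
   the response window exceeding baseline mean + 3.5 baseline SD, to the
   window's maximum (earliest frame on ties). Decay: least-squares fit of
   a·exp(−(t − t_peak)/τ) + c from the peak; the offset c is included
   because traces need not return exactly to zero. Trials with no crossing,
   a peak before the crossing, or a failed/rising fit are excluded by
   status, with counts logged.
6. **Sparseness** — the Treves–Rolls ratio S(r) = (Σr/N)² / (Σr²/N),
   over glomeruli for one odor (population sparseness) or over odors for
   one glomerulus (lifetime sparseness). Negative amplitudes are clipped to
   zero first: the ratio is defined for non-negative activity and negative
   entries can push it outside [1/N, 1]. An all-zero vector is undefined
   and returns NaN. Optionally, amplitudes at or below the responsiveness
   threshold can be zeroed first (off by default).
7. **Respiration** — traces are band-pass filtered (0.5–15 Hz default,
   covering anesthetized ~1–3 Hz through fast awake breathing), peaks
   picked with SD-relative prominence (amplitude-invariant) and a 100 ms
   refractory period (caps the detectable rate at 10 Hz), then each event
   is snapped to the local maximum of the raw signal within half a
   refractory period — the zero-phase filter does not delay peaks but does
   skew asymmetric waveforms, and the snap restores sample accuracy. The
   summary statistic is the arithmetic mean of 1/interval over a 5-minute
   window. Circular mean and resultant length support phase comparisons
   between simultaneous recordings.
8. **Behavior** — tracking takes the centroid of the largest
   supra-threshold blob per frame (missing frames interpolated, flagged).
   Localization latency is the first sample at or after odor onset within
   1 cm of the active inlet; path length sums segments from onset to
   arrival; velocities average over the whole pre-onset baseline and over
   onset-to-arrival. The exclusion rule flags animals by starting distance;
   the default excludes starts closer than 10 cm to the source (a trial too
   easy to be informative), with the opposite direction selectable.
9. **Statistics** — two-sided Wilcoxon rank-sum (tie-corrected
   Mann–Whitney asymptotic form), sign-rank, two-sample Kolmogorov–Smirnov
   and Kruskal–Wallis tests with optional Bonferroni correction
   (p ← min(1, k·p)); a seeded percentile bootstrap on the difference of
   group means; and a four-parameter logistic (4PL) concentration-response
   fit, the standard dose-response sigmoid, fitted on the natural scale
   with positivity bounds on EC50 and the Hill slope.

## Synthetic data

No raw recordings accompany the study design this package serves, so the
`synthetic` module generates all inputs with complete ground truth, and
every estimator is validated by parameter recovery.

**Imaging.** A tuned glomerulus-odor trial is a linear ramp from zero at
odor onset to the pair's peak amplitude over `rise_interval` seconds,
followed by exponential decay with `decay_tau`. This is the simplest shape
on which both the 3.5-SD crossing and the decay constant are analytically
known. Tuning is Bernoulli per pair (`responder_fraction`, default 0.3)
with lognormal peak amplitudes (log-mean −2.3, log-SD 1.0, i.e. median
dF/F ≈ 0.10 with a heavy right tail) — chosen as a realistic sparse,
skewed tuning profile; the study design reports no raw amplitude
distributions, so these defaults serve estimator testability. Defaults
mirror the multiphoton configuration: 4 frames/s, 15 odors × 3 repeats,
5 s odor, 5 s baseline, 15 s gap, interleaved blank trials, additive white
Gaussian noise (SD 0.01 dF/F per ROI trace). Movie mode draws glomeruli as
non-overlapping ellipses (rejection-sampled) over a dim background, with
F(t) = F₀·exp(−t/bleach_tau)·(1 + transient) + pixel noise; trace mode
emits the transient directly and therefore carries no bleaching term.
Onsets can be jittered uniformly within a frame (`onset_jitter`) to dither
frame quantization in kinetics studies.

**Respiration.** Per-cycle instantaneous frequencies are drawn from
N(rate, jitter_cv·rate) (truncated at 20% of the mean) and inverted into
peak-to-peak intervals, so the ground-truth mean instantaneous frequency
is unbiased by construction. The waveform between inhalation peaks is an
asymmetric raised cosine (fall over 65% of the cycle, rise over 35%),
resembling a smooth thermocouple signal; the exact shape is not
analysis-relevant.

**Behavior.** A persistent random walk (heading diffusion scaled by
`tortuosity`, wall reflection) for the baseline and `approach_delay`
seconds after onset, then a biased walk toward the active inlet;
`tortuosity = 0` gives a straight approach whose arrival time is exact
geometry. The tracking renderer paints a Gaussian blob per position.

**What the generators do not emulate:** optics (PSF, out-of-focus light),
motion artifacts, neuropil contamination, shot noise, indicator
nonlinearity and saturation, respiration-locked response onsets, odor
plume dynamics. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to these
real-data effects.

## Numerical choices

- Time origin t = 0 at recording start; frames 0-based; second-valued
  windows are half-open [start, stop) and map to frames by floor.
- Exponential and 4PL fits use `scipy.optimize.curve_fit` with bounded
  parameters and data-driven initial guesses; failures are reported as
  statuses, never silently substituted.
- Peak ties resolve to the earliest frame; threshold comparisons are
  strict everywhere (responsiveness, ratio rule, exclusion cutoff).
- The rise-time estimator is frame-quantized: with a continuous onset the
  crossing snaps to the first frame after onset, giving a mean bias of
  about half a frame period (−0.12 s at 4 frames/s) relative to the
  designed onset-to-peak interval. Recovery is assessed at a one-frame
  tolerance.
- The bootstrap mean test uses the percentile rule
  p = (1 + #{|d* − d_obs| ≥ |d_obs|}) / (n_boot + 1). It is first-order
  accurate: measurably anticonservative for small groups (rejection ≈ 0.07
  at α = 0.05 with 20 samples/group) and calibrated within 0.05 ± 0.02 for
  groups of a few hundred, the regime of the quantities it is applied to
  here (hundreds of inter-breath intervals, thousands of glomerulus-odor
  pairs). Calibration is verified at 200 samples/group.
- Respiration recovery in the acceptance script averages three 5-minute
  traces per rate (≈480 breaths each), mirroring a per-group mean across
  animals; kinetics recovery uses 500 trials per condition. These sizes
  hold sampling error well below each stated tolerance.

## Known limitations

- Bleach correction assumes a single shared exponential per trace; spatially
  heterogeneous bleaching is not modeled.
- The ratio-rule threshold is global per dataset (as in the analysis it
  implements), not per odor.
- The 4PL fit can be weakly identified when the concentration range does
  not bracket the EC50; the fit status flags degenerate and decreasing
  cases but does not profile uncertainty.
- Tracking assumes a single animal and a unimodal intensity blob.
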