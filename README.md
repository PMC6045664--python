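# glomkit

Analysis of odor-evoked calcium signals in olfactory-bulb glomeruli, for
experimenters imaging olfactory receptor neuron (ORN) axon terminals with
genetically encoded calcium indicators — plus the respiration and
open-arena odor-localization analytics that accompany such experiments.
Because raw recordings of this kind are rarely shareable, the package also
ships seeded synthetic-data generators with complete ground truth, so every
estimator is validated by parameter recovery.

## What it computes

- **dF/F and bleach correction** — (F − F₀)/F₀ per ROI and trial, with a
  divisive single-exponential photobleaching correction fitted to blank
  trials (multiphoton) or the baseline period (epifluorescence).
- **Response amplitudes** — mean dF/F in the 5 s after odor onset,
  averaged over 3–5 repeats, into a glomerulus × odor matrix.
- **ROC-ratio responsiveness threshold** — the lowest candidate threshold
  at which glomerulus-odor responses outnumber blank-trial responses 10:1
  (counting strictly above the candidate), with the ROC curve and AUROC
  reported alongside.
- **Transient kinetics** — per single trial: rise time from the first
  3.5-SD baseline deviation to the response peak, and the decay constant
  from a single-exponential fit starting at the peak.
- **Sparseness** — the Treves–Rolls ratio S(r) = (Σᵢ rᵢ/N)² / (Σᵢ rᵢ²/N),
  across glomeruli for one odor (population sparseness, PSⱼ) and across
  odors for one glomerulus (lifetime sparseness, LSᵢ); S ∈ [1/N, 1], 1 for
  uniform activity, 1/N for a lone responder.
- **Respiration** — breath detection by band-pass filtering and
  sample-accurate peak picking; mean instantaneous frequency
  (1/inter-breath interval) over a 5-minute window; circular phase
  statistics.
- **Behavior** — arena tracking by blob centroid; odor-localization
  latency (first approach within 1 cm of the active inlet), path length,
  initial distance, pre/post-onset velocities, and a configurable
  starting-distance exclusion rule.
- **Statistics** — rank-sum / sign-rank / Kolmogorov–Smirnov /
  Kruskal–Wallis with Bonferroni correction, a seeded bootstrap test on
  the difference of group means, and a four-parameter logistic
  concentration-response fit.

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

```python
import numpy as np
from glomkit import imaging, kinetics, sparseness, synthetic, threshold

cfg = synthetic.SimImagingConfig(n_glomeruli=20, n_odors=15, n_repeats=3,
                                 blank_trials=5, seed=7)
traces, trials, truth = synthetic.generate_traces(cfg)

responses = imaging.build_response_table(traces, trials)
thr = threshold.select_threshold(responses.amplitude.ravel(),
                                 responses.blank_amplitudes.ravel())
counts, _ = imaging.count_responsive(responses, thr.threshold)
sp = sparseness.sparseness_summary(responses.amplitude, responses.odor_ids)

rts = []
for g in range(traces.n_rois):
    for k in range(traces.n_trials):
        if trials.loc[k, "is_blank"]:
            continue
        r = kinetics.analyze_trial(traces.dff[g, k], cfg.frame_rate,
                                   (0.0, 5.0), (5.0, cfg.trial_duration))
        if r.fit_status == "ok":
            rts.append((r.rise_time, r.decay_tau))
rts = np.array(rts)

print(f"threshold = {thr.threshold:.4f} dF/F  "
      f"(ratio {thr.achieved_ratio:.1f}, AUROC {thr.auroc:.3f})")
print(f"responsive glomeruli per odor: median {counts.median():.0f} "
      f"(range {counts.min()}-{counts.max()})")
print(f"population sparseness = {sp.mean_population_sparseness:.3f}, "
      f"lifetime = {sp.mean_lifetime_sparseness:.3f}")
print(f"kinetics over {len(rts)} trials: rise {rts[:,0].mean():.2f} s, "
      f"decay tau {rts[:,1].mean():.2f} s")
```

Output:

```
threshold = 0.0030 dF/F  (ratio 11.1, AUROC 0.660)
responsive glomeruli per odor: median 6 (range 2-10)
population sparseness = 0.179, lifetime = 0.200
kinetics over 301 trials: rise 1.43 s, decay tau 4.04 s
```

The threshold is the smallest amplitude at which tuned glomerulus-odor
pairs outnumber blank-trial "responses" better than 10:1 (here 11.1:1).
Sparseness near 0.18 reflects the sparse tuning built into the generator
(30% of pairs tuned, heavy-tailed amplitudes). The mean measured rise time
falls below the generator's designed 2.35 s onset-to-peak interval because
weak transients cross the 3.5-SD criterion late — a genuine property of
SD-threshold rise times at low signal-to-noise — and the mean decay
constant sits near its designed 4.74 s, pulled slightly by low-amplitude
fits that survive the status filter.

## Command line

```sh
glom simulate traces --seed 1 --out sim/            # synthetic dataset
glom simulate respiration --rate 1.6 --out resp/
glom analyze respiration --trace resp/respiration.csv --out resp/analysis
glom analyze threshold --responses amps.csv --blanks blanks.csv --out thr/
glom run --config run.yaml                          # end-to-end pipeline
```

Every pipeline stage persists its intermediates as CSV/JSON, so any stage
can be audited or re-run independently.

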