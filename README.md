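# contextwm

Simulation and analysis pipeline for studying how **episodic-memory context
reinstatement intrudes on working-memory maintenance**.

In the paradigm this package models, participants first learn sets of 12
words, each set bound to a picture context (a scene, or a face/scene shown
left or right of fixation). They then hold four same-context words over an
18-s unfilled delay. Episodic reinstatement of the encoding context during
the delay can re-activate the other words from that context — and that
intrusion is measurable three ways:

1. **Free recall** (behavioral): substitution errors are disproportionately
   *previous-trial targets* (4 of the 68 candidate nontarget words) and
   *same-context* words (8 of 68), relative to a bootstrap null in which
   errors are uniform draws from all 68 candidates.
2. **Delayed-nonmatch-to-sample (DNMS) reaction times**: after the delay, a
   probe word must be rejected ("mismatch") unless it is one of the four
   targets. *Lure* probes — same-context non-targets — are answered slower
   than *other-context* probes, visible in within-subject z-scored log RT
   (zRT).
3. **fMRI decoding**: an L2-regularized one-vs-rest logistic decoder
   (four independent units, face-left / face-right / scene-left /
   scene-right, probability outputs that do not sum to 1) is trained on a
   miniblock localizer and applied to the task. Trial-wise delay-period
   evidence for the probe's context predicts RT slowing in random-intercept
   mixed models:

   ```
   Model 1:  RT ~ 1 + TargetMemoryScore × TrialType                + (1 | Subject)
   Model 2:  RT ~ 1 + ProbeCtxEv_targets + ProbeCtxEv_delay
                    + ProbeCtxEv_probe                             + (1 | Subject)
   Model 3:  RT ~ 1 + ProbeCtxEv_delay × Overlap                   + (1 | Subject)
   ```

   where `Overlap` counts (learning-trial, target) co-presentations of the
   probe with the current targets during context learning (0–9), and
   `TargetMemoryScore` is the number of the 4 target words whose context
   the subject later identified correctly (0–4).

Because the behavioral cohorts of the original studies are not public, the
package ships a **synthetic-data generator** as first-class, tested code: a
latent per-trial *reinstatement trace* drives both the RT model and the
synthetic BOLD signal, so decoded evidence and behavior are coupled through
one latent quantity and planted couplings are recoverable end-to-end. Real
fMRI data (NIfTI + binary ROI mask + events TSV) can be fed through the
same decoding path (`contextwm.pipeline.analyze_real_data`).

## Layout

- `src/contextwm/` — the library: `design` (vocabularies, context sets,
  learning schedules, trial sequences, overlap), `behavior` (generative
  behavioral model), `bold` (pattern bank, HRF, localizer/task runs,
  high-pass), `recall` (scoring, error taxonomy, bootstrap null), `rt`
  (exclusions, zRT, contrasts, memory split), `mvpa` (decoder and evidence
  extraction), `models` (mixed models), `pipeline` + `io` (orchestration,
  seeds, serialization).
- `analysis/` — numbered drivers, one per analysis stage; each writes its
  tables under `results/` and prints what it found.
- `docs/methods.md` — the generative model, analysis conventions, numerical
  choices, and calibration details.

## Worked example

```bash
python analysis/03_exp2_rt_contrasts.py 0
```

prints (seed 0, 80 subjects × 60 trials, shipped defaults):

```
subjects excluded below 2/3 accuracy: 0

accuracy by probe type:
lure      95.38
other     93.88
target    95.12

mean zRT by probe type:
lure      0.098
other    -0.020
target   -0.080

paired contrasts on per-subject mean zRT:
       contrast       t  df      p  mean_diff
  lure_vs_other  3.3701  79 0.0012     0.1182
 lure_vs_target  5.5396  79 0.0000     0.1787
target_vs_other -1.7529  79 0.0835    -0.0605
```

Accuracy is near ceiling and flat across probe types, yet lure probes are
slower than both target and other-context probes by ~0.12–0.18 within-
subject SD units — the context-intrusion signature in a cohort whose only
"memory" is the planted reinstatement trace. The other drivers follow the
same pattern: `02` reproduces the recall-error bootstrap analysis, `04`
runs the full BOLD → decoding → mixed-model chain, `05` and `06` check
parameter recovery and type-I calibration.

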