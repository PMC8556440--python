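# renalpet

Synthetic-phantom feasibility pipeline for **dose-reduced
[<sup>18</sup>F]PSMA-1007 PET imaging of the renal cortex**.

PSMA (prostate-specific membrane antigen) is physiologically expressed in
the renal proximal tubules, so PSMA PET tracers accumulate strongly in
renal parenchyma.  That makes them candidates for functional renal
cortical imaging — the clinical domain of [<sup>99m</sup>Tc]Tc-DMSA
scintigraphy, which is mostly performed in children at very low
radiation doses.  Whether a PET protocol can compete hinges on three
questions this package's pipeline addresses quantitatively:

1. **When to image** — at which time point post-injection does the
   blood-corrected renal tissue concentration peak?
2. **How reproducible is split renal function** — the left renal uptake
   percentage, LRU% = 100·A<sub>L</sub>/(A<sub>L</sub>+A<sub>R</sub>),
   measured across repeated acquisitions and retrospectively rebinned
   frame durations?
3. **How far can the administered activity drop** — at constant
   activity × time (constant expected counts), prolonging a single-bed
   acquisition from 60 s to 15 min allows a 15-fold activity reduction;
   what pediatric effective dose does that imply?

The raw clinical images behind these questions are not public.
`renalpet` therefore couples the deterministic analyses (the pediatric
dose chain, the published per-patient summary table, packaged as a
fixture) with a **digital two-kidney phantom** whose simulated
acquisitions carry the statistical structure the analysis relies on:
tissue/blood kinetics with fluorine-18 decay, Poisson counting noise
scaling with activity × duration, binomial list-mode-style rebinning
(rebinned durations share events with their parent), Gaussian-blur
reconstruction surrogate, and segmentation boundary variability.  See
`docs/methods.md` for the model details and its limits.

Core quantities:

- `C_tissue = C_kidney/(1−v) − C_blood·v/(1−v)` with `v = V_blood/V_kidney = 0.25`
  (blood-corrected parenchymal concentration);
- per-patient LRU% median, sample SD, range and *delta max* (highest −
  lowest measurement);
- Kruskal–Wallis rank-sum tests on patient-median-normalized LRU% by
  acquisition duration and by time point, with Dunn's Bonferroni-corrected
  post-hoc comparisons;
- pediatric effective dose: 0.022 mSv/MBq (adult) × 4.9 (mean
  adult→1-year-old ratio of six <sup>18</sup>F tracers) = 0.11 mSv/MBq;
  4.0/15 = 0.27 MBq/kg; 0.3 mSv PET + 0.1 mSv CT = 0.4 mSv for a 10 kg
  one-year-old.

## Worked example

Run the full study replica (12 patients, 8 scans each, rebinned into 362
series) and the dose budget:

```bash
$ renalpet run-study --outdir study_out --seed 1
362 series; median delta max 2.8%; KW p (duration) 0.9252; KW p (time p.i.) 1.465e-10
outputs in study_out

$ renalpet dose
conversion factor (adult -> 1-year-old): 4.9
pediatric dose coefficient: 0.11 mSv/MBq
activity reduction factor: 15
reduced administered activity: 0.27 MBq/kg
injected activity: 2.7 MBq
PET effective dose: 0.3 mSv
CT effective dose: 0.1 mSv
total effective dose: 0.4 mSv
total without CT: 0.3 mSv
```

Reading the study line: the simulated cohort yields 362 analyzable
series (two patients' 2 h list-mode rebins are lost, as in the study
design); the median per-patient delta max of 2.8 percentage points says
repeated split-function measurements agree to within a few percent; the
Kruskal–Wallis p-values show no duration effect but a significant
time-point effect on *normalized* LRU% — segmentation variability and
early-time blood pool move the ratio over time, while rebinned durations
of the same acquisition share events and segmentation and so barely
differ.  `study_out/` contains the per-patient summary
(`patient_summaries.csv`, the analysis's central table), the long-format
LRU% table, normalized values, tissue-concentration and noise-vs-duration
curves, Dunn post-hoc comparisons, the statistics report and the dose
budget.

Library use mirrors the CLI:

```python
from renalpet import StudyConfig, run_study
result = run_study(StudyConfig(master_seed=1))
print(result.summaries[["patient_id", "median_lru", "sd_lru", "delta_max"]])
```

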