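# derplab

Difference-ERP (dERP) analysis of perceptual-reversal EEG, implemented as a
tested, configurable pipeline with a synthetic cohort generator standing in
for unreleased recordings.

The pipeline covers:

- **montage / ROIs** — a 32-channel extended 10-20 montage with a shipped
  electrode-adjacency table, and four built-in spatio-temporal regions of
  interest (RP, RN, PP, FN) for the reversal-related component chain.
- **synthetic data** (`derplab.synth`) — trial-level stimulus-locked EEG
  (500 Hz, −100..+800 ms) for a two-group cohort (meditators /
  non-meditators) × two experiments (passive / hold) × two conditions
  (reversal / stability). Components are Gaussian-in-time deflections with
  fixed topographies; reversal-only components survive the
  reversal-minus-stability subtraction. Noise is white + 1/f, with optional
  large artifact excursions. `paper_fixture()` ships the default cohort
  (12 + 15 subjects, published per-cell trial counts, FN planted in
  meditators only).
- **preprocessing** (`derplab.preprocess`) — offline re-referencing to the
  TP9/TP10 average, ±150 µV trial rejection (strict inequality), zero-phase
  25 Hz Butterworth low-pass, −60..+40 ms baseline correction.
- **averaging** (`derplab.derp`) — selective trial averaging to per-subject
  ERPs, reversal − stability difference traces, grand means.
- **component detection** (`derplab.detect`) — running one-sample t-tests
  against zero with a run-length presence criterion (p < 0.01 for ≥ 10
  consecutive samples = 20 ms at 500 Hz): confirmatory (any ROI electrode)
  and exploratory (two *adjacent* electrodes with time-overlapping runs)
  variants; ROI peak picking (largest strict interior local extremum, with
  whole-window-mean fallback).
- **group statistics** (`derplab.stats`) — mixed-design ANOVA (between:
  GROUP; within: EXPERIMENT, ELECTRODE) with partial η², optional
  Greenhouse-Geisser adjustment, Wilcoxon signed-rank post-hocs (exact null
  for n ≤ 25), Holm step-down correction with dual
  corrected/uncorrected reporting.
- **source clustering** (`derplab.sources`) — per-vertex one-sample
  t-tests, α-thresholding, and repeated k-means with explained-variance
  elbow selection per hemisphere (cutoff 0.95, ≤ 8 clusters/hemisphere) on
  arbitrary 3D point clouds.
- **I/O** — a minimal BrainVision (.vhdr/.vmrk/binary) reader/writer with
  marker-driven epoching (`derplab.brainvision`).

## CLI

```sh
derplab reproduce --seed 2019 --out results/run     # fixture end to end
derplab simulate  --out results/epochs              # write epoch sets
derplab stats     --out results/run                 # pipeline + text report
derplab sources   --field field.tsv --out clusters.tsv
derplab report    --results results/run             # figures
```

All verbs accept `--config config.yaml` (a full pipeline config, echoed
into every output directory for provenance) and `--seed`.

Output tables are TSV: trial bookkeeping (totals / after rejection / max /
min per group × experiment), presence verdicts per component × group ×
experiment, peak tables (one row per subject × electrode), ANOVA tables
(F, dfs, p, partial η²), and post-hoc contrasts with corrected and
uncorrected p side by side.

## Notes

- The published latency ANOVA degrees of freedom imply electrode-set sizes
  inconsistent with the published ROI table (e.g. 9 levels for a 6-electrode
  ROI); this package derives dfs from its own design and follows the ROI
  table.
- Single-trial noise magnitudes and between-subject jitters of the
  synthetic cohort are assumptions (no such values are published), tuned so
  that planted parameters are recovered at the published trial counts.
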