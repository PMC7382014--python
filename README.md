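# facetremor

Facial-landmark trajectory analysis for Parkinson-disease screening from
short expression videos. Starting from 106-point facial-landmark
sequences (pixel coordinates per frame), the package:

1. **normalizes** trajectories into a face-anchored, non-Cartesian
   coordinate system — origin at the midpoint of the inner eye corners,
   inner eye corners pinned at (±1, 0) and a nose anchor at (0, −1) —
   which cancels rigid head translation, rotation and uniform scale;
2. **extracts 8 features per key point** (848 per record): expression
   amplitude (x/y range and covariance of the relative coordinates, plus
   covariance of the absolute coordinates) and positional-jitter tremor
   statistics (`jitter_abs`, `jitter_ppq5`, `jitter_rap`, `jitter_ddp`)
   on the absolute coordinates;
3. **screens** each feature for a two-group difference (Welch's t-test
   by default) and counts significant key points per feature family at
   configurable alpha levels;
4. **compresses** features with LASSO (penalty sweep with downstream
   LR/SVM accuracy) and ranks key points by random-forest importance;
5. **classifies** records with LR / SVM / decision tree / random forest
   under subject-grouped stratified cross-validation, and with
   LSTM / simple-RNN sequence models on first-order differenced
   coordinate series (NumPy implementations, deterministic per seed).

No clinical data ships with the package; a synthetic cohort generator
(`facetremor.synthetic_faces`) produces landmark sequences with the
relevant statistical structure (group-dependent smile amplitude,
group-dependent white positional tremor, nuisance rigid head motion) so
every stage is testable offline.

## Command-line usage

Every stage is a subcommand of `facetremor`:

```bash
facetremor synth --seed 7 --out data/              # synthetic cohort
facetremor import --manifest m.csv --out data/     # Face++-dialect JSON / CSV import
facetremor normalize --manifest data/manifest.csv --out rel/ --basis per_frame
facetremor features  --manifest data/manifest.csv --out features.csv
facetremor screen    --features features.csv --alpha 0.05 --alpha 0.005 --out screen.csv
facetremor select    --features features.csv --grid default --out sweep.csv
facetremor classify  --features features.csv --algo lr,svm,dt,rf --folds 5 --seed 7 --out report.json
facetremor seqtrain  --manifest data/manifest.csv --arch lstm --seed 7 --report seq.json
facetremor run       --config run.yaml             # full pipeline, one YAML config
```

Records are long-format CSV landmark tables (`frame_index, point_name,
m, n`) listed in a manifest CSV (`subject_id, record_id, label,
frame_interval, path`); per-frame JSON detection results
(`{"landmark": {name: {"x": .., "y": ..}}}`) are accepted as an import
dialect. Labels are `PD` / `control`.

## Notes on methodology

- Covariance uses the population convention (divide by N).
- Jitter windows are fully interior; divisors are N−1 (`abs`), N−4
  (`ppq5`), N−2 (`rap`, `ddp`). Records shorter than 5 frames are
  rejected.
- Cross-validation is always grouped by subject: each subject's repeated
  records stay in one fold, since identity leakage across folds inflates
  accuracy substantially on per-subject repeated recordings.
- The significance screen treats records as test units by default
  (mirroring a per-record analysis); pass `--by-subject` /
  `aggregate_subjects=True` to use subject means, which respects
  independence.
- Synthetic tremor is white positional noise, not an explicit 4–6 Hz
  oscillation: at a 10 Hz frame rate physiological tremor is at/above
  the Nyquist frequency, and white noise is what the jitter statistics
  measure.
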