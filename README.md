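# thermovine

A tested pipeline for on-the-go estimation of grapevine stem water potential
(Ψ_stem) from canopy thermal imaging. Since no field dataset is public, the
package ships a first-class synthetic-campaign generator so every stage is
runnable and testable offline:

- **`thermovine.synth`** — synthetic vineyard campaigns: per-day weather with
  Tetens-based VPD, wet/dry reference temperatures, per-vine ground-truth
  Ψ_stem with a calibrated marginal distribution (mean ≈ −1.23 MPa,
  SD ≈ 0.298 MPa, range [−2.05, −0.40]), and rendered 320×256 thermal frames
  with sky / canopy / soil band structure.
- **`thermovine.geometry`** — acquisition arithmetic for a sideways-looking
  camera on a moving vehicle: per-frame ground coverage (1.07 m × 0.85 m at
  defaults), frames per 25 m replication (1080 at 5 km/h, 60 FPS), the
  non-overlap subsampling stride (46), the count of disjoint scenes (23) and
  the centred block covering the monitored middle plants (14).
- **`thermovine.thermal`** — ROI cropping, closed-interval [T_wet, T_dry]
  segmentation, per-frame mean/median/SD, the CWSI and I_g indices, and the
  per-vine feature table under two feature sets (`with_refs` includes
  segmentation + indices; `without_refs` never touches references).
- **`thermovine.forest`** — a from-scratch rotation-forest regressor over
  reduced-error-pruning regression trees (greedy variance-reduction growth,
  held-out-fold bottom-up pruning, per-group PCA rotations on bootstrap
  samples, JSON serialisation).
- **`thermovine.evaluate`** — the model-development protocol: balanced
  east+west global dataset, range- and date-stratified 80/20 split
  (252 → 200 train / 50 test), calibration, seeded 10-fold cross-validation,
  external prediction, R² (squared Pearson, with the coefficient-of-
  determination variant also reported) and RMSE, plus a slope-equality
  t-test between two observed-vs-predicted regressions.
- **`thermovine.pipeline` / `thermovine.cli`** — end-to-end orchestration
  from one YAML config and one master seed; 6 reports per run
  (east / west / global × both feature sets), byte-reproducible.

## CLI

```sh
thermovine geometry                           # print the derivation table
thermovine run --out out/ --seed 1            # full default campaign -> 6 reports
thermovine synth --out camp/ --seed 3         # frames + weather.csv + truth.csv
thermovine features --frames camp/frames --weather camp/weather.csv \
    --truth camp/truth.csv --feature-set with-refs --out features.csv
thermovine train --features features.csv --model-out model.json
thermovine evaluate --features features.csv --side all \
    --feature-set with-refs --seed 1 --out eval/
```

All commands accept `--config config.yaml` (see `RunConfig.to_yaml` for the
schema); exit code 2 flags validation errors.

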