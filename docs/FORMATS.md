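# On-disk format contract

All artifacts are plain TSV (tab-separated, header row, UTF-8) or JSON.
All indices on disk are 0-based. Floating-point values are written with
full precision and must be read back with round-trip parsing.

## Edge ordering

Every edge vector (windowed FC rows, centroid rows) lists the strict upper
triangle of the R × R matrix in row-major order:
(0,1), (0,2), …, (0,R−1), (1,2), …, (R−2,R−1); length E = R(R−1)/2.
Edge column headers are `e0 … e{E-1}` in this order.

## Files

- **Time series** `timeseries/<subject_id>.tsv` — header = ROI ids, one row
  per volume, T × R numeric body. ROI order must match the parcellation.
- **Motion trace** `motion/<subject_id>.tsv` — 6 numeric columns, no
  header: 3 translations (mm) then 3 rotations (radians), SPM realignment
  order; one row per volume.
- **Parcellation** `parcellation.tsv` — columns `roi_id`, `network`
  (∈ DMN, CCN, SMN, OCN), optional `x, y, z` MNI coordinates.
- **Manifest** `manifest.tsv` — columns `subject_id`, `group`
  (∈ NC, SCD, AD), `sex`, `age`, `education_years`, `fd_mean`, score
  columns (`composite_score` for synthetic cohorts). Subject ids unique.
- **Ground truth** `ground_truth.tsv` (synthetic only) — `subject_id`,
  `volume_index` (0-based), `state` (0-based raw generator state).
- **Windowed FC** — `window_start` (0-based volume index) then `e0 … e{E-1}`
  Fisher-z values; one row per window.
- **Centroids** `centroids_<scope>.tsv` — k rows × E edge columns, rows in
  raw fitting order; the accompanying `model_<scope>.json` carries `order`
  (raw index → strength rank), `strengths`, `k`, `n_init`, `cost` and the
  `config_hash`.
- **Assignments** `assignments.tsv` — `subject_id`, `window_index`
  (0-based), `ordered_label` (0 = low … k−1 = high).
- **State summaries** `state_summaries.tsv` — `subject_id`, `group`,
  `state` (name), `state_rank`, `occurrences`, `global_mean`,
  `dmn_mean`, `ccn_mean`, `smn_mean`, `ocn_mean`.
- **Stats report** `stats.json` — per state × measure: omnibus ANOVA and
  Bonferroni-adjusted pairwise tests; per state × measure × sample: partial
  correlations; plus `counts` (subjects_in = excluded_motion +
  excluded_states + analyzed), `selected_k`, `ratio_curves` and
  `config_hash`.
- **Config echo** `config.json` — the full pipeline configuration and its
  hash; every other JSON artifact of the run repeats the same hash.
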