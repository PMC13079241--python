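# mapsetrend

Trending analysis of single-wall automated MAPSE (mitral annular plane
systolic excursion) against manual global MAPSE, for deciding whether serial
MAPSE from one left-ventricular wall tracks global LV function.

The pipeline has five parts:

- **`mapsetrend.synthdata`** — synthetic annulus tracks (smooth
  raised-cosine excursion anchored at ECG R-waves, with configurable noise,
  detection dropouts and single-frame outliers), two-timepoint surgical
  cohorts of paired automated/manual measurements, and three-observer
  regional wall-motion (RWMA) ratings — all with explicit ground truth and
  single-seed reproducibility.
- **`mapsetrend.extraction`** — the automated post-detection algorithm:
  cycle segmentation between consecutive R-waves, end-diastole/end-systole
  identification, per-cycle MAPSE, three cycle-rejection rules
  (frame-to-frame jump > 5 mm, detection fraction < 60 %, misplaced
  end-diastolic anchor), recording-level aggregation (up to 5 cycles at
  baseline, up to 10 postoperatively) and feasibility rates.
- **`mapsetrend.trending`** — per-(patient, wall) paired changes of
  single-wall automated MAPSE vs manual global MAPSE, a central exclusion
  zone (half-width 1.8 mm, the least significant change), four-quadrant
  concordance rates with a 90 % adequacy convention, paired *t*
  comparisons of the deltas, and four-quadrant plots.
- **`mapsetrend.rwma`** — third-observer adjudication of wall-motion
  ratings, Cohen's kappa between the primary observers, classification of
  the four RWMA patterns (same/remote wall x persistent/dynamic) and
  pattern-stratified concordance.
- **`mapsetrend.io` / `mapsetrend.pipeline` / `mapsetrend.cli`** — CSV/JSON/YAML
  readers and writers with schema validation, the end-to-end driver and the
  JSON + Markdown report.

## CLI

```sh
# generate a synthetic cohort, ratings and demo annulus tracks
mapsetrend simulate --seed 1 --out run/

# cycle segmentation + QC + aggregation over a directory of track CSVs
mapsetrend extract --tracks run/tracks --out run/

# trending + RWMA analysis of a measurement table
mapsetrend analyze --cohort run/cohort.csv --ratings run/ratings.csv \
    --out run/ --lsc 1.8 --fig-format png

# everything in one go
mapsetrend all --seed 1 --out run/
```

`mapsetrend all` writes `cohort.csv`, `ratings.csv`, `tracks/`,
`track_measurements.csv`, `report.json`, `report.md`, `table2.csv` and three
four-quadrant figures (pooled, per wall, per RWMA pattern). A YAML config
(`--config`) can override any `track`/`cohort`/`extraction`/`analysis`
dataclass field; see `mapsetrend.io.load_config`.

## File formats

- cohort CSV: `patient_id, timepoint {pre_cpb, icu}, wall {anterior,
  inferior, lateral, septal}, method {auto, manual}, mapse_mm, n_cycles`
- ratings CSV: `patient_id, timepoint, wall, observer {obs1, obs2, obs3},
  rating {present, absent, indeterminate}`
- track CSV: `frame_index, time_s, long_pos_mm, detected` plus a JSON
  sidecar with `r_wave_times_s` and `fps`
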