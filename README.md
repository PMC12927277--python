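# pupilpipe

A stimulation-locked pupillometry analysis pipeline for binocular eye-tracking
studies of transcutaneous auricular vagus nerve stimulation (taVNS) versus
earlobe sham, with a realistic synthetic-data generator for calibration and
power studies.

The pipeline covers:

- **Synthetic study generator** (`pupilpipe.synthetic`) — binocular 1000 Hz
  pupil traces for a within-participant design (default: 94 participants ×
  2 conditions × 3 blocks × 15 pulses; 1 s pulse + 25 s interstimulus
  interval), with hippus, slow drift, blinks, occlusion dips, sensation
  ratings coupled to responsiveness, and an optional lateralized (right-eye,
  taVNS-locked) response component. Faster outcome-level and epoch-level
  generators serve Monte-Carlo studies.
- **Signal conditioning** (`pupilpipe.preprocess`) — per eye: blink detection
  from missing-sample runs (merge gaps < 0.25 s, pad ±150 ms), 6 Hz
  zero-phase 4th-order Butterworth low-pass with decimation to 100 Hz,
  linear interpolation, then a two-pass temporal-derivative artifact
  rejection (0.75 SD, then 3.5 SD of the first difference) using a 60 ms
  quiet-period rule to locate artifact boundaries, windows padded
  −150/+250 ms. Every applied window is recorded in a ledger.
- **Trials** (`pupilpipe.trials`) — segmentation into −1…+25 s epochs,
  percent-change baseline correction over [−1, 0) s, outcome extraction over
  0–5 s (max dilation, peak latency, trapezoid AUC) on the binocular mean,
  and exclusion rules (interpolated run > 1 s, or > 50% bad samples in
  either eye).
- **Inference** (`pupilpipe.inference`, `pupilpipe.lmm`) — effect-coded
  design (stimulation ±0.5, linear block, z-scored amplitude, /100-coded
  rating difference, order ±0.5), REML linear mixed models with random
  intercepts and stimulation/block slopes, Satterthwaite degrees of freedom,
  a convergence fallback ladder, time-resolved per-bin models with joint
  Benjamini–Hochberg FDR, responder classification, estimated marginal
  means, and Steiger's Z for dependent correlations.
- **Laterality** (`pupilpipe.laterality`) — per-bin across-trial Pearson
  correlation between the left and right eye, Fisher-z transformed, averaged
  over early (−1…1 s) and late (2…6 s) segments, and a Stimulation × Time
  mixed model: unilateral stimulation that drives one eye more than the
  other shows up as a negative interaction.

## Worked example

```python
import pupilpipe as pp

design = pp.StudyDesign(n_participants=8)           # 8 of the default 94
effects = pp.EffectSpec(seed=42, stimulation_effect=1.5)

# 1. simulate and condition each session, then segment into trials
groups = []
for raw, _ in pp.simulate_study(design, effects):
    clean = pp.preprocess_recording(raw)            # 100 Hz, flagged, ledger
    groups.append(pp.segment(clean))                # 90 epochs per session

# 2. one row per trial: outcomes + exclusion flags
table, report = pp.trial_table(groups)
n_exc = int(table["excluded"].sum())
print(pp.exclusion_summary(n_exc, len(table)))
# {'n_excluded': ..., 'n_total': 720, 'percent_excluded': ...}

# 3. main mixed model: stimulation effect on max dilation
meta = pp.study_meta_table(design, effects)
frame = pp.code_design(table, meta)
fit = pp.fit_main_model(frame)
print(fit.table[["term", "estimate", "se", "df", "p"]])

# 4. responders and marginal means along the rating difference
labels = pp.classify_responders(table)
emm = pp.estimate_marginal_means(fit, [-0.05, 0.0, 0.05])

# 5. binocular laterality: early/late left-right correlation model
from pupilpipe.laterality import laterality_table_from_epochs
for epochs in groups:
    for ep in epochs:
        if not ep.excluded:
            pp.baseline_correct(ep)
    pp.apply_exclusions(epochs)
lat = laterality_table_from_epochs(groups)
lat_fit = pp.fit_laterality_model(lat)
print(lat_fit.coef("stimulation:time"))             # negative when lateralized
```

## Command line

```sh
pupilpipe simulate --design design.toml --seed 7 --out raw/
pupilpipe preprocess --in raw/ --out clean/
pupilpipe outcomes --in clean/ --out trials.csv
pupilpipe fit --trials trials.csv --meta raw/meta.csv --out fits/
pupilpipe laterality --in clean/ --out lat/
```

`design.toml` / `--effects` / `--params` are TOML files whose keys mirror the
`StudyDesign`, `EffectSpec` and `PreprocessParams` dataclass fields.

## Reports and tests

`python scripts/acceptance.py --seed 7 --out report.json` runs the full-size
synthetic study through the pipeline plus Monte-Carlo calibration checks and
writes the main quantities as JSON. `python -m pytest` runs the test suite
(the R cross-checks against `lmerTest` are skipped when `Rscript` is not
available).

See `docs/methods.md` for the methodological choices and their rationale.
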