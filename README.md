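# consenslab

Consensus ground-truth activity labeling for older adults' wearable data.

The package builds per-minute activity labels by triangulating two
imperfect label sources collected in the wild — a thigh-worn sensor's
per-minute activity-second compositions and verbally reported activity
events — and uses the resulting consensus labels to benchmark a
third-party activity recognizer's confidence stream. It ships a synthetic
cohort generator that emulates all four input streams (thigh epochs,
verbal entries, recognizer confidences, smartwatch wear mask) so the whole
pipeline runs and is tested without any private study data.

## What it does

- **activity_scheme** — the 8-leaf hierarchical activity taxonomy
  (Lying, Sitting not/in transport, Standing, Low/Moderate/Vigorous
  Stepping, Cycling), mapping tables for the thigh-sensor and recognizer
  classes (shipped as an auditable JSON resource), and MET intensity
  categories.
- **thigh_epochs** — the >30 s per-minute majority rule: derives lying /
  sitting-not-in-transport / standing by aggregation and subtraction,
  refines stepping into intensity sub-labels by personalized cadence
  thresholds, excludes minutes without a strict 30 s majority.
- **cadence** — per-participant cadence histograms + KDE, automated
  peak/valley threshold estimation (2 peaks → θ_LM, 3 peaks → θ_LM and
  θ_MV), manual-threshold files (the reference deployment's values ship as
  a fixture), and an exertion-keyword audit.
- **verbal_events** — interval reconstruction for the ten time-cue styles
  (C1–C7 reconstructable, I1–I3 excluded), series-entry expansion with an
  accounting tally, exclusion accounting (no-time / no-label / both /
  not-worn), and projection onto the minute grid (≥30 s overlap rule).
- **consensus** — triangulation (consensus = thigh label when worn and the
  label is a member of the verbal label set), per-participant and
  per-activity shrinkage tables, singleton-only confusion matrix, report
  rendering.
- **benchmark** — one-vs-rest ROC, Youden-J-optimal thresholds, rank-based
  AUC per recognizer class against thigh-only / verbal-only / consensus
  label sources, and FP/FN cross-tabulations for IN_VEHICLE and STILL.
- **cohort** — the synthetic generator: semi-Markov truth timelines with
  overnight lying blocks, minute alternation channels with an analytic
  excluded-epoch rate, posture-confusion and verbal-confusion channels,
  the reference time-cue style mix, intensity-dependent under-reporting,
  and recognizer error modes (motorized-tool vehicle false positives,
  idle-vehicle misses, cycling with a still wrist). Deterministic under
  `(config, seed)` with per-participant substreams.

## CLI

```sh
consenslab simulate --seed 1 --outdir cohort/          # generate inputs
consenslab ingest-thigh --epochs cohort/thigh_epochs.csv \
    --thresholds thr.csv --out labeled.csv
consenslab thresholds --stepping cohort/thigh_epochs.csv --out thr.csv
consenslab reconstruct-verbal --events cohort/verbal_events.csv \
    --wear cohort/wear_mask.csv --out verbal_minutes.csv
consenslab consensus --thigh labeled.csv --verbal verbal_minutes.csv \
    --wear cohort/wear_mask.csv --outdir report/
consenslab run-all --seed 1 --outdir run/               # whole chain
consenslab simulate --print-defaults --outdir ignored   # config reference
```

`run-all` writes the shrinkage tables (`table5.csv`, `table6.csv`), the
confusion matrix, the AUC grid (`table8.csv`), the FP/FN cross-tab
(`table9.csv`), and a `summary.json` with provenance (seed, version,
input hashes).

## File formats

All inputs/outputs are plain CSV/JSON. Epoch CSV columns:
`participant_id, minute_start, sedentary_s, sitting_transport_s,
lying_primary_s, lying_secondary_s, upright_s, stepping_s, cycling_s,
steps, met`. Event CSV columns: `participant_id, report_time,
event_index, labels` (pipe-separated leaf names), `cue_style,
stated_start, stated_end, stated_duration_min, raw_text`. Wear mask:
`participant_id, minute_start, worn`. Recognizer confidences: one column
per class, values 0–100.
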