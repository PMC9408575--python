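# moodmap

Unsupervised classification and visualization of mood states from
psychometric scores and behavioral signals. The pipeline converts
seven-component mood scores into two T-scored indicators (TMD and F),
extracts behavioral features from gaze traces (heatmap extent `E`, saccade
count `S`) and facial-expression time series (smile-frame count `R` via a
recurrent SOM, expression-cluster count `G` via a growing hierarchical
SOM), fuses them into per-session feature vectors, and maps the sessions
with a from-scratch self-organizing map whose U-Matrix boundary field is
segmented into semantically labeled categories (positive / neutral /
negative).

Because the original subject data are not public, a first-class synthetic
data module generates cohorts, gaze traces, and smile tempo-cycle
sequences with ground truth, so every stage is testable end to end.

## Modules

| module | purpose |
| --- | --- |
| `moodmap.psychometrics` | component scores, TMD composite, T-score conversion, CSV I/O |
| `moodmap.som` | online SOM: BMU search, square shrinking neighborhood, linear decay |
| `moodmap.umatrix` | boundary-depth field, quantile segmentation, semantic labels |
| `moodmap.rsom` | recurrent SOM (15-unit chain), smile-frame extraction |
| `moodmap.ghsom` | growing hierarchical SOM over prototype vectors |
| `moodmap.features` | saccade detection, gaze heatmap/extent, Gabor frame features |
| `moodmap.synthetic` | seeded generators for cohorts, gaze, and smile sequences |
| `moodmap.pipeline` | fusion patterns (TMD_F / I / II / III), orchestration, artifacts |

## CLI

```bash
# write a synthetic 20-subject cohort (poms.csv, gaze/, faces/, gt.json)
moodmap simulate --out data/ --seed 1

# individual stages
moodmap score data/poms.csv --out points.csv
moodmap features data/gaze/A_1.csv
moodmap smiles data/faces/A_1.csv --epochs 50
moodmap ghsom prototypes.csv --t-m 0.08

# full pipeline: U-Matrix PNG/CSV, segmentation + report JSON, manifest
moodmap run data/ --pattern tmdf --seed 1 --out out/
moodmap run data/ --pattern iii --seed 1 --out out_iii/
```

Patterns: `tmdf` uses TMD and F only; `i` adds gaze features (E, S);
`ii` adds expression features (R, G); `iii` uses all six. All options can
also be given via `--config cfg.yaml` (keys mirror
`moodmap.pipeline.RunConfig`).

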