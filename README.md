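# seldi-nodal

A tested, reusable re-implementation of a SELDI-TOF-MS serum-proteomics
pipeline for discriminating node-positive from node-negative colorectal-cancer
patients:

- **Spectrum preprocessing** — morphological baseline subtraction, m/z
  windowing to 2,000–20,000 Da, total-ion-current normalization (cohort-mean
  target), in that fixed order.
- **Two-pass peak detection** — per-spectrum local maxima at S/N ≥ 3, kept
  when present in ≥ 20% of spectra, greedily clustered across spectra within a
  0.5% mass window, and completed into a full sample × cluster intensity
  matrix with a relaxed second-pass S/N of 2 (below-threshold fills flagged).
- **Univariate screening** — pooled-variance Student t tests per cluster
  (Welch optional), strict (p < 10⁻⁴) and reported (p < 0.05) screens, Pearson
  χ² rate comparison, and intra-/inter-assay CV quality control on replicate
  spectra.
- **Oblique classification trees** — CART with Gini impurity and
  linear-combination splits ("Σ cᵢ·xᵢ ≤ t routes left") found by cyclic
  coordinate descent with seeded random restarts and backward deletion;
  cost-complexity pruning chosen by stratified 10-fold CV with the 1-SE rule;
  variable importance scaled so the top feature scores 100. The published
  fixed two-splitter tree over m/z 3,104 / 3,781 / 5,867 / 7,970 / 9,290 ships
  as `published_tree()`.
- **Synthetic-spectrum generator** — since no raw spectra were ever deposited,
  a generator renders cohorts whose class-conditional peak intensities follow
  the published 22-peak table (plus 24 nuisance peaks to a 46-peak panel),
  with decaying baseline, additive noise, ~0.03% mass jitter and ~17%
  intensity CV, at the study's cohort sizes (70/75 training, 35/30 test).

## CLI

```sh
seldi-nodal simulate  --seed 1 --out-dir data/            # spectra + manifest
seldi-nodal simulate  --matrix-only --out-dir data/       # feature matrix only
seldi-nodal preprocess --in data/manifest.csv --out-dir processed/
seldi-nodal detect    --in processed/manifest.csv --out matrix.csv
seldi-nodal train     --matrix matrix.csv --out model.json
seldi-nodal predict   --model model.json --matrix matrix.csv --out preds.csv
seldi-nodal evaluate  --model model.json --matrix matrix.csv
seldi-nodal qc        --in replicate_manifest.csv --targets 3000-10000:3
seldi-nodal experiment --seed 1 --out-dir results/        # full end-to-end run
```

File formats are plain text: per-spectrum `mz,intensity` CSV (comma or tab on
input), a `sample_id,label,chip_id,path` manifest, matrix CSV with `mz_<m/z>`
columns, tree models as JSON, config as YAML (`--config cfg.yaml`; flags
override).

## Layout

```
src/seldi_nodal/
  spectra_io.py      data model, CSV/mzML/manifest/tree-model/config I/O
  synthetic_data.py  peak tables, generator configs, cohort/QC simulation
  preprocessing.py   baseline, windowing, TIC normalization
  peak_detection.py  noise estimation, detection, clustering, PeakMatrix
  univariate_stats.py  t/χ² tests, screening, replicate CV QC
  oblique_tree.py    split search, growing, pruning, importance, CV
  evaluation.py      metrics, experiment driver, reports
  cli.py             click command group
```
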