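# connload

Group statistics for structural brain connectomes:

- **Network-based statistics (NBS)** — edgewise two-sample t-scores on a
  shared 90-ROI scaffold, suprathreshold connected components, a
  permutation test on the largest-component *extent* (edge count), and a
  t-threshold sweep (0.05–5 in steps of 0.05).
- **Node abnormality** — per-subject edge z-scoring against control edge
  distributions (leave-one-out for controls), abnormal-edge masks, the
  per-node ratio of abnormal to total connections, and *abnormality load*
  (count of abnormal nodes) at whole-brain / lobe / per-ROI resolution over
  a (z, node-abnormality) threshold grid, with selection of the most
  discriminative threshold pair.
- **Estimation statistics** — Cohen *d* and AUROC with 95% BCa bootstrap
  confidence intervals (5000 resamples), one-tailed Wilcoxon rank-sum,
  Kruskal–Wallis, Benjamini–Hochberg FDR, and Yates-corrected chi-square
  tests for 2×2 demographics tables.
- **Synthetic cohorts** — a generator producing control and patient groups
  on a shared binary scaffold (constant density) with edge-specific
  truncated-normal weight distributions and injected edge-weight effects
  (localized vs widespread presets), returning full ground truth for
  recovery experiments.

Everything is deterministic given a seed.

## Data formats

- **Matrices**: plain delimited text (whitespace or comma), 90 rows ×
  90 columns, no header, row order = atlas ROI order. Symmetric, zero
  diagonal; an exact 0 means "no connection". All subjects of a cohort
  must share the same nonzero edge set (constant density).
- **Cohort manifest**: CSV with columns `subject_id, group, side`
  (groups `control`, `FBTCS-`, `FBTCS+`; sides `left`, `right`, `none`)
  plus optional demographics (`sex, age, hs, outcome`).
- **Atlas**: CSV with columns `roi, hemisphere, homologue, lobe`
  (a built-in 90-region atlas with alternating left/right homologue pairs
  and lobe sizes 18/14/26/14/12/6 is the default).

## CLI

```bash
# write a synthetic cohort (manifest + matrices + ground truth)
connload simulate --out-dir cohort/ --seed 1

# NBS: one patient group vs controls (single threshold or sweep)
connload nbs --manifest cohort/manifest.csv --matrix-dir cohort/ \
    --group FBTCS+ --threshold 3 --permutations 5000 --seed 0 --out-dir nbs_out/

# abnormality loads over the (z, ratio) grid, plus per-ROI profiles at one z
connload abnormality --manifest cohort/manifest.csv --matrix-dir cohort/ \
    --z 2.5 --out-dir abn_out/

# estimation statistics on a load table at one threshold pair
connload estimate --loads abn_out/loads.tsv --z 2.5 --ratio 0.05 --out est.json

# chi-square demographics tests from the manifest
connload demographics --manifest cohort/manifest.csv

# everything end to end (YAML config optional; defaults to synthetic presets)
connload run-full --out-dir report/ --seed 1
```

`run-full` executes both NBS contrasts, the three-group abnormality-load
comparison with threshold-pair selection and BCa estimation statistics,
and the per-ROI ipsilateral/contralateral comparison, writing
`report.json` and `roiwise.tsv` with a full provenance block.

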