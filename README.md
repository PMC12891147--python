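# olvf

Semi-quantitative vertebral fractural-deformity scoring and hip-fracture
screening-performance analysis for sex-stratified older cohorts, with a
latent-frailty synthetic cohort generator so the whole pipeline can be
exercised without clinical data.

## What it does

- **Morphometry** (`olvf.morphometry`): estimates per-vertebra fractional
  height loss from anterior/middle/posterior heights by interpolating the
  expected height from morphologically normal neighbours, and maps each
  finding to a seven-category extended semi-quantitative grade
  (none 0, minimal −0.5, mild −1, moderate −1.5, moderately severe −2,
  severe −2.5, collapsed −3) using closed-left height-loss bands
  (20%, 25%, 1/3, 40%, 2/3). Reader judgements enter as flags: minimal
  grade requires a fracture-like change; deformities wholly attributed to
  non-fracture causes score 0.
- **Sum score** (`olvf.scoring`): the OLVF sum score (OLVFss) over the 15
  levels T3–L5 with adjacency adjustments — a minimal deformity next to one
  scored ≤ −1.0 is ignored, and runs of k ≥ 2 adjacent minimal deformities
  contribute −0.5·ceil(k/2) — plus the most-severe-single-deformity metric
  (raw minimum score).
- **Classification** (`olvf.classification`): sex-specific baseline
  positivity metrics (women: FN T ≤ −2.7, LS T ≤ −3.7 / −2.5,
  OLVFss ≤ −1.5, most-severe = −3.0 / ≤ −2.5; men: FN T ≤ −2.1,
  LS T ≤ −2.5, OLVFss ≤ −2.0 / −2.5 / −3.0, most-severe ≤ −2.0 / −2.5 /
  = −3.0). Missing T-scores make a subject unevaluable for that metric.
- **Screening performance** (`olvf.performance`): analysis-set construction
  (deaths before the horizon without prior hip fracture excluded;
  fracture-then-death kept) and crude PPV, detection sensitivity,
  incidence and risk ratio (PPV/incidence) per metric and horizon.
- **Synthetic cohorts** (`olvf.cohort`): a single latent standard-normal
  frailty drives correlated BMD T-scores, Poisson deformity burden and
  logistic hip-fracture risk; `expected_summaries` gives model-implied
  operating characteristics by Gauss–Hermite quadrature (T-score metrics)
  or pilot simulation (OLVF metrics). Shipped configs: `female_default`,
  `male_default`, `null_association`.
- **I/O and CLI** (`olvf.io`, `olvf.cli`): CSV schemas for subjects,
  vertebrae, per-subject scores and performance tables; a click CLI.

## CLI

```sh
olvf simulate --config female_default --seed 7 \
    --subjects subjects.csv --vertebrae vertebrae.csv
olvf score    --subjects subjects.csv --vertebrae vertebrae.csv --out scores.csv
olvf evaluate --subjects subjects.csv --vertebrae vertebrae.csv \
    --horizon 3 --horizon 5 --out-dir out/
olvf report   --subjects subjects.csv --vertebrae vertebrae.csv --out-dir out/
```

`--metric name=quantity,cutpoint` overrides the built-in metric set
(quantities: `fn_tscore`, `ls_tscore`, `olvfss`, `most_severe_olvf`).
Outputs are deterministic: identical inputs give byte-identical
`performance.csv`.

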