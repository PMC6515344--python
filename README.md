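# circlin

Circular-to-linear ratio analysis of circular RNA (circRNA) dysregulation in
case/control cohorts, with myotonic dystrophy type 1 (DM1) muscle biopsies as
the motivating setting.

DM1 is caused by expanded CTG repeats in *DMPK* whose toxic transcripts
derail the alternative-splicing machinery. Because circRNAs are produced by
back-splicing — a non-colinear splice joining a downstream donor to an
upstream acceptor — a spliceopathy is expected to leave a trace in the ratio
of circular to linear transcript isoforms. `circlin` implements the
quantitative machinery needed to test that hypothesis and to evaluate the
resulting "circular-to-linear score" as a disease biomarker, for
bioinformaticians working with junction-level RNA-seq counts and qPCR Ct
tables.

## What it computes

**RNA-seq arm.** From CIRI2-style back-splice tables and linear
splice-junction counts (generic TSV or STAR `SJ.out.tab`):

- per-million normalization against library size and a *presence filter*
  (keep a back-splice event detected in ≥ 70 % of either study group);
- the per-sample circular-to-linear ratio of event *e* in sample *i*,

  `ratio(e, i) = bs_reads(e, i) / max{ linear junction reads sharing the
  donor or acceptor site of e }`,

  with explicit statuses instead of division by zero (`zero_circ`,
  `no_linear_partner` = circular-only, `both_zero`);
- candidate intersection against an external circRNA list (event- or
  gene-level ids).

**qPCR arm.** From long-format Ct tables:

- primer efficiency `10^(−1/slope)` from dilution series;
- comparative-Ct relative expression `2^−ΔΔCt` against averaged reference
  genes;
- the circular fraction per gene, `log2(circ/lin) = −(Ct_circ − Ct_lin)`;
- two-group tests gated by D'Agostino–Pearson normality (Student *t* vs
  Mann–Whitney) with the adaptive two-stage Benjamini–Krieger–Yekutieli FDR
  at Q = 1 %.

**Biomarker arm.** The per-sample circular-to-linear score (mean log2 fold
change over significant features, referenced to the control-group mean),
ROC/AUC via the Mann–Whitney pair-ordering statistic, Pearson correlation
with muscle strength (MRC megascore) and splicing covariates (percent exon
exclusion from gel band intensities), and a *t*-contrast across MIRS disease
stages.

**Synthetic cohorts.** A generator plants a fold change θ on the
circular-to-linear odds of selected genes in cases — graded by a latent
per-patient severity that also drives MRC, MIRS and splicing covariates —
on top of negative-binomial junction counts, and returns the ground truth
for recovery testing.

## Worked example

```sh
circlin run --seed 1 --out-dir demo_run
```

runs the full simulated pipeline (30 cases / 29 controls, 60 genes, 5
planted two-fold effects) and prints the report, which includes:

```
## qPCR arm
- circular fractions tested: 9
- significant at the FDR cut-off: 5

## Biomarker
- AUC[GENE0004] = 0.903
- AUC[GENE0033] = 0.890
- AUC[GENE0023] = 0.864
- AUC[GENE0058] = 0.840
- AUC[GENE0059] = 0.833
- AUC[circ_lin_score] = 0.998
- MIRS high (4-5) vs low (1-3) score means: 0.820 vs 0.592 (p = 0.00224)
```

All five planted genes are recovered at Q = 0.01; each individual circular
fraction discriminates cases from controls with AUC ≈ 0.83–0.90, the
combined score better still; the score falls with muscle strength
(r = −0.79 vs MRC in this run) and rises across MIRS stages. The same
library calls are available programmatically:

```python
from circlin import run_pipeline
results = run_pipeline(seed=1, out_dir="demo_run")
results["score_auc"], results["significant_features"]
```

Equivalent stage-wise subcommands: `circlin simulate`, `circlin quantify`
(CIRI2 + linear junction tables), `circlin qpcr` (Ct tables), and
`circlin biomarker`. Every run writes a `manifest.json` with the seed,
config snapshot and SHA-256 digests of all outputs; identical seed and
config reproduce every file byte for byte.

## Layout

- `circlin.io` — TSV dialects (CIRI2, STAR SJ, metadata, Ct, splicing) and
  round-trip-exact writers
- `circlin.quant` — normalization, presence filter, ratio matrix, candidate
  intersection
- `circlin.stats` — primer efficiency, ΔΔCt, circular fractions, group
  tests, two-stage FDR
- `circlin.biomarker` — score, ROC/AUC, correlations, exon-exclusion
  percentages, MIRS contrast
- `circlin.simulate` — synthetic cohorts with ground truth
- `circlin.pipeline` / `circlin.cli` — orchestration, manifest, report

See `docs/methods.md` for the model, parameter defaults and limitations.
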