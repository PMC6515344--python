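# Methods

## The circular-to-linear ratio

A back-splice junction read is evidence of a circRNA; a linear
splice-junction read is evidence of the colinear isoform. For a back-splice
event *e* (chromosome, first base `start`, last base `end`; 1-based
inclusive) the package compares its junction count in sample *i* against
every annotated linear junction that shares the event's donor site (the
`end` coordinate on the + strand, `start` on −) or acceptor site, on the
same chromosome and a compatible strand (`.` matches either orientation and,
for unstranded events, either donor/acceptor role). The partner is the
candidate with the **highest** read count, so the ratio compares two
like-for-like quantities — reads spanning one splice junction each — and is
robust to how many linear junctions a gene uses:

    ratio(e, i) = bs_count(e, i) / max_candidate_count(e, i)

Division by zero is never produced. A back-splice with no expressed linear
partner is biologically meaningful ("circular only") and carries status
`no_linear_partner`; `zero_circ` and `both_zero` cover the remaining
degenerate cells. Ties on the maximum leave the ratio unchanged; the
reported partner is deterministic (smallest donor, then acceptor position).
Because the ratio is a within-sample quotient, it is exactly invariant to
per-million library-size normalization — the pipeline still normalizes both
tables so that absolute abundances are comparable across samples, and
`normalize_linear_per_million` exists precisely to keep both sides of the
quotient on one scale.

The presence filter retains an event detected (raw count > 0) in at least
`min_fraction` (default 0.7) of the control group *or* of the case group.
The either/both reading of that rule is genuinely ambiguous in common usage,
so both are implemented (`mode="either"` default, `mode="both"` stricter).

## qPCR quantification

Ct values are cycle counts at threshold: one cycle ≈ one doubling, so Ct is
a native −log2 abundance scale. Three operations build on this:

* **Primer efficiency** — least-squares slope *m* of Ct against
  log10(template); amplification factor `10^(−1/m)`; 2.0 is perfect
  doubling, and slopes ≥ 0 are flagged invalid. Efficiencies are QC only;
  no Pfaffl-style correction is applied downstream because the assay
  design targets efficiency ≈ 2.
* **Relative expression** — ΔCt against the arithmetic mean of the
  reference-gene Cts per sample, ΔΔCt against the control-group mean ΔCt,
  expression `2^−ΔΔCt`. Exactly invariant to any global Ct shift.
  Replicates are averaged on the Ct scale before any Δ. A sample missing a
  reference gene is excluded entirely rather than patched.
* **Circular fraction** — `dCt = Ct_circ − Ct_lin` within one gene;
  `log2(circ/lin) = −dCt`. The linear isoform serves as the internal
  reference, so no housekeeping normalization enters; swapping the isoform
  labels negates the log2 fraction exactly.

## Differential testing

Per feature (a circular fraction or a relative expression), the two groups
are compared with a two-tailed test chosen by a normality gate: if both
groups have ≥ 8 observations and both pass the D'Agostino–Pearson omnibus
test at α = 0.05, an equal-variance Student *t* (Welch by flag); otherwise
Mann–Whitney. Groups below 8 fall straight to Mann–Whitney, since the
kurtosis component of the omnibus test is undefined there. The Mann–Whitney
branch is exact for tie-free samples up to n = 25 per group and otherwise
uses the tie-corrected normal approximation *without* continuity
correction — chosen so that identical samples yield p = 1 exactly rather
than an arbitrary sub-unit value. Group fold changes are differences of
group means on the log2 scale, which is the natural scale of dCt data.

Families of p-values are corrected with the adaptive two-stage
Benjamini–Krieger–Yekutieli procedure at Q = 0.01: stage 1 is
Benjamini–Hochberg at q′ = q/(1+q); its rejection count r₁ estimates the
true-null count m₀ = m − r₁; stage 2 reruns the step-up at q′·m/m₀ (nothing
is rejected when r₁ = 0, everything when m₀ = 0). The implementation is
independent of statsmodels' and is cross-checked against it in the tests.
Each analysis (expression, fractions) is treated as its own testing family.

## The biomarker score and its evaluation

The circular-to-linear score of sample *i* is the mean, over the
significantly modulated features, of `value(f, i) − mean(control values
of f)` on the log2 scale — i.e., a per-sample mean log2 fold change with a
geometric-mean reference on the linear scale. Controls therefore average to
zero by construction. The score is linear in the feature set: scoring a
union of disjoint sets gives the weighted mean of the subset scores.

Discrimination is summarized by the ROC curve over all observed thresholds
and the AUC computed as the Mann–Whitney statistic (ties get half credit),
making it exactly invariant under strictly monotone transforms of the
score and exactly complementary under label flips. The positive class is
the case group and higher scores predict case status; no polarity
auto-detection is performed. Pearson correlations carry the conventional
t-transform p-value (n − 2 df); zero-variance inputs are flagged undefined
rather than silently dropped. The MIRS contrast compares scores of mildly
staged cases (stages 1–3) against severely staged ones (4–5) with a
two-tailed *t*-test. Percent exon exclusion is `100·excl/(incl+excl)` from
gel band intensities; inclusion-type assays report the same exclusion axis
so all splicing covariates are directly comparable.

## Synthetic cohorts

The generator produces the data structure the analysis assumes, with ground
truth for recovery tests. Per gene *g*: baseline expression
e_g ~ LogNormal(log 50, 1) in reads-per-million; baseline circular share
f_g ~ Beta(2, 6) (mean 0.25 — roughly a third of events end up with a
circular-to-linear ratio above 0.5, a realistic proportion for muscle).
Per sample *i*: library size L_i ~ LogUniform(5, 20 million) reads — a
deliberately desk-scale depth, recorded in the truth object; deep
ribo-depleted libraries run an order of magnitude larger, which changes
count noise but not the structure of the analysis. Counts are negative
binomial with variance μ + α·μ² (α = 0.2, a typical biological dispersion);
the back-splice gets mean L_i·e_g·f·10⁻⁶ and the linear total, mean
L_i·e_g·(1−f)·10⁻⁶, is split across 2–4 linear junctions sharing the
event's donor or acceptor site by per-gene Dirichlet weights, so the
"highest expressed linear junction" rule faces a non-trivial but stable
choice. Circular and linear means sum to the gene's total by construction.

The planted effect multiplies the circular-to-linear **odds** f/(1−f) of
true-positive genes in cases by θ^(1−c+c·s_i), where s_i ~ Uniform(0, 1) is
a latent per-case severity and c ∈ [0, 1] the severity coupling. Since the
odds equal the circular-to-linear ratio, θ is an analytic target for the
ratio fold change (verified by Monte-Carlo recovery within [1.8, 2.2] at
θ = 2). Severity also drives the clinical covariates: MRC megascore
130 − 18·s + N(0, 3) clipped at the control baseline of 130 (controls sit
exactly at baseline, matching a healthy reference cohort with essentially
no strength deficit; case mean ≈ 121), MIRS stage by severity quartile
mapped to stages 2–5 (adult cohorts rarely contain stage 1), and percent
exon exclusion linear in severity with the implied band-intensity pair
emitted for round-trip testing.

qPCR Cts follow the same latent state: `Ct = 34 − log2(abundance) +
N(0, σ_ct)` with σ_ct = 0.35 cycles (typical replicate-averaged scatter;
chosen together with the effect sizes so that planted two-fold effects are
recoverable at Q = 1 % in a 30/29 cohort with realistic margins). Target
abundances are size_factor·e_g·f and size_factor·e_g·(1−f); reference
genes amplify at fixed levels times the shared per-sample size factor, so
reference-averaged ΔCt is exactly unbiased. All randomness derives from one
seed through per-table substreams, making every emitted table independently
reproducible byte for byte.

What the generator does *not* emulate — and hence what passing recovery
tests cannot show about patient data: shared biological variability of
circular fractions across genes within a subject (features are conditionally
independent given severity, so the combined score discriminates more
cleanly here — AUC ≈ 0.99 at the defaults — than single features,
AUC ≈ 0.83–0.90, would suggest for real cohorts); batch and RIN effects;
sex/age structure; CTG-repeat genetics; and any raw-read-level artifacts
(alignment, multi-mapping, back-splice false positives are upstream of the
consumed CIRI2 tables).

## Numerical and design choices

- Coordinates 1-based inclusive everywhere; STAR intron bounds are
  converted to exonic junction positions (donor = intron_start − 1,
  acceptor = intron_end + 1); STAR strand codes 0/1/2 map to `./+/−`; only
  uniquely mapped reads are counted.
- Duplicate back-splice rows in one CIRI2 file are summed with a warning;
  coordinate/id mismatches trust the coordinates.
- Missing Cts are dropped per record and never imputed; Ct values outside
  5–40 cycles are rejected as implausible.
- p-values are clipped to the smallest positive float so that downstream
  procedures see values in (0, 1].
- Default problem sizes (60 genes / 9-target qPCR panel in the pipeline;
  200-feature null and 55-feature power simulations at 25–50 seeds in the
  validation experiments) are chosen so the statistical claims are testable
  at desk scale while keeping full runs in the tens of seconds.
- Candidate intersection accepts gene-level ids (returning all back-splice
  isoforms of the gene) and event-level ids simultaneously, since curated
  circRNA lists mix both conventions.
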