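# oncopanel

Tumor-only genomic profiling for targeted cancer gene panels, built around
the analysis used for head-and-neck squamous cell carcinoma (HNSCC)
cohorts: copy-number calling from capture coverage, detection of allelic
imbalance and copy-neutral loss of heterozygosity (CN-LOH) from
heterozygous-SNP allele fractions, somatic variant filtering, gene-level
integration into biallelic-inactivation and actionability calls, and exact
per-gene mutation-frequency comparison between cohorts.  A synthetic-cohort
simulator with known ground truth makes every stage testable end to end.

## Who this is for

Anyone analyzing tumor-only targeted panels (no matched normal for most
samples) who needs CNV, LOH and mutation evidence merged per gene per
sample — and wants the pipeline's statistical machinery verifiable against
independent oracles rather than trusted blindly.

## The model

**Coverage.** For a genomic segment with total tumor copy number $C_T$ in a
sample of purity $p$, the expected coverage log-ratio against a diploid
pooled-normal reference is

$$\log_2\frac{p\,C_T + 2(1-p)}{2}.$$

Per-bin log-ratios (400 bp bins) are segmented per chromosome by circular
binary segmentation (CBS): the maximal two-sample $t$ statistic over all
circular arcs, split accepted when a permutation test gives
$p < \alpha = 0.01$, recursing into the pieces.  Segment means invert to
integer copy numbers (using purity when known) and map to copy states:
0 = deep deletion, 1 = shallow deletion, 2 = neutral, 3–4 = gain, ≥5 =
amplification.

**Allelic imbalance.** A germline heterozygous SNP with $m$ alternate
copies out of $C_T$ has expected variant allele fraction

$$\mathrm{VAF} = \frac{p\,m + (1-p)}{p\,C_T + 2(1-p)},$$

so its deviation $|\mathrm{VAF}-0.5|$ measures allelic imbalance (at CN-LOH
the expected deviation is $p/2$).  Informative SNPs (population allele
frequency strictly inside (0.0001, 0.95), depth > 30, observed VAF inside
homozygote-exclusion cutoffs) give a deviation series, segmented by the
same CBS; segments with mean deviation ≥ 0.15 are called imbalanced, and the
segment's copy number resolves the mechanism: CN-LOH (2 copies),
deletion-LOH (≤1) or imbalanced gain (≥3).  Matched normals add per-variant
VAF-shift support.

**Integration.** Filtered, classified mutations merge with copy states and
LOH per gene: deep deletion, two mutations, mutation + deletion/CN-LOH, and
amplification of the mutated allele (multiplicity estimate
$\hat m = \mathrm{VAF}\,(p\,C_T + 2(1-p))/p \ge 1.5$ at $C_T \ge 3$) are
biallelic mechanisms.  Actionability rules keep pathogenic/hotspot
mutations, deep deletions and amplifications to ≥5 copies, and drop shallow
deletions without a second hit.

**Cohort comparison.** Per gene, a 2×2 table of mutated samples is tested
with Fisher's exact test (probability-mass rule, exact integer
arithmetic); effect sizes are conditional-MLE odds ratios of the
noncentral hypergeometric model with exact tail-inversion confidence
intervals, and Benjamini–Hochberg adjustment across genes.

## Worked example

```python
from oncopanel.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_out", seed=17,
                     simulate={"n_samples": 12, "n_paired": 4})
res = run_pipeline(cfg)
print(res["matrix"].frequencies.head(6).round(3).to_string())
print("actionable fraction:", round(res["actionable_fraction"], 3))
```

prints

```
TP53      0.667
KMT2C     0.500
CDKN2A    0.500
NOTCH1    0.500
PIK3CA    0.417
EGFR      0.333
actionable fraction: 1.0
```

i.e. in this 12-sample simulated cohort TP53 is altered (mutation, copy
change or LOH) in two-thirds of samples, and every sample carries at least
one alteration passing the strict actionability rules.  `demo_out/` holds
the per-sample segments (`segments.seg`), LOH calls (`loh.tsv`), the
gene × sample mechanism matrix (`matrix.tsv`), actionability verdicts, the
simulator's ground truth (`truth.json`) and a `summary.json` with per-stage
counts.  Example cells of the matrix:

```
                        S01                  S02            S03
TP53    mutation_plus_cnloh  mutation_plus_cnloh           none
CDKN2A                 none  mutation_plus_cnloh  deep_deletion
```

The same stages are available as subcommands of the `oncopanel` CLI
(`simulate`, `cnv-call`, `loh-call`, `filter`, `compare`, `run`) operating
on BED / VCF / coverage-TSV / SEG files.

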