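# Methods

This note documents the models, defaults and design choices behind
`oncopanel`, and what the synthetic-data evaluations do and do not show.

## Observation model

All stages share one admixture model.  A tumor sample is a mixture of a
fraction $p$ (purity) of tumor cells and $1-p$ diploid normal cells.  A
locus inside a segment with total tumor copy number $C_T$ contributes DNA
proportional to $p\,C_T + 2(1-p)$; hence the expected coverage log-ratio
of the segment against a diploid reference is $\log_2((p\,C_T+2(1-p))/2)$,
and an allele present in $m$ tumor copies and $g \in \{0,1,2\}$ germline
copies has expected VAF $(p\,m + (1-p)g) / (p\,C_T + 2(1-p))$.  The model
assumes a single clone (no subclonal copy states) and ignores mapping or
GC bias; purity is an input, never estimated (tumor-only purity inference
is out of scope).

Useful consequences: a CN-LOH segment (2 total / 0 minor copies) has
coverage ratio exactly 0 but heterozygous-SNP deviation $p/2$, so the
deviation threshold of 0.15 implies a detectability floor at purity
$\approx 0.30$; a fully deleted locus in an impure sample shows VAF 0.5
(only normal DNA remains) and is detected by coverage, not imbalance.

## Circular binary segmentation

`segmentation.cbs_segment` treats each (sub)series as circular, scores
every arc against its complement with the pooled two-sample $t$ statistic
(computed from cumulative sums, all arcs vectorized), and accepts the
maximal arc when a permutation test gives $p < \alpha$.  Defaults:
$\alpha = 0.01$, 1000 permutations, minimum segment width 3 bins.
Numerical conventions, chosen to be stated and testable:

- tie-breaking: the lexicographically first (leftmost) maximal arc;
- zero within-arc variance with distinct means scores $+\infty$; a
  constant series scores 0 and never splits;
- the permutation count is sequential with early stopping once
  significance is unreachable (the decision is identical to the full
  count); the stream is a caller-seeded `numpy` generator, so breakpoints
  are reproducible;
- recursion proceeds independently on the up-to-three pieces of an
  accepted split.

Permutation inference sets a resolution floor: an arc of $k$ bins in a
series of $n$ can reach $p < \alpha$ only if roughly $n/\binom{n}{k} <
\alpha$ (at $\alpha = 0.01$, a 3-bin segment needs $n \gtrsim 27$).  The
oracle-agreement evaluation therefore generates noise-free series of
length 25–50 with segments of at least 8 bins and level gaps ≥ 0.5 —
configurations a permutation test can resolve — and on those the
implementation matches an exhaustive least-squares changepoint search
(0–2 changes) exactly.  Shorter segments are a limitation of the method,
not of the implementation.

## Copy-number calling

The pooled-normal reference is the per-bin median of total-depth-
normalized coverage across normals; bins with median raw depth < 10 are
flagged unreliable and excluded.  Sample log2 ratios are median-centered
(removing global yield), segmented per chromosome, optionally recentered
(auto mode subtracts the bin-weighted modal segment mean, found by
clustering segment means with a 0.2 log2 gap — a shift-invariant rule, so
recentering is idempotent), and inverted to integer copies:
$\mathrm{CN} = (2 \cdot 2^{\bar r} - 2(1-p))/p$ (purity 1 when unknown),
rounding halves away from zero and clipping at 0.  Copy states use the
configurable thresholds 0 / 1 / 2 / 3–4 / ≥5.  GC and mappability
corrections are omitted: the reference median absorbs target-level bias,
and the simulator generates none.

## Allelic imbalance and LOH

Informative SNPs require population AF strictly inside (0.0001, 0.95),
depth strictly above 30, and observed VAF strictly inside the
homozygote-exclusion cutoffs (0.05, 0.95) — symmetric defaults, exposed in
configuration, since only "exclusion of homozygous variants" is specified
by the underlying procedure.  Deviations are segmented on variant index
rather than genomic distance (panel gaps would otherwise dominate arc
statistics).  A segment is imbalanced when its mean deviation ≥ 0.15 (the
median is available as a config alternative).  Mechanisms come from the
copy number of the region: ≤1 deletion-LOH, 2 CN-LOH, ≥3 imbalanced gain.
Because one deviation segment can span adjacent genes in different copy
states (their expected deviations can coincide), gene-level integration
re-derives the mechanism from the gene's own majority copy number combined
with the gene's majority imbalance vote.  Paired samples add per-variant
shifts $|\mathrm{VAF}_T - \mathrm{VAF}_N|$ at loci heterozygous in the
normal; a segment gains paired support at mean shift ≥ 0.15 (mirroring the
tumor-only threshold; no separate value is specified).  Paired mode only
adds support flags — imbalance calls are identical to tumor-only mode.

At purity 1 a CN-LOH heterozygote has VAF exactly 0 or 1 and is
indistinguishable from a homozygote; the noise-free evaluation therefore
disables the homozygote filter (and the noise-free simulator preset plants
no homozygous SNPs).  That filter exists for impure, noisy data, where LOH
heterozygotes sit well inside (0.05, 0.95).

## Variant filtering and classification

Defaults: population AF ≤ 0.001, depth ≥ 20, ≥ 4 alt reads,
panel-of-normals occurrence ≤ 1; paired mode drops variants present in the
matched normal.  These are conventional targeted-panel cutoffs (the
procedure being reproduced names its databases but not its thresholds);
all are configuration-exposed.  Manual curation is replaced by an explicit
precedence rule: an upstream predictor verdict wins; else truncating
(nonsense/frameshift/splice-site) variants in tumor suppressors and
hotspot variants are pathogenic, silent variants benign, everything else a
VUS.  Gene summaries keep non-benign variants (pathogenic and VUS).

## Integration and actionability

Mechanism labels follow a fixed priority: deep deletion → ≥2 mutations →
mutation + (shallow deletion or deletion-LOH) → mutation + CN-LOH →
mutant-allele amplification → amplification (no mutation) → single hit →
none; the first five are biallelic.  Either copy loss or deletion-LOH
qualifies as the second hit (the source procedure does not state whether
both were required).  Mutant-allele amplification uses $\hat m \ge 1.5$
(midpoint between 1 and 2 copies) with CN ≥ 3; with unknown purity the
estimate uses purity 1 and the record is marked putative.  Actionability:
pathogenic/hotspot mutation, deep deletion, or total CN ≥ 5 ("at least 3
additional copies" and "at least 5 copies" are treated as the same ≥5
total rule); shallow deletions without a second hit and VUS-only genes are
excluded.  The gene → pathway map ships as editable configuration.

## Exact cohort comparison

`exact_test` computes the probability-mass two-sided Fisher p with exact
integer binomial-coefficient comparisons (ties resolved exactly, not to
float tolerance).  The conditional MLE solves the score equation
$E_\psi[A] = a$ of the Fisher noncentral hypergeometric distribution by
root bracketing in log-odds (log-space weights, softmax expectations);
support-edge tables give 0 or ∞.  Confidence intervals invert the
one-sided tails at $(1-\mathrm{level})/2$ by the same bracketing.  Tests
cross-check all three against independent oracles (exact-fraction
enumeration, golden-section likelihood search, bisection) and against
scipy's `fisher_exact` and conditional `odds_ratio` — scipy is never the
implementation.  Per-gene denominators may differ (a gene unsequenced in
one source cohort uses that cohort's reduced size).  The comparison counts
small-scale mutations only; CNV/LOH do not enter it.

## The simulator

`simulate.generate_cohort` emulates the study conditions the pipeline
targets: 48 tumor samples, 13 with matched normals, mean tumor depth 150×
(negative-binomial with shape 10 — capture data is overdispersed; normals
100×), coverage noise 0.15 log2 units, purity uniform on 0.6–0.9, a
16-gene HNSCC driver panel (24 × 400 bp bins per gene, autosomes only — the
cohorts in question are predominantly male, making X calls ambiguous), and
per-gene driver-event probabilities seeded from the recurrently altered
HNSCC genes (TP53, FAT1, NOTCH1, KMT2C, CDKN2A, KMT2D, CCND1, PIK3CA,
EGFR, PTEN, HRAS, CASP8, ATM, BRCA2, ARID1A, NF1).  Germline SNPs are
placed as a homogeneous Poisson process at 2.5/kb with population AFs from
a mixture favoring common variants but including tails on both sides of
the informativeness window, 25% homozygous; heterozygotes alternate
parental haplotypes (random starting side) — statistically inert, since
the deviation statistic is symmetric in the carrier haplotype, but it
keeps both haplotypes represented in segments with few SNPs, which matters
only at purity 1 where one side is uncallable.  Recurrent low-VAF
technical artifacts at shared loci exercise the panel of normals; silent
and predicted-benign passengers exercise the benign-elimination rules.
Copy events per gene are drawn from {neutral (2,1), shallow deletion
(1,0), CN-LOH (2,0), deep deletion (0,0), gain (3,1), amplification
(6,1)}.  Variants observed with zero alternate reads are not emitted (a
caller would not report them).  A `noise_free()` preset (exact depths and
VAFs, purity 1, no coverage noise, no homozygous SNPs) makes the entire
pipeline deterministic for exact-recovery checks.

What the simulator does **not** model: subclonal structure, GC/mappability
bias, FFPE artifacts beyond the fixed-locus kind, mutational signatures,
read-level errors, germline CNVs, and sex chromosomes.  Passing synthetic
evaluations therefore demonstrates correctness of the statistical
machinery under the stated model, not performance on real capture data.

## Evaluation problem sizes

Chosen once as the package's standard evaluation: 200 noise-free series
plus 100 noisy replicates for the segmentation oracle; all 2×2 tables with
total ≤ 60 (631,595 tables) plus 100 random tables for the exact-test
oracles; 1000 null replicates at n = 67 vs 595 for calibration; 200
planted CN-LOH events at purity 0.5 and 100 at 0.2; 48-sample cohorts
(768 gene-sample pairs) for end-to-end recovery.

## Known limitations

- Purity must be supplied for absolute copy numbers; without it, calls are
  relative to the recentered baseline and multiplicities are "putative".
- The 0.15 deviation rule makes CN-LOH undetectable below ~30% purity by
  construction; the pipeline inherits that floor.
- CBS cannot certify segments too short for permutation significance (see
  above); such events surface only through the coverage channel.
- Cohort-level recurrence analysis (GISTIC-style peaks) and
  mutual-exclusivity statistics are out of scope.
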