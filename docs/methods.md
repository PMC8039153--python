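# Methods

This note records the models, estimators, defaults and numerical choices
behind `tequant`, and what the synthetic-data tests do and do not
establish about real data.

## Problem setting

In animals lacking maintenance DNA methylation (zebrafish *uhrf1* or
*dnmt1* mutants are the motivating case), transposable elements — LTR
retrotransposons in particular — are transcriptionally derepressed,
while the somatic CpG methylome loses its bimodal structure. The package
quantifies TE expression at the family level from interval-level read
placements, tests differential expression with a transparent
negative-binomial model, classifies CpG methylation states from
bisulfite read counts, and integrates the two views (which families are
both upregulated and normally methylated; whether TE changes track their
nearest genes; how methylation behaves around gene TSSs).

## TE counting

Reads and repeat loci are intervals on a shared chromosome namespace;
all internal coordinates are 0-based half-open, with readers converting
1-based inclusive dialects (RepeatMasker tables, Bismark coverage) at
the boundary. Counting follows union semantics on unstranded features:
overlap means ≥ 1 bp intersection; a read overlapping loci of two or
more **different** families is ambiguous and counted nowhere; a read
overlapping several loci of the **same** family increments the
earliest-starting overlapped locus (ties broken by chromosome name).
This family-aware relaxation of strict union counting exists because
quantification is by family: discarding same-family multi-overlaps would
systematically undercount tandem and nested repeats. Each read record
is counted at most once; multi-mapping is not re-resolved
(TEtranscripts-style EM reassignment is out of scope). Simple-repeat and
low-complexity records are dropped at parse time, and repeat classes
outside {DNA, LTR, LINE, SINE} collapse to "other".

## Differential expression

The NB test is deliberately simple and fully inspectable rather than a
DESeq2 workalike:

- **Size factors** are median-of-ratios: factor_s = median over features
  positive in all samples of count_fs / geometric mean_f.
- **Dispersion** α is per-feature method-of-moments, (v − m)/m², pooled
  across the two conditions by degrees of freedom and floored at 1e-8.
  There is no empirical-Bayes sharing across features.
- **L2FC** = log2(m̂₂ + 0.5) − log2(m̂₁ + 0.5) on normalized condition
  means. The 0.5 pseudocount stabilizes low counts; there is no
  shrinkage prior, so strong fold changes stay wide (as in the
  motivating datasets, where LTR L2FC spans > 6 down to < −2).
- **Wald test**: Var(log2 m̂) ≈ (m + αm²)/(n m² ln²2) by the delta
  method; the statistic L2FC/SE is referred to a Student-t with
  n₁+n₂−2 degrees of freedom. The t reference matters: the SE rests on
  a variance estimated from very few replicates (typically 3v3, 4 df),
  and a normal reference is visibly anti-conservative there (empirical
  type-I ≈ 0.11 at nominal 0.05 in our null simulations, vs ≈ 0.04–0.05
  with the t reference).
- **Multiplicity**: Benjamini–Hochberg over all tested features; TE and
  gene sets are adjusted separately, as they are analyzed as separate
  datasets. Features with zero counts everywhere report p = 1, L2FC = 0.
- **Direction calls**: up/down require padj < 0.05 and |L2FC| above a
  threshold — 0 for TE families, 1.5 for genes.

The class × direction table is tested with a Pearson chi-square of
independence without Yates correction (counts in the motivating tables
are large); rows or columns with zero totals are dropped with a warning.
The alternative reading — each class against genome composition — is not
implemented. ΔΔCt follows the standard bookkeeping: ΔCt = Ct_target −
Ct_reference, ΔΔCt subtracts the control-group mean ΔCt, and
L2FC = −ΔΔCt.

## Methylome

Replicates are pooled per condition before anything else (condition
percent = 100·ΣM/ΣT), mirroring the practice of merging RRBS replicates
to increase coverage; a CpG enters the joint table only when its pooled
coverage reaches 10 in **every** condition. A per-sample mode is
available by passing each sample as its own condition. States are
strict: percent < 20 unmethylated, > 80 methylated, everything else —
including exactly 20 and 80 — intermediate. Cytosine positions are kept
as reported; opposite-strand CpG merging is not performed.

Densities default to decile bins: the terminal deciles nest inside the
classification bands, so a bimodal methylome shows as mass concentrated
in bins 0 and 9 (≈ 0.86 of mass under the default synthetic WT), and the
hypomethylated mutant as a single interior mode. Genomic context uses a
±1 kb strand-aware promoter window around the TSS (configurable; no
standard definition exists) with precedence promoter > exon > intron >
intergenic across genes.

## Integration

The background comparison operates at the **region** level: focal
regions are all genomic copies of the upregulated families; an equal
number of background regions is drawn uniformly without replacement
from all TE loci (focal families eligible by default, excludable by
flag); CpG percents inside each region set are then compared with a
two-sided Mann–Whitney U test. The U test enumerates the exact
permutation null (ties included) when both groups hold ≤ 8 values, and
otherwise uses the normal approximation with tie correction and a 0.5
continuity correction. The default is a single background draw; a
seeded multi-draw mode reports the median p over draws, which
quantifies — and at toy scale substantially dampens — background
sampling noise. Nearest-gene assignment has no distance limit within a
chromosome (cross-chromosome genes are never nearest); distance is the
bp gap between interval ends, 0 for any overlap, ties to the lower gene
start. The bystander report deduplicates neighbor genes (several copies
can flank one gene), reports the fraction significantly up, compares
neighbor L2FC against all genes by Mann–Whitney, and correlates family
L2FC with mean neighbor L2FC across families. TSS metaplots bin CpGs on
a strand-oriented ±4 kb axis (80 bins of 100 bp by default); empty bins
carry NaN, never interpolation.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not sequence:

- **Genome/annotation**: 2 chromosomes × 300 kb; 60 non-overlapping
  genes (2–6 kb, 2–4 exons); 400 TE loci (200–1500 bp) placed uniformly
  in intergenic + intronic space, never across an exon, overlaps among
  TEs allowed (nested repeats are real); class mix DNA 0.55, LTR 0.20,
  LINE 0.15, SINE 0.05, other 0.05 — a DNA-transposon-dominated
  complement with a minority of LTRs; 20 families per class, assigned
  cyclically within a class so no family is accidentally absent; integer
  SW scores carried per locus.
- **Expression**: per locus and sample, counts ~ NB(mean 50, dispersion
  0.05); 3 replicates per condition. The default truth map concentrates
  upregulation in eight LTR (Gypsy) families (true L2FC 1.5–3) and
  scatters modest downregulation (L2FC −1) over six DNA, three LINE and
  one LTR family — the qualitative shape of the motivating study's
  table. Reads are single fixed-length (100 bp) intervals placed
  uniformly inside their source locus; no pairs, no splicing — counting
  logic, not alignment, is under test. Each read's BED name encodes its
  source locus for exact provenance in tests.
- **Methylome**: ~8,000 CpG positions, 3× denser in promoter windows;
  WT percent per CpG from the mixture 0.74·Beta(20,1) + 0.26·Beta(1,20)
  (the weight is a free parameter of somatic methylomes; 0.74 puts the
  WT grand mean near 72% and the >80% fraction near the weight); CpGs
  inside upregulated-family loci draw the high component with
  probability 0.98, so derepressed families sit in normally-methylated
  sequence. Mutant methylation is multiplicative: high-component CpGs
  retain 48% of their WT value (placing the WT-methylated partition
  near 46% and the mutant grand mean near 35%), low-component CpGs are
  untouched. Coverage per CpG and sample is zero-truncated
  Poisson(20); methylated reads are Binomial(coverage, truth).
- **Genes**: gene-level NB counts with log-normal base means around 100
  and a sprinkling of true DEGs (8% up / 4% down at |L2FC| 2.5), enough
  to exercise the gene DEG table and the bystander analysis.
- **Reproducibility**: every stream derives from the master seed via
  named SeedSequence spawn keys, one per (generator, sample); adding
  samples never perturbs existing ones, and equal seeds give
  byte-identical outputs.

What passing tests on this generator shows: the counting rule, the NB
test's calibration and power, the state classification, the overlap and
nearest-gene machinery, and the end-to-end recovery of a designed
LTR-concentrated signal all behave as specified under NB counts and a
Beta-mixture methylome. What it does not show: robustness to alignment
artifacts, multi-mapping bias, bisulfite conversion failure, coverage
biases correlated with methylation, or cell-type heterogeneity —
real-data phenomena the generator deliberately omits.

## Problem sizes and determinism

Test and acceptance workloads use the default toy scale: 2,000-feature
null panels for calibration; 20 generator seeds for recovery rates;
1,000 seeded draws for the background null; 100 randomized instances
per brute-force oracle. The acceptance script derives every substream
from its `--seed` argument, so reruns with the same seed are exactly
reproducible.

## Known limitations

- Dispersion estimation at n = 3 per group is noisy; the t reference
  restores calibration but power for |L2FC| ≈ 1 at family level depends
  on family copy number.
- The background comparison treats CpGs as exchangeable units within
  region sets; at toy scale a single background draw is noticeably
  noisy (hence the multi-draw mode), and conditional on one methylome
  the null rejection rate can drift within a few points of 5%.
- BH is applied per result set; no independent filtering of low-count
  features is performed.
- `other`-class repeats are carried through counting but excluded from
  the class × direction table, which reports the four named classes.
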