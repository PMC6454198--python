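# Methods

`lncpair` implements a complete desk-scale version of a multi-group
RNA-seq workflow for inferring candidate lncRNA–mRNA regulatory
interactions in a non-model organism: read QC, FPKM expression, a
five-step lncRNA filtration cascade, two-group negative-binomial (NB)
differential expression with Benjamini–Hochberg FDR control, Pearson
co-expression edges, genomic co-localization edges, and their overlap
and cross-comparison intersection. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Coordinates and annotation

All genomic arithmetic uses 0-based half-open intervals internally; GTF
on disk is 1-based inclusive, converted only at the file boundary. Gene
spans run from the minimum exon start to the maximum exon end across a
gene's transcripts (introns included), so locus-to-locus distances are
gap-based: `genomic_gap` returns the number of bases strictly between
two intervals, 0 for overlap or abutment, and is undefined across
chromosomes. Transcript strand must be `+` or `-`; unstranded records
are rejected because both the filtration cascade and the
upstream/downstream orientation logic require orientation.

## Read QC

A read is removed under the first failing rule, in order: exact
adapter substring; N fraction above `max_n_frac` (default 0.10);
fraction of bases at Phred ≤ `low_qual_phred` (default 5) above
`low_qual_frac` (default 0.5). Clean-data summaries are per-base
tallies: Q20/Q30 are fractions of bases at Phred ≥ 20/30, GC is
computed over called (non-N) bases. The exact thresholds used by
sequencing vendors' in-house filters are rarely published; these are
conventional defaults and are configurable — the synthetic read
fixtures carry a ledger, so tests check exact bookkeeping rather than
any particular threshold folklore.

## Expression

FPKM is the plain definition
`FPKM = count · 10^9 / (length · library_size)` with length = mature
transcript length (sum of exon lengths) and library size defaulting to
the per-sample column sum of the count matrix (an explicit per-sample
total may override it; true "fragments mapped" denominators require
alignments, which are out of scope). Gene-level FPKM is the sum of
member-transcript FPKM, which conserves the per-sample total under
grouping. No effective-length correction or TPM is attempted.

## lncRNA filtration cascade

Five rules applied in strict order; each rejected transcript records
its first failing rule:

1. exon count ≥ 2 (default `min_exons = 2`);
2. mature length > 200 bp (default `min_len = 200`);
3. reference comparison: same-strand exonic overlap with a coding exon
   eliminates the candidate; exonic overlap with (or identity to) an
   annotated lncRNA labels it `annotated_lncRNA`;
4. expression: maximum FPKM across samples ≥ `min_fpkm` (default 0.5;
   a mean-based rule is available);
5. coding potential: flagged coding by ≥ 1 predictor → TUCP
   (transcript of uncertain coding potential); by none → novel lncRNA.

Three decisions here were genuinely open and are worth stating. First,
rule 3 is strand-aware by design: eliminating candidates on any-strand
exonic overlap would make antisense lncRNAs — which are defined by
opposite-strand exonic overlap — impossible, so only same-strand
overlap eliminates. Second, annotated-lncRNA matches still pass rules
1, 2 and 4 (a transcript must be expressed to be reported) but skip
rule 5; coding-potential screening is for novel candidates. Third,
"expressed" is read permissively as max-over-samples ≥ 0.5 FPKM.
Overlap throughout means ≥ 1 bp of exonic intersection, with no
minimum-fraction rule.

External coding-potential predictors are represented by a boolean
transcript × predictor table; a built-in stand-in
(`orf_coding_heuristic`) calls a sequence coding when any forward frame
contains an ATG-initiated open reading frame of ≥ 100 codons, so the
cascade can run without third-party tools.

Surviving lncRNAs are classified positionally with precedence
antisense > intronic > lincRNA: antisense on any opposite-strand
exonic overlap with a coding gene; intronic when contained entirely in
one intron with no exonic overlap; lincRNA otherwise.

## Differential expression

Counts are normalized with median-of-ratios size factors (median of
count/geometric-mean ratios per sample, rescaled so the factors'
geometric mean is 1). Dispersion uses the NB parameterization
`Var = μ + φμ²`. The per-feature method-of-moments estimate
`φ = max(0, (s² − m)/m²)` is computed within each group on normalized
counts, averaged across groups, and floored at 1e-8. Because the raw
moment estimator is extremely variable at 2–3 replicates per group —
roughly half the features draw a severe underestimate, which makes any
downstream test anticonservative — the default estimate is bounded
below by the dataset-wide median estimate. This restores null
calibration (raw p < 0.05 fraction ≈ 0.05, and essentially zero BH
discoveries under a global null in the test suite) at the cost of some
power for genuinely low-dispersion features; it is the same compromise
classic NB pipelines make by sharing dispersion information across
features.

The test itself is a Wald test on the log scale:
`z = log(μ̂_B + c) − log(μ̂_A + c)` over
`SE = sqrt((1/μ̂₀ + φ)(1/n_B + 1/n_A))`, with μ̂₀ the pooled
normalized mean of both groups. Evaluating the delta-method variance at
the pooled mean under the null (a score-flavoured plug-in) is better
behaved at three replicates per group than per-group plug-ins. The
pseudo-count `c = 1` normalized count keeps fold changes finite when
one group is unobserved; features with zero counts in both groups
report p = 1 and log2FC = 0 by convention. Two-sided p-values come
from the normal reference and are adjusted per comparison with the
Benjamini–Hochberg step-up rule
(`adj_(i) = min_{j≥i} p_(j)·m/j`, capped at 1); features with
`padj < α` (default α = 0.05) are called DE, partitioned into up/down
by the sign of log2FC. A significant feature with log2FC exactly 0 is
reported with direction "none" and excluded from both tallies.
Comparisons are declared "B vs A" and log2FC is B relative to A.
Fold-change sign flips and p-values are invariant under swapping B and
A, and p-values are invariant to relabeling samples within a group.

lncRNA differential expression is called at the transcript level and
mRNA at the gene level (summed member-transcript counts), matching the
id scheme of the interaction stage.

## Interaction edges

Co-expression: every DE-lncRNA × DE-mRNA pair is tested by Pearson
correlation over **all** samples (n = 9 in the default design), not per
comparison — a pair has one correlation; only DE status is
comparison-specific. The p-value is the two-sided tail of Student's t
with n − 2 df at `t = r·sqrt((n−2)/(1−r²))`; |r| = 1 reports the
smallest positive double rather than 0. Edges keep pairs with
`|r| ≥ 0.95` and `p ≤ 1e-4` by default; negative correlations are kept
on the same magnitude rule. The default thresholds bracket the weakest
published match in the validation table shipped with the package
(|r| = 0.951, p = 8.46e-5) and are prominent configuration knobs, since
the original analysis did not state its cutoffs.

Co-localization: same-chromosome pairs whose genomic gap between the
lncRNA transcript span and the mRNA gene span is at most `window`
(default 100,000 bp; the largest published match distance is
98,036 bp). Distance 0 reports location "overlapping"; otherwise the
location is upstream/downstream of the mRNA **in the mRNA's reading
direction**. Both the span convention and the strand-relative
orientation are configurable inferences — published tables rarely state
them.

An interaction candidate is a pair carrying both kinds of edge
(`overlap_interactions`); candidates present in every inter-group
comparison (`intersect_across_comparisons`) are the headline output.
Candidate lists are anti-monotone in all three thresholds. Venn region
counts over 2–3 DE feature sets use exhaustive membership enumeration.

## Enrichment and qPCR

Over-representation of a study gene set is tested per term with the
hypergeometric upper tail `P[X ≥ k]`, BH-adjusted across terms, with
rich factor k/K. The default universe is all genes expressed at
FPKM ≥ 0.5 in ≥ 1 sample. Terms with fewer than two universe members
are untestable and skipped (counted in the output's attrs). Length-bias
(Wallenius) corrections and pathway topology are deliberately out of
scope. qPCR relative quantities use the Livak 2^−ΔΔCT method with
amplification efficiency fixed at 2; the calibrator group's geometric
mean RQ is 1 by construction.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: a
3-group × 3-replicate design (the group labels are the three dietary
DHA/EPA ratios), coding genes laid out on slot boundaries every 300 kb
so that non-planted loci are geometric decoys (> 100 kb from every
gene), and a handful of planted lncRNA–mRNA pairs realized **exactly**
at configured distances and strand-relative locations (default five
pairs at 200 / 837 / 5,000 / 20,000 / 75,000 bp; the layout admits
planted distances up to 120 kb). lncRNA transcripts get 2–3 exons and
300–800 bp mature length — shorter and fewer-exoned than the 3–6-exon
coding genes — unless the configuration plants deliberate cascade
failures (single-exon, short, same-strand coding overlap, unexpressed,
or coding-potential-flagged candidates). About 30% of decoy loci are
emitted as pre-annotated lncRNAs to exercise the annotated path.

Counts are NB draws with `Var = μ + φμ²` (default φ = 0.1; base means
2^U(5,9)). Planted-pair members share a fold-change pattern across
groups (default ±{0, +3, −3} in log2, alternating sign by pair index,
so every pair is DE in every comparison) and a per-sample lognormal
latent factor. The latent variance is solved numerically so that the
expected Pearson correlation of the members' log-expression reaches the
pair's target (default 0.99), counting the covariance already
contributed by the aligned fold-change pattern and the residual NB
noise `1/μ + φ`; when the pattern alone meets the target the latent
variance is 0. Pair members default to φ = 0.01 and μ = 800 — the
planted condition is tightly co-regulated, strongly expressed pairs,
which is the only regime in which correlations ≈ 0.99 at n = 9 are
attainable at all under NB noise. Additional fold changes are planted
on decoy mRNAs and lncRNAs so DE sets are non-trivial in every
comparison.

One RNG stream per artifact type (annotation, counts, reads) is derived
from the master seed, so enlarging the read fixture never perturbs the
count matrix. FASTQ fixtures emit exactly the configured numbers of
adapter-bearing, poly-N, low-quality, and clean reads, tagged in the
read ids.

What the generator does **not** emulate: alignment and positional
coverage, isoform structure beyond one transcript per gene, GC or
length bias, batch effects, and correlated decoy structure beyond what
shared group means induce. Passing recovery tests therefore demonstrate
the pipeline's bookkeeping and statistical behaviour under its own
model assumptions, not performance on real libraries.

## Problem sizes and numerical choices

The default synthetic study is 60 coding genes, 20 lncRNA loci and 9
samples; recovery properties are checked over 20 independent seeds, and
null calibration over 2000 simulated features — sizes chosen so the
whole suite exercises every claim in seconds while keeping Monte-Carlo
bands meaningful. Ties in BH are handled by the step-up minimum; p-values
are clipped into (0, 1]; dispersion floors at 1e-8; correlation against a
constant profile raises rather than returning NaN, and such pairs are
skipped when enumerating edges.

## Known limitations

The NB test is a two-group Wald stand-in, not a reimplementation of any
specific assembler/quantifier stack; published dataset-scale DE counts
are not reproducible without the raw libraries and genome. Pearson
p-values assume bivariate normality, which log-scale RNA-seq data only
approximates. The co-expression p threshold applies to raw p-values
(adjusted alternatives are not implemented). Paired-end read linkage is
ignored in QC. GFF3 input, chromosome aliasing and trans-acting
(cross-chromosome) target prediction are out of scope.
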