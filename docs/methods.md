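# Methods

## Coordinate and data model

All internal coordinates are 0-based half-open; GFF3 and VCF conversions
happen only at the I/O boundary, and chromosome names are matched by exact
string equality (no `chrA01`/`A01` aliasing).  Genes carry exon structure,
strand, a subgenome label (LF/MF1/MF2 from the Brassica whole-genome
triplication), and optional paralog-set and ortholog identifiers, supplied
as GFF attributes.  Peaks are consumed as caller output (BED/narrowPeak);
peak calling, alignment and repeat annotation are upstream of this package.

## Gene marking

A gene is H3K27me3-marked in a sample when a *single* peak's intersection
with the gene's extended region (locus ± `flank_bp`, default 200, both
sides regardless of strand) exceeds `min_peak_len` (default 200 bp,
strict).  Overlaps are never summed across peaks.  The phrase "a more than
200-bp peak within the genic region" admits other readings, so the rule is
a config switch: `overlap` (default; robust to peaks extending past gene
ends), `contained` (peak fully inside and longer than the cutoff), and
`peak_length` (any overlap, peak itself longer than the cutoff).
Tissue-specific marking requires presence in both lines of one tissue and
absence in both lines of the other; stable marking is the four-sample
intersection.

## SES normalization and the differential test

Each ChIP library is scaled onto its own input: bins (default 1 kb; the
coverage grid is finer and re-binned) are sorted by ascending ChIP count,
cumulative count fractions P_k (ChIP) and Q_k (input) computed, and the
separation point k* = argmax(Q_k − P_k) (ties → smallest k) defines the
factor = cumulative input / cumulative ChIP at k*, clipped to [1e-6, 1e6].
At least 100 non-empty bins are required; an all-zero ChIP cumulative at k*
is an error.  Whether the original normalization ran ChIP-vs-input per
sample or ChIP-vs-ChIP between samples is not documented; normalizing each
ChIP to its input and comparing normalized rates is the package's choice
and the factors enter only through the effective library totals.

For two samples the per-gene 2×2 table is [[a, T_a − a], [b, T_b − b]] with
T = round(SES factor × library total); rounding keeps the margins integral
so the Fisher test stays exact.  The two-sided P sums hypergeometric
probabilities of tables no more likely than the observed one (the
minimum-likelihood convention, oracle-tested against exhaustive
enumeration).  The log₂ ratio of region rates uses a +1 pseudocount —
log₂(((a+1)/(T_a+1)) / ((b+1)/(T_b+1))) — so it is finite at zero counts;
the pseudocount never enters the test table.  Significance requires
|log₂| > 2.0 (strict), BH q < 0.05, and a marking call in the
higher-signal sample (which side must be marked is otherwise unspecified;
requiring the high side is the conservative reading).  Genes are tested
genome-wide and BH correction runs over that family.

## Expression statistics

Seven groups partition log₂(FPKM) at −3, 0, 3, 6, 9, with group 6 requiring
x > 9 strictly and group 0 reserved for genes without reads; absent an
explicit read indicator, FPKM < 0.01 is the group-0 proxy (the source
figure legend is ambiguous on whether total gene sets were FPKM-filtered;
no filter is applied by default).  DEG flags use |log₂((a+ε)/(b+ε))| ≥ 1.0
with ε = 0.01 pseudo-FPKM; the upstream confidence criterion of the
FPKM-producing tool is not recomputed.  τ = Σ(1 − xᵢ/x_max)/(n−1) is
computed on raw FPKM (the index is conventionally defined on expression
magnitudes; a log₂ variant is a one-line change upstream of the call), is
scale-invariant, and is undefined when all tissues are zero.  Group
distribution shifts use a Pearson chi-squared against expected proportions
from the total gene set with df = non-empty bins − 1.  Where a
"significantly higher/lower average" between gene classes is wanted and no
test is prescribed, the two-sided Wilcoxon rank-sum is used.

## Conservation

Paralog classes are mutually exclusive — for 3-copy sets all_three /
exactly_two / exactly_one / none, for 2-copy pairs both / one / none — so
class counts sum to the family totals; "conserved" aggregates all_three +
exactly_two + both and "copy-specific" aggregates exactly_one + one.  (The
prose description "at least two / at least one copies" conflicts with
printed counts that are mutually exclusive; the exclusive reading is the
arithmetically consistent one and is implemented.)  The marking input
defaults to the 14-day both-lines set.  Ortholog tables collapse to strict
1:1 by dropping every external gene hit by ≥ 2 focal genes (and every focal
gene with ≥ 2 external hits) together with their mappings; conservation
classes partition the 1:1 denominator.  SNP density counts homozygous SNPs
with depth strictly > 10 reads inside the gene locus (introns included)
per bp of locus.

## Profiles and vernalization

Metagene profiles use 20 fixed 50-bp bins per 1-kb flank and 40 equal bins
over the rescaled gene body (both configurable); per-window read density is
reported in RPM per bp so the profile is invariant to library depth and
flat under uniform coverage; minus-strand genes are reversed so the axis
runs 5′→3′.  Segment composition assigns each read one class with
precedence exon > intron > 2-kb-upstream > 2-kb-downstream > IRR >
intergenic.

The nucleation region is the first exon plus the proximal
`intron_extent_bp` (default 500 bp) of intron 1, clipped to the intron;
single-exon genes fall back to the 5′ half of the body.  The 500-bp default
is a modeling choice of the order of the *A. thaliana* nucleation region,
not a measured value, and is exposed as a parameter.  Genome background is
the median bin count (mean fallback when the median is zero).  A gene is
called `spread` when the fraction of gene-body bins above 2× background
reaches `b_spread` (default 0.5), `nucleation_only` when the nucleation
region is > `e_min`-fold (default 2.0) enriched but the body is still
narrow, `none` otherwise.

## Term enrichment

One-sided (over-representation) hypergeometric upper tail P(X ≥ k) per
term with BH control, enriched iff q < 0.01.  Terms are flat gene sets; no
true-path propagation over an ontology graph, matching the coarse slim-like
categories this analysis is used with.  The population is an explicit
required input.

## Synthetic study design

The generator emulates the study layout: two inbred lines × two tissues
(2-day cotyledons, 14-day leaves), a triplicated genome with 100 three-copy
sets, 200 two-copy pairs and 100 singletons (800 genes, three chromosomes,
one subgenome each) — small enough that the full pipeline runs in seconds
while every class remains populated.  Genes are 1–3 kb, ≥ 2 exons,
coordinates on a 50-bp grid, ≥ 4 kb intergenic spacing so 2-kb flanks never
collide.  Marking is planted per set and tissue with probability
`frac_marked` = 0.3 per tissue (giving marked fractions of the order the
study reports); a marked multi-copy set is copy-specific with probability
`frac_copy_specific` = 0.3 (one copy chosen once per set).  The two lines
share marking states by default (`line_discordance` = 0), reflecting the
near-identity of the inbred lines; the knob exists to exercise
between-line comparisons.

Counts are Poisson: background at `depth_chip` = 100 reads/kb (50-bp
coverage bins), marked gene bodies at `enrichment_fold` = 8× background,
inputs background everywhere.  An overdispersion knob (gamma-mixed Poisson)
exists but defaults off, keeping the analytic oracles exact.  Peaks are
emitted directly from truth (covering 65–90% of the body, always > 200 bp)
rather than re-called, since peak calling is out of scope.  Region counts
are sums of coverage bins over the gene ± 200 bp, so counts, coverage and
peaks are mutually consistent.  Expression plants a `tau_high_fraction`
= 0.2 of strictly one-tissue genes (log₂ FPKM ~ N(7,1) at home, N(−4,1)
elsewhere; τ ≈ 1), housekeeping genes with per-tissue scatter σ = 0.15 in
log₂ (mean τ ≈ 0.15), marked genes over-sampled 2:1 into the specific
class, and a 4× expression suppression in samples where a gene is marked —
producing the low-group shift and the negative mark/expression concordance
the analysis detects.  Vernalization coverage adds 6× enrichment over the
nucleation region at V1 and over the whole body at V2 for four FLC-like
singleton genes.  SNPs are Poisson at 0.005/bp, halved in marked genes,
with 30% of records failing the depth filter and 20% heterozygous (dropped
at read time) — the pass fractions cancel in the density ratio.

What the generator does **not** emulate: read-level data (mapping bias,
duplicates, multi-mappers), overdispersion beyond the optional gamma knob,
correlated replicates (the study pooled replicates), linkage between SNPs,
realistic gene length/expression distributions, or any sequence content.
Passing recovery tests therefore demonstrates correctness of the
statistics and classifiers under the planted model, not robustness to
alignment artefacts or biological overdispersion.

## Numerical choices and problem sizes

SES ties break to the smallest k; the factor is clipped to [1e-6, 1e6].
Strict inequalities at every published threshold (peak overlap > 200 bp,
|log₂| > 2.0, q < 0.05, SNP depth > 10, group 6 x > 9) are covered by
boundary tests.  Degenerate inputs error loudly: empty annotation, all-zero
τ vectors (flagged undefined and excluded from averages), all-zero
coverage, study genes outside the population.  The acceptance script uses
240-gene genomes (5 seeds) for recovery metrics and 2,000-gene genomes
(5 seeds) for null calibration — sizes at which every class is populated
and the whole script completes in well under a minute.

## Known limitations

The Fisher test on pooled counts ignores biological replicate variance and
is anti-conservative on real overdispersed data — the published design
pooled replicates, and the |log₂| > 2 gate absorbs much of the excess.
1:1 ortholog collapse is one consistent reading of a partially described
reduction (how 9,769 homologous genes reduce to a 6,207 1:1 set); it is
config-isolated.  Marking gives no partial credit for near-threshold
overlaps; term enrichment has no ontology structure; the CLI covers the
common paths while the library remains the full interface.
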