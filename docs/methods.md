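# Methods

## The contrast model

The cohort design is *F* families (default 4), each contributing one
high-trait and one low-trait sib. Genotypes enter as alt-allele dosages
`d ∈ {0, 1, 2}`. A locus is a **common differential indel** iff every
family is polymorphic (`Δ_f = d_high,f − d_low,f ≠ 0`) and all `Δ_f` share
one sign. Two interpretation choices are fixed here and verified against
the shipped 25-row candidate fixture:

* *Polymorphic* means genotype (dosage) inequality, so a het-vs-hom pair
  counts; the fixture contains such rows.
* *Direction* is the shared sign of the per-family dosage difference,
  defined uniformly on the alternate allele for insertions and deletions.
  Defining it on the "insertion allele" instead yields the identical
  retained set with flipped signs at deletion loci; the frequency profile
  exports both scales (`freq_*` and `insertion_freq_*`).
* Only direction is required to be shared, not the genotype pattern itself
  — fixture rows differ in pattern while agreeing in sign.
* Families larger than one high/low pair would be compared on family-mean
  dosages; with one pair per family this reduces to the pairwise rule.

Loci with any missing dosage among the design samples are excluded and
counted rather than imputed. No significance test is attached to the
filter; it is combinatorial, which is why the implementation is checked
against an exhaustive enumeration of all 3^8 dosage patterns.

## Call-confidence filter

Records are kept iff site quality ≥ `min_quality` (default 20, phred),
per-individual depth < `max_depth` (default 100, exclusive), alt-supporting
reads > `min_strand_alt_support` (default 3, exclusive) on at least one
strand, and 1 ≤ length ≤ 49 bp. Site quality stands in for base quality
because only site-level quality survives into VCF. Strand support is read
from a DP4-style INFO field (ref-fwd, ref-rev, alt-fwd, alt-rev); the field
name is a config key. The strand criterion applies only to records carrying
the alternate allele: a backfilled homozygous-reference record has no
alt-supporting reads by definition, and rejecting it for that would delete
every explicit reference genotype. Absent fields pass their criterion.
Each rejected record increments a per-criterion counter, so relaxing any
threshold can only grow the kept set (tested property).

## Normalization and merging

Normalization trims the shared allele suffix, then the shared prefix,
always retaining one anchor base and advancing the position per trimmed
prefix base; it is idempotent and matches an exhaustive trim-search oracle
on all allele pairs up to 8 bp. Full left-alignment against a reference
sequence is deliberately out of scope — the package runs without a
reference — so calls of one event emitted at different anchors are distinct
keys. Merging unions calls on `(chrom, pos, ref, alt)`; an explicit 0/0
record gives dosage 0, absence of any record gives a missing value.
Reference alleles at one position must be prefix-compatible (two deletion
lengths at one anchor are legitimate distinct variants); refs disagreeing
on an overlapping base raise a consistency error. Coordinates are 1-based
inclusive throughout (VCF convention).

## Annotation

Categories are assigned per gene-overlapping transcript and reduced by the
conventional precedence exonic > splicing > ncRNA_exonic > UTR5 > UTR3 >
intronic > upstream/downstream > intergenic; a variant upstream of one gene
and downstream of another (and in no gene body) gets the combined
`upstream;downstream` category. Defaults: 1,000 bp flanking windows, 2 bp
splice windows — the conventional annotator defaults, exposed as config
keys. Overlap uses the anchor base for insertions and the deleted span
`[pos+1, pos+len]` for deletions. UTR side follows transcript strand
relative to the CDS span. Exonic indels are frameshift iff length mod
3 ≠ 0, crossed with insertion/deletion. Novelty is exact membership of the
normalized key in the known-variant set — no positional fuzz. The summary
reports distinct gene counts under both any-overlap and primary-category
conventions (they coincide unless intergenic records carried gene ids,
which they never do here).

## Evidence integration

Physical gene spans are converted to genetic positions by piecewise-linear
interpolation of a (bp, cM) marker map, clamping beyond terminal anchors
(`numpy.interp`). The gene's cM *interval* (not midpoint) is compared with
QTL records: CI overlap is closed-interval intersection; peak proximity is
the minimum interval-to-peak distance, strictly `< 5` cM. GWAS proximity is
the minimum interval-to-SNP distance in bp, strictly `< 5` Mb, 0 inside the
gene body. QTL and GWAS records are first filtered to a configured
trait-label set (default: protein/fat percentage synonyms). The four flags
reduce to tiers in fixed order: A = peak ∧ SNP ∧ core pathway; B = CI ∧
SNP; C = peak ∧ SNP; D = SNP ∧ core pathway; E = SNP; else none. Genes are
profiled when they carry ≥ 1 differential indel whose primary category is
not intergenic; the retained set is the union of QTL-evidenced and
GWAS-evidenced genes.

Enrichment uses the one-sided hypergeometric upper tail
`P(X ≥ k)` for the 2×2 table `(k, n−k, K−k, N−K−n+k)` via
`scipy.stats.hypergeom.sf`, with sets intersected with the background
(default: all genes in the model) before testing. Significance is
uncorrected `p < 0.05`, matching the analysis convention this package
operationalizes; a Benjamini–Hochberg column is emitted for reference but
does not drive the flag. The test suite checks the statistic against an
independent exact `math.comb` tail summation for every table with N ≤ 30.

## Summaries

Cohort averages reproduce printed tables: means are computed in exact
rational arithmetic and rounded half-away-from-zero at each column's
printed precision (integers; percentages 2 dp; depth 1 dp). The printed
per-sample read counts do not sum exactly to their published total, so the
total is reported as the package's own sum and only the means are treated
as checkable arithmetic. Length histograms report 1-bp and <10-bp shares as
2-decimal percentages; chromosome tables report per-Mb densities and an
X-vs-autosome density ratio.

## Synthetic data

The generator's defaults are the emulated study conditions: 8 diploid
samples in four high/low sib pairs; indel lengths from a mixture of a point
mass at 1 bp (0.4447) and a truncated geometric on 2–49 bp calibrated so
that 0.9796 of lengths fall under 10 bp; insertion fraction 1842/3625;
placement proportional to chromosome length with a 0.6 density multiplier
on X; a known-variant set holding 23.33% of the planted differential loci
(so the novelty complement is 76.67%); and 11 candidate genes planted to
attain tiers A, A, A, A, B, B, C, C, D, D, E. The default scale —
~15,000 nonredundant loci, 300 planted differential — keeps a full run in
seconds; `SimulationConfig.paper_scale()` provides a cohort near the real
per-sample counts for ad-hoc benchmarking.

Design choices and what they imply for interpretation:

* Genotypes are drawn per sample from per-locus allele frequencies; sib
  relatedness is **not** simulated, because the contrast filter never uses
  it. Passing tests therefore say nothing about linkage structure in real
  data.
* Planted loci are constructed directly from sign-consistent per-family
  dosage pairs, optionally realizing exact group-frequency targets
  (multiples of 1/8; note that not every on-grid pair is reachable — e.g.
  high 0.625 vs low 0.25 admits no sign-consistent assignment, and such
  targets raise a config error).
* Background loci that would pass the contrast filter by chance are
  redrawn by default, so noise-free recovery is exactly sensitivity 1 /
  FDP 0. The veto is a switch (`exclude_chance_differential`); with it off,
  the observed chance pass count matches the 3^8 enumeration expectation
  under the genotype law (tested within 3σ). Real cohorts have no such
  veto: at genome scale the retained set necessarily contains chance
  concordant loci.
* Candidate genes occupy fixed chromosome fractions spaced far enough in
  cM/bp that planted QTL and GWAS evidence cannot leak between them; the
  planted QTL geometry per tier (peak at the gene for A, peakless CI for B,
  off-gene CI with a near peak for C) makes each target tier attainable by
  construction.
* Per-sample VCFs carry explicit 0/0 records at all non-missing loci
  (genotype backfilling, as a joint caller would emit); missing-call noise
  drops records entirely. Filter-bait records engineered to fail exactly
  one criterion each are appended for rejection-count bookkeeping; genes in
  the model cover only ~0.5% of the toy genome, so synthetic category
  distributions are intergenic-heavy relative to a real gene-dense genome.

Determinism: one integer seed drives genome, cohort and resource
generation; identical config + seed yields byte-identical files.

## Known limitations

* No reference-based left-alignment; identical events called at different
  anchors are not reconciled.
* Annotation is category-level only — no amino-acid consequence, no
  isoform ranking.
* The genetic-map interpolation is linear between anchors; real map
  curvature between sparse anchors is not modeled.
* The enrichment background is the gene model, not a curated annotation
  universe; with small backgrounds the uncorrected p < 0.05 rule is
  permissive by design.
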