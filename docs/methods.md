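# Methods

## Scope and data model

The pipeline operates on per-CpG methylation call tables: one record per CpG
dinucleotide, identified by the 0-based position of its plus-strand cytosine,
carrying methylated/unmethylated read counts. Input cytosine reports
(chrom, 1-based position, strand, meth, unmeth, context) are converted at the
boundary; the (+, p) and (−, p+1) calls of one CpG are merged by summing
counts, which conserves totals exactly. Unpaired strand records are retained
at their plus-strand-equivalent position rather than dropped: discarding them
would bias coverage at asymmetrically covered CpGs, and the merge stays
count-conserving either way. %mCG at a covered CpG is 100·meth/(meth+unmeth);
at zero coverage it is *missing*, never 0 or 100, so that coverage-weighted
region averages (Σmeth/Σcoverage) are unbiased by uncovered sites.

Bisulphite conversion is estimated on the spike-in contig by pooling all its
cytosine calls and treating every one as unmethylated truth — that is the
contig's purpose, and pooling rather than averaging per-site rates weights by
the evidence available.

Depth equalisation across libraries uses per-read binomial thinning (each
read kept independently with probability *f*, seeded). Exact hypergeometric
down-sampling to a fixed total would also work; thinning was chosen because
it is order-independent, streamable and has the same mean. The thinning seed
is recorded in the table metadata.

## DMR calling

Smoothing follows the local-likelihood approach standard for low-pass
bisulphite data. Implementation choices that the method family leaves open
are fixed as follows and are all exercised by tests:

* window: half-width max(h, smallest half-width whose symmetric window holds
  ns CpGs), never crossing a cluster boundary (clusters split at maxGap);
* weights: tricube(d/(w+1)) × coverage — the +1 keeps boundary CpGs at
  positive weight; zero-coverage CpGs contribute nothing but still receive a
  fitted value;
* fit: quadratic basis solved from the 3×3 normal equations; windows with
  fewer than three distinct covered positions fall back to the
  coverage-weighted window mean; fitted values are clipped to [0, 1].

The per-CpG statistic is a two-sample t on the smoothed proportions with a
pooled within-group variance that is (a) averaged over the 101 nearest
retained CpGs and (b) floored at the genome-wide 75th percentile of the
averaged variance. Local averaging stabilises the 2-vs-2 variance estimate;
the floor prevents near-zero denominators at flat regions from dominating
the tails. The exact percentile used by the original analyses of this type
is not standardised; 75 is the conventional choice and is configurable.
Positive t means hypermethylated in mutant.

Cut-offs are the empirical 0.01/0.99 quantiles (linear interpolation) of the
finite t values. Candidates are maximal same-side runs of retained CpGs,
optionally gap-limited (1,500 bp in the cross-tissue mode; unbounded in the
full-depth mode, mirroring the two printed parameterisations). A region ends
at the last CpG position + 2, covering both strands' cytosines, half-open
for clean BED export. The mean-methylation-change filter (>15 points,
strict) is computed from **raw counts** — weighted region methylation per
replicate, averaged within group — not from smoothed values: the filter is a
statement about methylation, not about the test statistic. Candidates whose
raw-count delta contradicts the statistic's side are dropped (rare;
possible at low coverage).

A consequence of empirical-quantile cut-offs worth knowing: when true
signal occupies more than ~1% of retained CpGs, the 0.99 quantile lies
inside the signal distribution and weak regions fragment. At genome scale
DMRs are far rarer than 1%; the desk-scale simulations sit near the
boundary, which the recovery results reflect (sensitivity ≈0.91–0.99
across seeds rather than ≈1).

## Annotation

Feature classification assigns the region's central CpG (lower-middle on
even counts) the highest-ranked feature it hits: TSS ±2.5 kb > single-exon
transcript body > strand-aware last exon (3′ exon/UTR) > other exon >
intron > intergenic. The same 2.5-kb TSS window is used for the
TSS-proximity summary so one promoter definition serves both computations.
The expected distribution assigns every base pair to its highest-ranked
covering feature via interval union/subtraction, so classes partition the
genome exactly. Genic/intergenic and CGI summaries use whole-interval
intersection on half-open intervals (abutting = not overlapping). Shore
profiles take DMRs whose centre lies within 5 kb of the nearest CGI centre
(ties to the lower coordinate) and record the offset together with the
island's weighted %mCG for sorting.

## ChIP layer

Reads are extended strand-aware to 200-bp fragments from their 5′ alignment
start and counted into 32-nt bins (a fragment increments every bin it
overlaps). Interval RPKM counts *fragments overlapping the interval* — kept
exact via sorted fragment endpoints rather than approximated from bins — as
fragments × 10⁹ / (bp × library size). Enrichment requires ratio > 2.0 over
input in *every* ChIP replicate (strict at the boundary; zero input with
nonzero ChIP counts as infinitely enriched). Peak fold change is mean mutant
RPKM / mean wild-type RPKM with increased/decreased at >1.5 and <1/1.5
(both strict); proximity to DMRs is edge-to-edge distance, inclusive at
2 kb. Active = H3K4me1 ∧ H3K27ac, poised = H3K4me1 only; H3K27ac alone is
no state. The Mann–Whitney test enumerates all group assignments exactly
for ≤16 pooled values without ties, otherwise uses the tie- and
continuity-corrected normal approximation.

## Multi-tissue and expression layers

Per-tissue DMR sets merge by interval union — any shared base merges,
abutting regions do not, so touching calls stay distinct — with provenance
(contributing tissues, source-call count) conserved. The region × sample
matrix holds weighted %mCG for regions with ≥8 CpGs each covered ≥6× in
every sample. Clustering is UPGMA on Euclidean distance, implemented
directly so tie-breaking is deterministic in input order (scipy's
average-linkage agrees on tie-free data and is cross-checked in tests).
Per-tissue deltas for merged coordinates are recomputed over the merged
span for comparability; a region is "not a DMR in tissue T" when
|Δ_T| < 5 points (strict). Vestigial classification partitions focal-tissue
DMRs into marked-in-focal (any of H3K4me1/H3K27ac/H3K4me3), marked-elsewhere-
only (H3K4me1 in another tissue) and unmarked-everywhere.

Expression linkage flags genes whose TSS lies within 50 kb (point-to-edge,
inclusive) of a DMR or of a changed H3K4me1 peak; differential-expression
testing itself is consumed from a table (fold change on the linear scale,
adjusted p, α = 0.05). Fold-change strata use fold > cut and fold < 1/cut,
strict, hence monotone in the cut.

## Synthetic study generator

The generator emulates the target study conditions: 2v2 replicated
methylomes at 30× mean Poisson coverage (15× for the cross-tissue
emulation via thinning), background methylation 0.78, CGIs at 0.05,
~1-kb regulatory elements at 0.30 with 15 guaranteed CpGs each, half of the
elements planted as DMRs with |Δ| = 30 points, 94% hyper (hypo elements
model ordinary-methylation loss: 0.78 → 0.48), a fully unmethylated
spike-in contig read through a 0.003 conversion-failure rate, and a
transgene contig carrying one hypermethylating element. Replicate noise is
beta-binomial with intraclass correlation 0.02 — enough overdispersion to
make the 2-vs-2 variance estimate non-trivial without destroying desk-scale
power. CpG density is 0.01/bp background (mouse-like order of magnitude)
and 0.08/bp in CGIs. Gene density is 8/Mb, the mammalian order of
magnitude, which also supplies enough TSS-linked elements for the
expression-linkage property tests.

ChIP libraries draw uniform background reads at 0.04 reads/bp and plant
extra fragments across the full overlap footprint (element + fragment
length) of marked elements so the realized coverage ratio equals the
nominal fold (3×). The density follows a Poisson power calculation:
sd(log ratio) ≈ sqrt(1/(900·d)) must clear log(3/2) with margin, giving
>0.95 per-replicate probability that a fold-3 1-kb element exceeds the
2-fold cut. In mutant libraries, enrichment at planted-DMR elements is
attenuated to 30% of its excess, emulating enhancer-mark loss. The DE
generator gives genes linked to attenuated elements fold ≈ 0.5 with small
adjusted p, and null genes log2-normal fold with uniform p.

What the generator does **not** model: read-level sequences and alignment
artefacts, PCR duplicates, CpG-density autocorrelation beyond CGIs/elements,
copy-number structure of real multi-copy transgenes, batch effects, or
regional methylation waves. Passing recovery tests therefore demonstrates
the pipeline's statistical machinery under the stated noise model, not
robustness to alignment- or sample-quality pathologies of real libraries.

## Problem sizes and determinism

The test suite and the reproduction script run simulations of 2–20 Mb
(~20k–210k CpGs per sample): large enough that empirical quantiles, variance
flooring and recovery statistics are meaningful, small enough for a
single-CPU desk run. All generators are pure functions of (seed, config);
every stochastic step in tests and in `scripts/acceptance.py` derives from a
single seed. The smoothing kernel has numba-compiled and pure-numpy paths
asserted equal to 1e-12.

## Known limitations

* Peak calling is not implemented; peaks enter as BED (the generator's truth
  marks stand in for them at desk scale).
* Single-replicate designs are rejected; the t-statistic needs within-group
  variance.
* The full-depth mode's ">5 reads per CpG" variant reported alongside the
  headline analysis of the target study design is exposed via
  `min_coverage`/`coverage_mode` knobs rather than fixed, since the two
  printed descriptions differ.
* FDR control is out of scope: the method's significance machinery is the
  quantile cut-off plus effect-size filter, by design.
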