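# Methods

## The measurement model

The pipeline analyzes converted (EM-seq/bisulfite-style) paired-end
sequencing of a genome in which an LTR retrotransposon is actively
transposing. Three signals are extracted from the same libraries:

1. **Discordant read mates.** Reads are mapped both to the reference
   genome and to the extracted element sequence. A fragment spanning the
   junction of a non-reference insertion yields one mate on the genome and
   one on the element. Genome-side mates accumulate on both sides of the
   insertion point and point toward it; element-side mates identify which
   LTR fed each border.
2. **Depth of coverage.** Because all element copies are (near-)identical,
   reads from every copy pile onto the single reference copy; the depth
   ratio between the element's internal region and its flanks scales with
   copy number.
3. **Per-cytosine conversion counts.** An unmethylated C reads as T (G as
   A on the opposite strand view); a methylated C survives conversion.
   Counts per cytosine, per strand, per context (CG/CHG/CHH, H = A/C/T)
   form the seven-column report all methylation statistics consume.

## The insertion caller

Discordant pairs are grouped by genome-side contig and start proximity
(`max_gap`, default 700 bp = the maximum library insert; the proximity
radius has to cover the span over which junction fragments start). Sorted
by start, a candidate cluster must consist of `m` 3′-pointing reads
followed by `n` 5′-pointing reads with a single direction switch and
`m, n >= 3`; anything else is discarded (clusters with several clean
switches — two nearby insertions — are first split into consecutive
(3′-run, 5′-run) couples; set `split_clusters=False` for the stricter
single-switch reading). The site is the interval between the end of the
`m`-th and the start of the `m+1`-st read.

**TSD.** During integration the target site is duplicated, so the two
boundary reads overlap by exactly the TSD length, each carrying a
soft-clip of element-derived bases on its insertion-proximal end. Which
read end "5′" refers to depends on whether one reasons in read or
reference orientation; the caller therefore requires a soft-clip on the
insertion-proximal end of each boundary read, which is well-defined under
both nomenclatures.

**Strand and LTR-of-origin.** A pair whose genome and element mates map on
opposite strands indicates a sense insertion, equal strands an antisense
one; within a valid cluster all pairs must agree, otherwise the strand is
reported ambiguous and no LTR labels are assigned. For a sense insertion
the upstream border is fed by the 5′ LTR and the downstream border by the
3′ LTR (swapped for antisense).

**Ties.** When two retained calls claim overlapping intervals the one with
higher total support is kept and the loser logged.

**Nested / hairpin screens.** Element-side pairs in the same reference
orientation (the signature of sequence antisense to itself) with a mate
overlapping an LTR are evidence of an antisense nested insertion; at least
2 qualifying mates at each LTR are required for a confident call ('Y';
'y' = any evidence, 'N' = none). Pairs with *both* mates on LTR sequence in
that inverted configuration indicate two LTR copies in antisense proximity
(a hairpin template). Both screens only see configurations closer than one
library insert (~300–700 bp): a fragment cannot span farther, so more
distant inverted repeats are structurally invisible to them.

## Copy number

`ratio = mean depth(internal region) / mean depth(flank union)`. Flank
bases are pooled base-wise into one mean rather than averaged per-flank
(the two conventions differ only when flank lengths differ). The internal
region deliberately excludes the LTRs, whose depth is depressed by
multi-mapping between the two identical LTR copies. The mean inverse ratio
over control samples carrying only the reference copy calibrates the
estimate so controls land at 1. The ΔΔCt calculator assumes 100% primer
efficiency (exact doubling per cycle) and averages technical replicates on
the Ct scale before differencing; the ×2 factor is the diploid wild-type
copy number of both the element and the reference gene. Extra-chromosomal
element DNA can inflate the qPCR estimate relative to the coverage route;
this is a known caveat of the assay, not modeled here.

## Methylation statistics

Weighted methylation is `100 * sum(meth) / sum(meth + unmeth)` over the
cytosines of a region — coverage-weighted by construction, additive under
any partition of the records. Zero-coverage cytosines contribute nothing
to either sum; a region with zero total coverage is *undefined* (NaN),
never 0. The conversion rate is 100 minus the weighted methylation over
all contexts on the chloroplast-like control, which is truly unmethylated,
so residual methylated calls measure conversion failure. Group
comparisons use the two-sided Wilcoxon rank-sum test (tie-corrected normal
approximation — adequate at the per-cytosine sample sizes involved, where
each cytosine's methylation fraction is one observation) with
Benjamini–Hochberg adjustment across the comparisons of one invocation.
Wilson 95% score intervals use the closed form (z = 1.95996).

## Per-LTR methylation and landing sites

Only the element-side mates of a cluster carry methylation evidence over
the element, so the per-LTR subsets consist of those mates alone, keyed by
the LTR-of-origin labels; ambiguous reads are excluded and the 5′/3′
subsets are disjoint. Cytosine positions are taken on the extracted
element coordinate system, with the masked 3′-LTR sub-interval excluded
from the denominator (no read can be placed there by construction).
Concordance between the two LTRs of each insertion is the squared Pearson
correlation over insertions with both sides defined (minimum 3 pairs).

A landing site's pre-insertion methylation is read from same-genotype
individuals that do not carry the insertion, pooled by counts over a
±200 bp window (the window size is a package choice — narrow enough to be
local, wide enough to hold tens of cytosines at 30×; configurable).
Classification thresholds are fixed at 10% per context with strict
inequalities; a value exactly at 10% falls to the less-methylated class
and is flagged borderline. Pathway subclassification (RdDM/CMT2/
independent) applies only to non-CG sites, by any-overlap of the window
with an external annotation BED (largest overlap wins). The shift metaplot
uses 50 bp bins over ±2 kb, computed on the insertion-free coordinate
system — carrier reads near the junction map there with their
element-derived bases soft-clipped, so carrier and non-carrier coordinates
agree — and reports the mean carrier-minus-non-carrier weighted
methylation per bin, context and sample group.

## The synthetic-data generator

The generator is first-class, tested code and defines the study
conditions: a miniature multi-contig genome (default 2 × 100 kb plus a
10 kb chloroplast-like control) with one embedded reference element copy
(5 kb, 400 bp identical LTRs, a ~100 bp masked window in the 3′ LTR),
20 planted insertions with 5–8 bp TSDs and random strands at 2 kb minimum
spacing, 30× coverage, 150 bp paired-end reads, uniform insert sizes in
300–700 bp, and a 0.001 conversion-failure probability. Methylation levels
are assigned per region class and context — arm (15/5/2% for CG/CHG/CHH),
pericentromere (80/55/15), element LTR (85/60/12), element internal
(90/65/10), chloroplast (0/0/0) — values chosen once to mimic a plant
methylome with a silenced element; per-insertion LTR overrides and local
flank perturbations support the concordance and metaplot analyses.
Fragments are strand-symmetric (50% top-/bottom-strand conversion views).

Alignments are derived from the planted truth instead of an external
aligner, preserving the record semantics the callers consume:

* reads fully inside a planted element are placed on the element sequence
  (coordinates and strand flipped through antisense copies, with the
  conversion view flipped accordingly);
* concordant pairs fully interior to one element are projected onto the
  reference genomic copy — this is what makes depth scale with copy
  number;
* reads straddling an element boundary are placed on the genome with the
  element-derived portion soft-clipped, and boundary-spanning pairs become
  discordant;
* pairs joining two different element copies (nested junctions, inverted
  LTR pairs) stay on the element reference in improper orientation.

Two multi-mapping effects are emulated: element-side placements entirely
inside the masked 3′-LTR window are dropped, and genome-side placements
fully contained in an LTR of the reference copy are dropped (two identical
LTRs make them ambiguous). A placement also needs an aligned block of at
least `min_anchor` (25) bp — a local aligner cannot seed on less — which
keeps boundary soft-clip records realistic and the cluster direction
pattern clean. The mate-overlap rule of standard methylation extractors is
honored in the pile-up: within a pair, positions already observed by the
first mate are not counted again.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing errors and base qualities, PCR
duplicates (deduplication is a no-op here), mappability structure beyond
the two LTR effects above, biased insert-size distributions, genetic
variation between individuals, and partial conversion of methylated
cytosines (only failure to convert unmethylated ones is modeled). Recall
and exactness figures from simulations are therefore upper bounds on
real-data performance.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open in memory; SAM and the cytosine
  report are 1-based on disk, BED 0-based (each writer states this).
* Context at sequence edges is computed with N padding (N counts as H).
* Rank-sum groups with fewer than 2 values return NA rather than a
  p-value; concordance with fewer than 3 complete pairs returns None;
  zero-coverage summaries are NaN-flagged, never 0.
* Cluster splitting at multiple direction switches pairs consecutive
  (3′-run, 5′-run) couples left to right; unpaired leading/trailing runs
  are dropped and logged.
* All randomness flows from a single integer seed per sample through
  per-stage generator streams; identical config + seed reproduces reads,
  alignments and reports byte-for-byte. `genome_seed` lets several
  samples share one genome while differing in insertions and reads.

## Problem sizes

The shipped tests run the full conditions above (200 kb genome, 20
insertions, 30×) for recovery, TSD and copy-number checks; 20 replicate
small-genome simulations for the conversion-rate bound; and a four-sample
100 kb cohort (one perturbed carrier, one null carrier, two non-carriers)
for the landing-site metaplot. These sizes were chosen so the whole suite
completes in well under a minute of simulation time while leaving
estimator noise far below the tested tolerances.
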