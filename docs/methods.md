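# Methods

`subtelcnv` re-implements, as a tested pipeline on synthetic data with
planted truth, the structural analysis by which a subtelomeric EPSPS
gene-cassette copy-number variant is localised and quantified in glyphosate
resistant goosegrass (*Eleusine indica*): cohort read-depth CNV calling,
cassette junction validation from spanning long reads, copy-number and
zygosity estimation, tandem repeat analysis of telomeres and subtelomeres,
distance-based relatedness trees, and the dosage expression filter.

## The cassette model

The locus is modelled as ordered, oriented segments.  One tandem unit is

    [flank ST array | A | B1 | I | B2 | short ST array | B2' | I' | B1' | A']

where A (default 35 kb) is the native EPSPS region, B1+B2 (default
5 kb + 36 kb) the co-duplicated downstream region with the novel insert I
(default 3,396 bp; the source material also quotes ~450 bp, so it is a
parameter) at its head, and primed segments are the reverse complement of
the forward half.  ST arrays are tandem copies of a 452 bp subtelomeric
unit (unit length is a parameter; 472 bp is also quoted): the *short*
array (default 12 forward + 31 reverse copies) separates the forward and
reverse halves and its strand flip is the **inversion point**; a *large*
array (default 43 forward + 294 reverse copies) precedes each unit and
closes the locus.  Every named junction (ST-A, A-B, B-I, I-B, B-ST)
therefore occurs twice per tandem unit and the inversion point once, which
is the half-coverage prediction the junction ratio test checks.

## Synthetic data

`GenomeSpec` builds chromosomes as
[telomere `(TTTAGGG)n` | subtelomere array | i.i.d. random background |
reversed arrays | reversed telomere].  GC skew is not modelled (the depth
caller does not GC-correct).  Individuals are diploid; a cohort design
assigns each haplotype a tandem copy count.  The default cohort mirrors
the resequencing study: eight resistant individuals (seven homozygous at
the configured tandem count T, one heterozygote) and eight susceptible.
The heterozygote carries the cassette on a single haplotype with
`round(0.6*T)` units: the published heterozygote's EPSPS depth (~8x) is
roughly a third of the homozygotes' (25-29x), i.e. its single resistant
haplotype carries a visibly shorter array — expected where unequal
crossing over keeps expanding and contracting the locus — and that is the
signature the zygosity flag keys on.  Truth tables record every planted
feature and the exact diploid copy number of regions A and B
(2 + 2·(t1+t2)).

Long reads are placed uniformly per haplotype; lengths are log-normal
around the configured mean (default 5 kb, sigma 0.3 log units), truncated
to [500 bp, chromosome length]; errors are independent per-base
substitutions/insertions/deletions (default 0.1%/0.05%/0.05%, HiFi-like).
`depth` is calibrated as total bases over total (diploid) haplotype
length; projected onto the haploid reference, background windows
therefore sit near 2·depth, which cancels in every ratio the pipeline
reports.

Alignment is replaced by exact truth projection.  Reference space: each
read splits at segment boundaries and each piece maps to its source
interval (background identically, cassette A/B copies onto native A/B);
pieces from ST arrays and region I are unmapped, as a repeat-aware aligner
would discard multimappers.  Cassette space: one maximal alignment record
per read against the one-unit model (flank+unit+flank), anchored at the
read's start phase, which is uniform over the unit — so every junction
context receives equal expected spanning support without modelling an
aligner's split-placement heuristics.

cDNA reads are assigned uniformly to C gene copies, m of which are marked;
count matrices are gamma-Poisson (negative binomial, Var = mu + phi·mu²)
with group-2 means of dosage genes scaled by the copy ratio.

## Depth CNV calling

Depth is scanned in fixed windows (default 5 kb; terminal short windows
are length-corrected), normalised by the genome-wide background (median of
window values after trimming the top and bottom 1%), and classified with
the published display thresholds, adopted as the only printed calling
parameters: duplication above 4x, deletion below 0.25x.  Adjacent
same-class windows merge; each call carries the minimum one-sided Poisson
tail probability of its windows' base counts against the background
expectation and is dropped above alpha = 0.01.  The Poisson tail treats
bases as independent, which long reads are not — it is a ranking score in
the spirit of the original caller, not a calibrated p-value; the ratio
thresholds do the real gating.  No further multiple-testing correction is
applied.  Cohort logic is pure interval algebra: (intersection of every
resistant individual's duplications) minus (union of all susceptible
individuals' duplications).  Zygosity: an individual is heterozygous if
its region depth ratio is below half the cohort median; copy number is
`round(ratio * ploidy)` against a single-copy-per-haplotype background.

## Junction support and macrostructure

A read supports a junction only if a *single* alignment record covers
`pos ± min_overhang` (default 100 bp; split alignments are evidence
against a junction, not for it).  B1/B2 canonicalise to "B" and ST-array
strand is ignored in junction ids (arrays are mixed-strand), so ids
survive reverse-complementing the reference and reproduce the five-name
junction list.  The ratio test compares mean non-inversion support to
inversion support with a counting-noise standard error
(ratio · sqrt(1/Σnon + 1/inv)) and flags consistency when 2 lies within
3 SE.

`self_align` is an exact k-mer dotplot (k = 15, both strands — no spaced
seeds), greedily chained by (anti)diagonal with a 100 bp gap allowance.
`infer_macrostructure` reads tandem arrays off self-overlapping forward
segments (lag ≤ length): within a cluster the smallest lag is the unit
and span/unit the copy count — exact for error-free arrays of 3 or more
copies.  Chance single-base matches at array boundaries are kept from
fusing adjacent arrays by requiring half-a-unit overlap for clustering.
Inverted duplications are reverse-strand segments with (near-)disjoint
arms; perfect palindromes chain into seed-width arm overlap at the
centre, which is tolerated.  Arms must cover 50% of the sequence *or*
exceed 5% each: at desk scale the repeat arrays dominate the locus, so a
pure 50% rule would miss the cassette's own inverted duplication even
though its midpoint sits exactly on the short-array centre.  Arrays
truncated at a sequence end report their copy count flagged as a minimum,
mirroring the unresolvable outer boundary of the large flanking array.

## Repeats, identity, trees

Telomere arrays are maximal phase-locked runs of the motif (per-copy
mismatch tolerance 10% of the motif length, i.e. 0 mismatches for a 7-mer),
on either strand; degenerate partial copies at sequence ends extend the
span but not the count.  Subtelomere unit counting is greedy and
phase-anchored: edlib finds the best occurrence, placements step
unit-by-unit in both directions (identity ≥ 90% per copy), and uncovered
flanks are rescanned — exact on planted arrays across the 12/31/43/294
copy regimes and robust to 5% substitution noise.

Percent identity is global alignment (match +1, mismatch −1, gap open −2,
gap extend −0.5; Biopython PairwiseAligner) with identity = matches /
alignment columns, so gaps count against identity; the better of forward
and reverse-complement orientations is used.  Trees are neighbor joining
on distances 100 − identity with lowest-index tie-breaking and negative
branches clamped to zero — NJ reconstructs additive matrices exactly, and
the published tree's "distance based on similarity" description makes the
distance route the faithful, dependency-free reading (no ML, no
bootstrap).  Newick is written with 6-decimal branch lengths.

## Expression

CPM normalisation, log2 fold change of group mean CPM with a 0.5
pseudocount, and two tests: an exact permutation test over all group-label
assignments (12,870 at 8 vs 8) of the difference in mean log-CPM —
one-sided for over-expression by default, so its floor is 1/12,870 — and
a negative-binomial Wald test (method-of-moments dispersion) for effects
past that floor.  The published quasi-likelihood engine is off-the-shelf
and is not re-implemented; the decision rule is: significant iff p < 0.01
and fold change > 2 over-expressed.  Missing rows (genes filtered during
testing) count as not significant and stay in the denominator, matching
the published "one out of four"; a tested-only mode excludes them.

## Desk scale and problem sizes

The `desk-scale` preset shrinks segment lengths 10x (A = 3,500 bp,
B = 4,100 bp, I = 340 bp), the flank-array copies 10x ((43,294) →
(4,29)), the caller window to 500 bp, and uses three chromosomes of
160-180 kb, so that a full 16-individual cohort at 30x simulates, calls
and intersects in well under a second; the short array keeps its 12+31
copies because its macrostructure is itself under test.  `paper-scale`
keeps all published dimensions with native A/B at their published
chromosome-3 coordinates.  All internal coordinates are 0-based half-open;
the printed tables' 1-based convention survives only inside the fixture
parsers, including the table's own length = stop − start convention.

## What passing tests do and do not show

The generator plants exact structure in i.i.d. background: no GC bias, no
mappability structure, no chimeric reads, no real aligner ambiguity in the
repeat arrays, and diverged-rather-than-identical subtelomere units only
where a test constructs them.  Recovery results therefore demonstrate the
*logic* of the pipeline (interval algebra, ratio arithmetic, junction
bookkeeping, filter rules) under the stated noise models, not calling
performance on real resequencing data.  The packaged tables are
transcriptions of printed results and are analysed, never re-derived.

## Known limitations

- The Poisson call score is anti-conservative on base counts; it is a
  gate behind the ratio thresholds, not an error rate.
- `infer_macrostructure` assumes arrays of one unit family per cluster;
  nested or higher-order repeats are out of scope.
- The NB Wald test uses a plug-in dispersion without shrinkage; at n = 8
  per group its tail p-values are approximate.
- Junction projection emits one record per read; real aligners sometimes
  split reads across tandem units, which would move support between
  junction occurrences but not between junction ids.
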