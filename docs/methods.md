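# Methods

`l1array` implements an annotation-level analysis of dense LINE-1 (L1)
repeat arrays: megabase-scale stretches of mammalian genomes in which
LINE coverage far exceeds the genomic average (~20% in mouse).  The
package calls such arrays from RepeatMasker-style annotations, asks what
genes they touch, whether they preferentially host tandemly duplicated
receptor-gene clusters, whether they contact the nuclear lamina, which
evolutionary cohorts of L1 subfamilies fill them, and whether the
full-length L1 copies they contain could still retrotranspose.  All
stages operate on annotations and sequences, never on raw reads.

## Coordinates and interval arithmetic

Every coordinate inside the package is 0-based, half-open (BED
convention).  RepeatMasker `.out` query coordinates (1-based inclusive)
are converted on read with `start = begin - 1`.  Features on chromosomes
missing from the genome map, or exceeding its lengths, are rejected
outright - silently dropping annotations would corrupt catalog counts.

Interval sets are stored per chromosome as sorted, disjoint arrays in
which book-ended runs are merged, because coverage is a property of the
base set: a base is covered or it is not.  Union length, intersection
length, window coverage and point membership are answered from prefix
sums.  Strand is parsed but ignored by all density computations; the scan
is strand-blind.  Lines flagged by RepeatMasker as overlapped by a better
match are kept - the union makes double annotation harmless.

Random region placement follows the shuffle idiom: per draw, a
chromosome is chosen with probability proportional to its number of
valid start positions `max(0, len - L + 1)` and the start is uniform
among them.  Draws are independent and may overlap each other and real
arrays; an optional exclusion set is available but off by default, since
no exclusion rule is part of the analysis definition.  All randomness
flows through one numpy generator seeded per call - identical inputs and
seed give bitwise identical output.

## Window scan and array calling

Coverage by class-filtered repeats (default: `rep_class == "LINE"`) is
measured in running windows of width W advanced by step s; windows that
would overrun the chromosome end are dropped rather than truncated, so
every fraction shares the denominator W (truncated windows would inflate
variance at chromosome ends).  Two presets encode the two analysis
scales:

| preset       | W      | s     | density d | min length L |
|--------------|--------|-------|-----------|--------------|
| `line_array` | 100 kb | 10 kb | > 0.70    | >= 100 kb    |
| `imprinted`  | 50 kb  | 10 kb | > 0.40    | >= 50 kb     |

A window qualifies when its fraction strictly exceeds d; overlapping or
book-ended qualifying windows merge into a candidate span, and spans of
at least L are reported.  The density threshold is strict (">70%") while
the length filter is inclusive: with W = L a single qualifying window
spans exactly L and must not be excluded.

**Boundary refinement.** The raw union span of qualifying windows
systematically overhangs a dense array: at d = 0.70 with background
p0 = 0.20 and array density p1 = 0.85, a window overlapping an array by
80 of 100 kb has expected fraction 0.72 and still qualifies, so each raw
boundary sits ~2 steps outside the true density change.  When the repeat
annotations are available, each span is therefore trimmed at step-bin
resolution.  Each bin is classified array-like or background-like by a
two-component likelihood with plug-in parameters estimated from the scan
itself (no ground truth involved): a Gaussian term on the bin's coverage
fraction (component means = median bin fraction in span interiors and
median window fraction below 0.5; fixed scale 0.15) plus a Poisson term
on the bin's count of annotated element starts (background vs interior
start rates).  The count channel matters: dense arrays are stacks of
many fragments (roughly eight-fold the background start rate under the
marked-point-process model below), so element counts separate the two
regimes even in the occasional 10-kb stretch whose realized coverage
fluctuates across the density threshold.  Bins are trimmed from each
span edge until two consecutive bins classify array-like, so a lone
dense clump in the background cannot stop the trim.  In design-stage
validation on 8,000 simulated array edges this localized every boundary
to within one step (10 kb) of the planted truth; a pure
coverage-threshold trim mislocalized ~0.2% of edges, which is the
irreducible rate at which 10-kb stretches of a 0.85-density array
genuinely realize sub-threshold coverage.  Without annotations (the
windows-only call path) the raw union span is returned and the density
field is NaN, since overlapping windows cannot be disentangled into
exact base counts.

The reported density is recomputed exactly over the final span and is
*not* re-filtered: a merged region's flanks can legitimately dilute it
below d.  Raising d never adds a region or extends a raw boundary
(qualifying windows only disappear); refined regions are always
contained in their raw spans.

## Genomic context and cluster enrichment

Each called region is placed in exactly one of four categories from its
per-gene relations (>= 1 bp overlap): INTERGENIC (no overlap),
INTRAGENIC (>= 1 enclosing transcript, nothing else), GENE_FLANKING
(only partial overlaps), WITHIN_AND_FLANKING (any mixture, including any
gene fully inside the region).  The relation-to-label mapping lives in
one function so an alternative reading is a one-line change.  Counts of
"regions containing genes" (>= 1 contained or partially overlapped gene)
are reported alongside; the two conventions intentionally need not be
reconcilable into one number.

Tandem-cluster enrichment asks whether arrays contain genes of a
name-matched family (defaults `^Olfr`, `^Vmn` - olfactory and
vomeronasal receptors, the canonical tandemly duplicated, monoallelically
expressed families) more often than random regions.  Success for a
region is >= 1 bp overlap with a family gene (full containment is a
configurable alternative; no containment definition is canonical).  The
null draws `n_random` (default 500) random regions whose lengths cycle
through the observed region lengths (a fixed-length mode exists); the
background success probability is estimated with a +0.5 / +1 continuity
correction, `p_hat = (k_bg + 0.5)/(n_random + 1)`, so an empty
background cannot produce a zero estimate (configurable off).  The
p-value is the exact binomial upper tail P(X >= k_obs | n_regions,
p_hat), computed by summing the pmf on the log-factorial (gammaln)
scale; it matches exhaustive enumeration to below 1e-12 for all n <= 20.
Only two families are tested, so raw p-values are reported without
multiple-testing correction.

## Lamina-associated domains and lineages

A region counts as lamina-associated in a cell type when it overlaps
that cell type's LADs by at least `min_overlap` (default 10 kb).  LAD
fragments within a cell type are unioned first, so adjacent fragments
jointly satisfy the rule - the criterion is total lamina contact, and
fragmented interval tracks would otherwise make the call depend on
arbitrary fragment boundaries.  Status is CONSTITUTIVE (all assayed cell
types), FACULTATIVE (some), or NONE.

Lineage stratification maps L1 subfamily names to the clade in which the
subfamily amplified, via ordered name-prefix rules (first match wins).
The bundled mouse default is `L1Md_* -> Mus`, `Lx* -> Muridae`,
`L1_Mur*/L1_Mus* -> Rodent`, `L1M* -> Eutherian`; unmatched names are
reported separately as `unassigned`, and a two-column TSV replaces the
rules for other genomes.  An element belongs to an array iff its
midpoint falls inside a called region, so boundary-straddling elements
are counted exactly once; within + outside = genome-wide holds exactly
by construction.  Ratios are normalized to the first declared lineage.

## L1 intactness

A retrotransposition-competent L1 is full length, carries intact ORF1
and ORF2, and ends in a functional AATAAA.  The classifier checks
exactly these four properties; thresholds live in `ElementSpec` with
defaults near the canonical mouse element (expected length 6 kb,
full-length at >= 95%, ORF1 >= 300 codons beginning in the 5' 45%,
ORF2 >= 1,200 codons, AATAAA within the final 60 bp) and are
config-overridable, since the database criteria this simplifies are not
published as a closed-form rule.  ORFs are scanned in the three forward
frames (inputs are sense-oriented extractions); nested starts sharing a
stop collapse to the earliest ATG; a codon containing N terminates the
scan with an "ambiguous base" note, and a frame reaching the sequence
end is flagged open-ended.  Only ORFs terminating at a genuine stop
qualify for the intactness flags - an open-ended or N-broken frame is
not an intact ORF.

The assessment is ORF2-anchored: ORF2 is identified first as the longest
qualifying ORF of >= `orf2_min_aa` codons, and ORF1 must be a *distinct*
long ORF starting both within the 5' search window and upstream of
ORF2's start.  The anchoring matters for defect attribution: in a ~6-kb
element a >= 1,200-codon ORF2 necessarily begins within the 5' 45%, so a
purely positional ORF1 rule would accept ORF2 itself as "ORF1" whenever
the real ORF1 is broken, and a premature stop in ORF1 would surface as a
missing ORF2.  With the anchored rule each lesion flips exactly its own
flag.  Frameshifts are detected only through their consequence - loss of
a qualifying ORF - never by alignment to a consensus.  Every false flag
contributes one human-readable defect string.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with recorded ground truth; its defaults are the study conditions used
throughout the tests.

*Repeats.*  Placement is a marked point process: within each genomic
segment (planted array or background gap), elements with geometric
lengths (mean 600 bp) and uniform starts are added - overlaps allowed,
as in real RepeatMasker tracks - until the segment's union coverage
reaches its target (background p0 = 0.20, arrays p1 = 0.85), so realized
coverage matches the target to within one element length (recorded in
the truth set; the +-0.03 contract is met by construction).  Planted
arrays (default ten of 150 kb on 5 Mb) are placed uniformly at random
subject to a 100-kb minimum separation - one window width, which keeps
adjacent calls distinct.  Lineage labels are drawn per element from
stratum-specific mixtures (background near-uniform across Eutherian /
Rodent / Muridae / Mus; arrays skewed young, 0.06/0.13/0.34/0.47,
mirroring the observed dominance of lineage-specific subfamilies inside
arrays), and subfamily names are drawn from per-lineage pools that the
default prefix rules invert exactly.  Optional SINE/LTR layers add
non-LINE classes.

*Genes.*  Background genes are uniform and independent of arrays.
Tandem clusters (n genes of fixed length and gap, named
`Olfr0001...`) are placed by rejection weighting: a uniform proposal is
accepted with weight `enrichment_factor` when the cluster falls entirely
inside an array and weight 1 otherwise.  At factor 1 every proposal is
accepted - placement is *exactly* uniform, which makes the null
configuration distributionally exchangeable with the random-region null
and is what a type-I calibration requires.  The calibration study
conditions (66 arrays of 150 kb on 8 x 10 Mb, 120 clusters of six 1.5-kb
genes, 260 background genes) were chosen, by measuring the true
rejection rate on 1,000 dedicated design datasets per candidate, so that
the test's actual type-I error at alpha = 0.05 is near-nominal (0.046);
with fewer clusters the exact binomial's discreteness makes the test
conservative.  Cluster count is therefore a statistical-resolution
choice, not a mimic of genome-wide receptor-gene density.

*LADs.*  Per cell type, each planted array is covered (with a 20-kb
flank) with probability q = 0.5, yielding a mix of constitutive,
facultative and non-associated arrays; decoy LAD fragments are placed at
least 50 kb from any array so that truth labels stay unambiguous under
the 10-kb overlap rule even after the caller's +-1-step boundary
resolution.

*L1 sequences.*  A consensus is designed per call: random 5' UTR, ORF1
(350 codons) and ORF2 (1,280 codons) of stop-free random sense codons,
a 60-bp spacer, and a 3' UTR carrying one AATAAA 30 bp from the end
(spurious in-window AATAAA occurrences and spurious long ORFs are
scrubbed, with verification).  Injected defects are position-randomized
within spans chosen so the lesion is guaranteed: a premature stop at
codon j of an n-codon ORF breaks it iff both the prefix (j) and any
restart (<= n-1-j) fall below the threshold, pinning j into
[n - min_aa, min_aa - 1]; frameshifts are single-base deletions verified
(and redrawn if needed) to leave no qualifying ORF2; poly(A) mutations
are verified to leave no AATAAA in the window; truncation removes the 5'
portion, the common lesion of real L1 insertions.  Background
substitutions at rate mu are available but off by default.

What the generator does **not** emulate: real subfamily sequence
divergence (annotations carry a crude lineage-dependent milliDiv draw
only), fragmented multi-row annotations of single elements, GC/gene-
density covariation with repeat content, fuzzy array edges, and
alignment-level lesions (indel-riddled ORFs scored by alignment).
Passing tests therefore demonstrate correctness of the interval logic,
calling, counting and statistics under a faithful coverage model - not
robustness to every idiosyncrasy of real genome annotation, for which
the pipeline accepts real UCSC rmsk / BED inputs directly.

## Determinism and numerics

Every stochastic operation takes an explicit seed; the pipeline requires
one for any stochastic stage and refuses to default it.  Generators are
`numpy.random.default_rng` instances created per call; child streams for
the annotation layers are spawned via `SeedSequence`, so generating
fewer layers does not shift the others.  Repeated runs with one config
and seed produce byte-identical output files.  Degenerate inputs fail
loudly: zero-length intervals, inverted coordinates, empty LAD
collections, patterns matching no gene, arrays that cannot fit, and
regions requested below n_random = 100 are all errors, not warnings.

## Problem sizes in the bundled checks

The self-contained checks run at desk scale, chosen to exercise every
code path with tight statistics: interval oracles on 10-kb toy
chromosomes (1,000 instances), array recovery on 5-Mb chromosomes over
20 generator seeds, calibration on 200 null and 100 enriched gene sets,
lineage recovery from ~10,000 in-array elements, and intactness on 100
defect-free plus 100 single-defect elements.  Genome-scale catalog
counts (the tens-of-regions inventories per species, lineage totals in
the hundreds of thousands) require full public annotation downloads and
are outside the bundled data; the pipeline accepts those inputs
unchanged through the same entry points.
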