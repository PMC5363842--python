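# Methods

`kzfptools` implements the computational analysis of KRAB zinc-finger
protein related genetic units (KZFP/rGUs): loci anchored on a zinc-finger-
coding repeat and typically carrying an upstream KRAB domain in the same
reading frame. The package covers unit annotation, cluster delineation,
permutation enrichment statistics, per-cluster consensus phylogenetics,
zinc-fingerprint evolution, retrocopy calling and coverage metaprofiles,
together with a synthetic-genome generator that provides ground truth for
every stage.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF and RepeatMasker input
(1-based inclusive) are converted at the I/O boundary as `(start−1, end)`,
which preserves interval length. Chromosome names are compared verbatim —
no `chr` normalisation — so naming mismatches surface as empty overlaps
rather than silent aliasing. Unstranded features are treated as `+`
wherever orientation matters, with a logged warning. The RepeatMasker
parser targets the standard 15-column `.out` layout; the column indices
are module constants and can be adjusted for other dialects.

## Zinc-finger and KRAB annotation

C2H2 fingers are matched with the pattern `C-X(2,4)-C-X(12)-H-X(3,4)-H`
(21–24 residues). Because the pattern is ambiguous, the scan is defined
operationally: left-to-right, shortest match first (smallest C–C gap, then
smallest H–H gap), resuming after the final histidine, so reported motifs
are non-overlapping and deterministic; `X` never satisfies an anchor.
Degenerate fingers with mutated C/H anchors are skipped, not reported.

The *zinc fingerprint* is the ordered list of specificity triplets — the
residues at alpha-helix positions −1, +3 and +6 of each finger, the main
DNA-contacting positions. Operationally these are spacer positions 6, 9
and 12 of the 12-residue spacer between the second cysteine and the first
histidine (equivalently 7, 4 and 1 residues before that histidine); the
mapping is pinned by the canonical Zif268 finger-1 contacts (R, E, R).

KRAB domains are detected with a packaged 42-column position-specific
scoring model of the KRAB-A box, scored as log2 odds against a uniform
background; unknown residues contribute 0 bits. Hits are local maxima at
or above a threshold defaulting to 60% of the maximum attainable score
(~96 of ~160 bits, i.e. ≥31/42 consensus matches — far beyond what random
protein sequence reaches). The PSSM is a transparent, swappable stand-in
for an annotation track whose provenance is otherwise unspecified; it
ships as a plain-text matrix and can be replaced by the user.

A KZFP ORF call requires a KRAB hit followed, in the same frame and with
no intervening stop codon, by at least `min_znf` fingers (default 3,
matching the three incomplete finger motifs of the anchoring repeat
consensus). When several KRAB hits precede the same stop, the 5'-most is
kept, as a maximal gene model. Editing a stop codon between KRAB and the
fingers removes the call — the pseudogenization behaviour exercised in the
tests.

## Clusters and positional statistics

A cluster is a single-linkage chain of ≥8 elements on one chromosome with
consecutive gaps <500 kb; `min_size=10` gives the olfactory/vomeronasal
receptor comparator rule. The gap is measured end-to-start against the
running maximum end of the chain, which makes chaining exactly equal to
the union-find closure of the pairwise gap relation even for nested
intervals (the property the oracle tests assert). Gap semantics
(end-to-start) are the strictest natural reading of "apart" and are
exposed as an option. Cluster span runs from the first member's start to
the last member's end, with no flanks; span length is the normaliser for
per-cluster peak densities.

Upstream KRAB association is strand-aware: the nearest feature whose
3'-most coordinate lies within 30 kb upstream (inclusive) of the element's
5' end; ties break by distance, then leftmost coordinate.

Positional correlation histograms signed anchor→feature offsets within a
symmetric window (default ±15 kb), sign-flipped for − strand anchors; bins
are half-open with boundary offsets going to the right bin. A 3'-extension
preprocessing (default 1 kb) is available for gene tracks.

The peak-proximity Fisher test compares real elements against a
within-chromosome shuffled control of the same count and lengths; the
contingency is {real, control} × {≥1 peak within ±window, none}, with an
exact two-sided p and a Haldane-corrected odds ratio when a cell is zero.

## Permutation nulls and composition summaries

Shuffle nulls reposition regions (cluster-style, 100×) or features
(peak-style, 10'000×) uniformly within their own chromosome, keeping
lengths; overlaps among shuffled objects are permitted (rejection sampling
would bias long objects). The empirical p uses the add-one estimator
`(1+#{null≥obs})/(n+1)`, never 0 at finite shuffle counts. Note the
estimator is conservative under heavy ties: when the overlap count has
narrow support, the attained type-I error falls below nominal, so
calibration checks use feature sets large enough for the count statistic
to spread (the packaged calibration uses 2000 features).

Subfamily over-representation uses the one-sided hypergeometric test on
(inside/outside clusters) × (this subfamily / all other repeats), with
significance at raw p<0.01; no multiple-testing correction is applied, by
design, matching the raw-p reporting convention of the analysis it
implements. Peak composition assigns each peak to exactly one category
with priority KZFP/rGU > selected TE (largest overlap, ties leftmost) >
other; selected TEs exclude Satellite/Simple_repeat/Low_complexity/Unknown
classes and subfamilies with <100 members inside clusters. The
differential-acetylation summary computes the fraction of cluster bases
under KO-only peaks by interval subtraction (base-conserving by
construction), per-subfamily KO/WT hit ratios for subfamilies with ≥3
cluster members, and per-cluster peak densities.

## Consensus phylogenetics

Within each cluster, unit sequences are aligned progressively: guide order
from 6-mer Jaccard distances by greedy joining, then profile–profile
global alignment with affine gaps (match 1, mismatch −1, open −4, extend
−1 for DNA; a gap of length L costs open+(L−1)·extend) under sum-of-pairs
column scoring averaged over non-gap residue pairs. The aligner is
deterministic given inputs and parameters. Consensus building drops
columns where gaps are the strict majority (internal gap characters would
distort downstream p-distances), emits the majority residue when its
frequency among non-gap characters reaches 0.5, and `N` otherwise, with
alphabet-order tie-breaks.

Pairwise consensus distances are p-distances (mismatches over aligned
non-gap columns, `N` excluded); the tree is canonical Saitou–Nei neighbor
joining with lexicographic tie-breaks on the Q criterion and negative
branch estimates clamped to 0 (deficit logged). NJ on p-distances was
chosen as the standard, deterministic distance method, testable against
additive-matrix oracles; p-distance may violate the triangle inequality,
and only symmetry and the zero diagonal are asserted. Nucleotide mode is
the default; the aligner accepts a protein alphabet for translated mode.

## Fingerprint evolution and retrocopies

Tandem duplications are maximal runs of identical consecutive triplets
(≥2 copies). Repeated blocks of 2–7 triplets are reported longest-first,
with occupied positions consumed so shorter blocks are not re-reported
inside longer ones — a maximality rule that avoids combinatorial
redundancy. Shared blocks between two fingerprints are maximal common
contiguous triplet substrings (≥2 by default), optionally matched against
the reversed partner array to capture opposite-strand encoding, with
positions mapped back to native orientation.

Segment homology (the BLAT-style presence matrix) locally aligns each
reference segment against every region with the same affine scheme;
presence requires ≥80% coverage at ≥80% identity (both configurable, since
no thresholds are canonical); an interrupted segment still counts as
present if coverage suffices. Segment boundaries are user input — they
were fixed by eye in the analysis this reproduces, not inferred.

Emergence ordering is Dollo-style: segments are characters gained once and
never regained, so carrier sets must form a laminar family (checked; a
violating segment pair is reported). Gain events nest uniquely into a
tree, and each gene attaches at the deepest event containing it, making
its segment set exactly the union of gains on its root path. Under the
single-gain precondition this tree is unique up to sibling order (sorted
by label), so no further mismatch-minimisation is needed.

Retrocopy calls require all three classic criteria: exactly one exon; a
genomically encoded poly-A run (≥10 adenines at ≥90% purity — at most one
non-A per ten — within 200 bp of the 3' end, strand-aware); and ≥80%
global identity to the concatenated exonic sequence of the best-matching
multi-exon donor. The poly-A thresholds are defaults for a criterion the
source analysis leaves unquantified, and are configurable.

## Coverage metaprofiles and response classes

Metaprofiles average a bedGraph-backed track over elements on a common
strand-oriented frame: 1.5 kb upstream and 3.5 kb downstream flanks at
1-bp resolution and the body rescaled to 100 bins by chunk-averaging.
Tracks are normalised to counts-per-million by default (the declared
normalisation where none is specified). Windows beyond a chromosome end
are masked, not errors. The 95% confidence band is the pointwise normal
approximation mean ± 1.96·sd/√n, matching the "confidence interval around
the mean" convention; a bootstrap is intentionally not the default.

Differential response is a declared fold-change classifier, a deliberate
simplification of count-model differential testing (out of scope here):
log2FC = log2((b+1)/(a+1)), class `up` when log2FC ≥ 1 and the larger
condition mean passes a minimum-signal filter, symmetric for `down`.
Distance-to-peak stratification assigns each element exclusively to the
first matching bin (overlap, <5 kb, <20 kb, ≥20 kb) with strict
inequalities, so a gap of exactly 5 kb falls outward into the <20 kb bin;
peak-free chromosomes map to ≥20 kb. An in-cluster versus isolated
comparison reports the two log2FC distributions with a two-sided rank-sum
p-value.

## Synthetic genomes

The generator plants, by default, 3 clusters of 10 units (inter-unit gaps
5–40 kb, well inside the 500 kb rule), 20 isolated units in groups of 5
(below the chaining minimum of 8), and 5 retrocopies on a separate
chromosome — the configuration under which the recovery tests run. Each
unit locus encodes, in one frame, the packaged KRAB-A consensus
(reverse-translated with a common-codon table), an in-frame stop-free
spacer (KRAB placed 60–3000 bp upstream of the finger array), then 3–8
fingers with planted specificity triplets joined by TGEKPY linkers, and a
terminating stop codon; strands are random. Donor genes carry an in-frame,
stop-free, GT…AG intron between KRAB and the array, so they remain valid
ORFs while their retrocopies — exon concatenations with a genomic 16-bp
poly-A tail — are intronless. Per-base substitutions are applied to
planted loci at `mutation_rate` (default 1%; recovery benchmarks use 0).
The same scoring model used for detection also plants the KRAB sequences,
which makes sensitivity self-consistent by construction.

TE annotations are drawn from an ERVK/ERV1-biased mix inside cluster
spans (~70% ERVK/ERV1) against a flat background mix, with intergenic
placement (rejection-sampled off unit and retrocopy loci). Densities are
chosen to be detectable by the enrichment stage, not to match any
published composition. WT signal places repressor-style peaks over unit 3'
ends and most ERVK/ERV1 cluster TEs; KO drops them and gains
activation-style peaks over half of the cluster TEs. Coverage is
negative-binomial per expression class (var = μ + αμ², dispersion α = 0.1;
α ≤ 0 yields deterministic means), realised as one draw per 50-bp bin
along each element, so per-element signal averages several bins — the
granularity at which a 4× planted effect is reliably classified.
Cluster units and cluster ERVK/ERV1 TEs are planted 4× up in KO; all
other elements are unchanged.

All randomness flows from a single seed; fixed seed gives byte-identical
output, which the end-to-end test asserts at the file level.

What the generator does *not* emulate: realistic chromosome sizes or
repeat landscapes, transcript isoforms, sequencing-read artefacts,
mappability, GC bias, or 3D chromatin structure. Passing recovery tests on
this generator therefore demonstrates algorithmic correctness under the
declared noise model, not performance on real genomes.

## Problem sizes

The packaged benchmarks use a ~8 Mb five-chromosome genome (50 units, 5
retrocopies, ~290 TEs), 300-bp consensus sequences with 8 lineages × 3
members for phylogeny recovery (50 replicates), 1000 replicate datasets of
100 shuffles for null calibration, and exhaustive 2×2 tables with margins
≤ 30 for exact-test agreement — sizes at which every oracle comparison is
exact and the whole suite runs on a single CPU in a few minutes.

## Known limitations

- The KRAB PSSM is consensus-derived, not trained on curated alignments;
  sensitivity to highly diverged KRAB-B/-b variants is untested.
- The progressive aligner applies unscaled gap penalties to profiles and
  has no iterative refinement; it is adequate for the within-cluster
  divergences simulated here (≤ a few percent within clusters).
- The fold-change classifier ignores replicate structure and dispersion
  estimation by design.
- Retrocopy detection requires a candidate transcript list; there is no
  genome-wide de novo scan.
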