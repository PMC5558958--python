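# Methods

This note documents the models, conventions and numerical choices behind
`mitoarch`, and what the synthetic-data validation does and does not show
about real data.

## Coordinates and the genome partition

Internal coordinates are 0-based half-open; external files (GenBank,
feature TSVs) use the 1-based inclusive convention, with the conversion
tested as an exact round trip. Circular genomes are linearized at annotated
position 1; a feature wrapping the origin is stored as two intervals in
strand order, and written back as a single external row whose end precedes
its start.

The five-part partition (genes, introns, intergenic; intergenic subdivided
into ORF, *ori*, GC cluster, AT spacer, residual) is an exclusive tiling:
every base is credited to exactly one class, so sizes sum to the genome
length as integers. Nesting is real in these genomes — *ori* elements
contain internal GC clusters — so overlaps are resolved by a fixed
precedence (gene exon > intron > intergenic ORF > *ori* > GC cluster > AT
spacer > residual). The choice of precedence is a reporting convention, not
a biological claim; it guarantees disjoint size tables. `N` bases are legal
input and count as non-GC everywhere.

The "fraction of size variation explained by intergenic DNA" is reported as
the R² of an ordinary least-squares regression of genome size on intergenic
size across genomes (the alternative reading — a ratio of differences
against the minimum-intergenic reference genome — is noted but not
implemented, since the source analysis presents a line regression).

## GC-cluster detection

Detection thresholds: pass 1 requires a window of length ≥ 16 with
GC ≥ 0.75; detected runs are masked; pass 2 rescans the unmasked stretches
with length ≥ 8 and GC ≥ 0.85, windows not crossing masked positions (they
may abut them); pooled clusters separated by gaps of ≤ 9 bp (i.e. < 10 bp)
are joined transitively.

A cluster's extent is the **union of all qualifying windows** ("coverage"
definition). This is the one unambiguous reading of threshold-based
detection, and it is checkable against an exhaustive oracle that enumerates
every qualifying substring — the test suite proves equivalence on hundreds
of random sequences, linear and circular. A consequence worth knowing:
coverage can legitimately extend a few bases beyond a GC-rich core into AT
flanks (a window may carry up to a quarter AT at the 0.75 threshold), so
cluster boundaries are not simply "first/last G or C".

The implementation reduces window qualification to prefix sums of the
integer score `q·[base is G/C] − p` for threshold `p/q` (exact arithmetic,
no float comparisons) and finds, for each start, the furthest qualifying
end by binary descent over a sparse table of range maxima — O(n log n)
rather than the oracle's O(n²). Circularity is handled by scanning the
doubled sequence with window length capped at the genome length.

## Cluster families

Clusters are pooled with their reverse complements; all-vs-all distances
are 1 − identity under global Needleman–Wunsch alignment (match +1,
mismatch −1, gap −2), clustered by UPGMA and cut at height
1 − identity_cutoff (default cutoff 0.6 — the grouping threshold is not
specified by the source analysis and is exposed as configuration, not a
claim). A reverse-complement entry sharing a group with its forward mate is
dropped; groups are retained greedily by descending size, discarding any
whose member overlap with retained families exceeds 80%, and finally
deduplicated so no cluster belongs to two families. Members are re-oriented
against the group's first entry before consensus so the consensus is
single-stranded; the consensus is the column majority (ties alphabetical,
gap-majority columns dropped) over a deterministic center-star multiple
alignment built on the same NW aligner. Center-star is used deliberately:
family members are near-identical short sequences, for which it is
accurate, dependency-free and reproducible. "Palindromic-like" means
global-alignment identity ≥ 0.8 between a cluster and its own reverse
complement.

## AT spacers and dinucleotides

Within each intergenic interval, clusters containing at least one G/C
tetranucleotide are excised; each remaining maximal fragment longer than
20 bp with GC < 0.1 is an AT spacer. The (AT+TA)/(AA+TT) ratio pools
overlapping dinucleotides across spacers (each spacer contributes
length − 1 counts, no wrap); a zero denominator returns an explicit
"undefined" (`None`) rather than a number.

## Gene order, DCJ, bsGOL

GOC restricts both genomes to their shared markers, extracts unordered,
sign-blind neighbor pairs on the circular order, and divides shared
adjacencies by shared marker count; GOL = 1 − GOC. The sign-blind
convention matches the use of transcriptional blocks as markers; a signed
variant of the adjacency definition would be a one-line change and is
deliberately not a user-facing switch until needed.

DCJ distance is computed exactly as N − C from the cycle count of the
adjacency graph over signed marker extremities (single circular chromosomes
only — multichromosomal and linear variants are out of scope). The formula
is verified against a breadth-first-search geodesic over all double-cut-and-
join moves for every signed circular order on four markers, and metric
properties are tested on the same exhaustive set.

bsGOL minimizes L = Σᵢ(Σⱼ bᵢⱼxⱼ − GOLᵢ)² over all leaf pairs, with
bᵢⱼ = 1 when branch j lies on the path between pair i (C(n,2) × (2n−3) for
an unrooted binary tree on n leaves; 105 × 27 at n = 15). The solver is
non-negative least squares by default — the objective alone permits
negative branch loss, which is meaningless — with the unconstrained
minimum-norm solution available for comparison. NNLS solutions are unique
for these design matrices in practice; no additional minimum-norm selection
is applied. Per-branch rates divide xⱼ by branch length; zero-length
branches yield NaN rates and all-zero design columns are flagged
unidentifiable rather than silently zeroed. Branches are indexed by a
deterministic bipartition ordering (smaller side size, then labels) since
no canonical numbering exists for an unrooted tree.

Note the linear model is an approximation: GOL along a path saturates
(events can break an adjacency only once), so apportioned branch losses are
mildly compressed for long paths. This is inherited from the method being
implemented, and is visible in the recovery experiment below.

## Intron loci

An intron record carries its host gene, insertion site in intron-free
coding coordinates (1-based, as in the `Species_Gene_ID_Loc` naming
convention), and the two 10-bp flanking exon sequences. Two introns link
when they share the host gene and either their concatenated 20-bp flank
identity (ungapped — the flanks are fixed-length exon snippets, alignment
adds nothing) reaches 0.8, or reaches 0.7 with insertion sites within 30 nt
("neighboring positions"; the 30 nt window quantifies a criterion the
source leaves qualitative, and is configuration). Flank conservation
outranks position, matching the stated priority of the criteria. Loci are
connected components under single linkage; a component containing two
introns of one species is split at its lowest-identity edge, repeatedly,
with deterministic tie-breaking — so assignment is invariant to input
order. Locus ordinals follow mean insertion site per host gene. Per-locus
identity is the conserved-column fraction of supplied alignments (amino
acid for ORF-bearing introns, nucleotide otherwise); single-member loci are
reported "not computable" rather than 1.0.

## Conservation statistics

Conserved-column identity is the fraction of alignment columns where every
row carries the same non-gap residue, over the **full** alignment length;
columns containing any gap, including all-gap columns, count as
non-conserved (a conservative convention; inputs are assumed pre-trimmed).
Enrichment of high-identity proteins uses the exact one-sided
hypergeometric tail: population = both groups pooled, success = identity
strictly above the threshold (default 0.9), sample = the focal group;
verified against brute-force tail enumeration. Alignment construction
itself is an external input; the built-in NW aligner exists for pairwise
fixtures and the short-element comparisons above.

## Synthetic data generator

The generator emulates the architecture the analysis assumes, with complete
ground truth. Per tree leaf it emits a circular genome built from:

- the 35-gene complement at realistic exon lengths (~13.9 kb total;
  tRNAs 75 bp), gene order evolved from a root order laid out as the seven
  syntenic blocks;
- intron loci at fixed coding-coordinate sites (ten in *cox1*, seven in
  *cob*, one in *rnl*), each present in each leaf with probability 0.5,
  with group I/II labels and ORF flags;
- intergenic regions each containing residual filler, one long AT spacer
  (400–1400 bp) plus short spacers (50–150 bp) between elements, optional
  free-standing ORFs (1–5 per genome), *ori* elements (1–8 per genome, an
  AT-pure core with two internal GC clusters), and 12–36 GC-cluster
  insertions drawn from four constructed consensus families (~80% GC,
  mutually < 0.56 identity including reverse complements), point-mutated at
  rate 0.01 and inserted in either orientation;
- an occasional `WTATAAGTA` transcription-initiation motif at region
  starts.

Composition: coding/intron/ORF sequence is sampled at 30% GC, AT spacers at
5% GC, and the residual-filler GC is solved per genome so that the expected
overall AT fraction equals the 80% target exactly; at ≥ 50 kb the realized
value concentrates within a fraction of a percentage point. (A single
background GC of 20% everywhere cannot satisfy both the genome-wide AT
target and the existence of detectable GC < 0.1 spacers; splitting the
non-coding background into near-pure-AT spacers plus balancing residual is
the resolution, and mirrors how the partition itself distinguishes the two
classes.) Because i.i.d. sampling at 20–30% GC occasionally produces
windows that would qualify as clusters by chance (~1 per kb of coding at
the 7/8 threshold), every non-cluster sequence passes a suppression step
that mutates a central G/C out of any chance-qualifying window — the only
detectable clusters in a generated genome are therefore the planted ones,
which is what makes planted-truth F1 a meaningful detector score.

Sequence evolution is per-site point mutation with probability
1 − exp(−rate·branch length), rate 0.1 per unit length. Rearrangement:
per-branch inversion (rate 4) and transposition (rate 5) counts are
Poisson(rate × multiplier × branch length), events applied in random order,
arcs chosen uniformly (event-size distributions are not modeled; uniform is
the neutral default); the ~9 events per unit length yields on the order of
25 events across the default 15-taxon tree, matching the observed scale.
Branch multipliers follow geometric Brownian motion of the log intensity
along the tree (spread 1.5), normalized to mean 1 — rearrangement rates in
real data are lineage-structured, with entire clades fast or slow, and an
i.i.d. multiplier model misses that.

Determinism: all randomness flows from one `numpy` generator in a fixed
traversal order; identical seeds give byte-identical FASTA output.

What the generator does **not** model: codon structure or selection (no
dN/dS truth), intron gain/loss along the tree (presence is i.i.d. per
leaf), cluster insertion homology across species (insertions are
independent per genome, so cross-genome family sizes are comparable but
individual insertions are not orthologous), indels in gene sequences, and
chance GC-rich windows (deliberately suppressed, above). Detector scores on
synthetic data therefore demonstrate correctness of the implementations
under the stated model, not detection performance on real mtDNA, where
boundary effects and borderline-composition elements are harder.

## Validation experiments and problem sizes

- GC-cluster detection equals the exhaustive substring oracle on 200 random
  sequences of length ≤ 500 (a quarter circular), and end-to-end F1 against
  planted truth on full 15-genome datasets is ≥ 0.9 (reciprocal-overlap
  matching at 0.8).
- DCJ equals the BFS oracle on all 96 signed circular orders of 4 markers.
- The 3-leaf bsGOL system GOL = (0.2, 0.3, 0.4) solves exactly to
  x = (0.05, 0.15, 0.25), L = 0.
- Branch-rate recovery: 15 leaves, 20 markers; one Brownian intensity draw
  held fixed; 25 replicate simulations; per-replicate NNLS solutions
  averaged; Spearman rank correlation between mean apportioned branch loss
  and the true per-branch expected event count (intensity × length) is
  ≥ 0.8. The per-branch *totals* are the right comparison scale: dividing
  both sides by branch length amplifies noise on the shortest branches
  (expected events ≪ 1) without adding information. Replication is what
  separates apportionment error from Poisson event noise; a single
  replicate correlates near 0.78 for the same reason.
- Spacer recovery against planted truth is deliberately partial: detected
  spacer fragments span whatever intergenic sequence remains after cluster
  excision, which merges planted spacers with adjacent residual filler;
  only cluster recovery carries an F1 guarantee.

Problem sizes throughout (sequence lengths, replicate counts, tree size)
are chosen so the full validation suite completes in well under a minute on
one core while still exercising every code path at the scale the analysis
uses (15 genomes of 80–90 kb).

## Known limitations

- The GOC adjacency convention is symmetric and sign-blind; a per-gene
  directed variant would change third-decimal values on real data.
- Family grouping quality depends on the unstated identity cutoff; the 0.6
  default separates the constructed families cleanly but real cluster
  families may need tuning.
- The bsGOL linear model compresses loss on long paths (saturation);
  branch *ranks* are robust, absolute rates on deep branches are
  underestimates.
- `group_gc_clusters` is O(k²) alignments in the number of clusters and is
  meant for per-genome cluster sets (tens to low hundreds), not pooled
  multi-genome sets.
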