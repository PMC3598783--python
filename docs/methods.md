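# Methods

This note records the models, conventions and numerical choices behind
`pbscreen`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and motif conventions

All coordinates are 0-based, half-open, everywhere in memory and in TSV
exports; BED exports follow BED semantics.  piggyBac integrates at TTAA
tetranucleotides; a clone genotype stores the TTAA start coordinate and an
orientation (+/−), the reference strand along which the transposon's
internal promoter points.

Csp6I recognises G^TAC and leaves a 2 nt 5′ TA overhang.  With `g` the
motif start, the first base of the downstream fragment is `g+1` on the
plus strand and `g+3` on the minus strand; these two *cut coordinates* are
where splinkerette read 5′ ends pile up, and the simulator and the site
caller share them as a single constant.  A unique alignment is anchored to
the nearest cut on its own strand within a 3 bp tolerance (measured to the
cut position, not the motif start), ties breaking toward the smaller motif
coordinate for determinism.

The primer-side convention: a sense (+) insertion is read from the plus
strand, anchored at the nearest motif fully 5′ of the TTAA; an antisense
(−) insertion is read from the minus strand, anchored at the nearest motif
fully 3′ of it.  Because simulator and caller share this convention, the
read strand of a site doubles as the orientation of the insertion it
represents, and orientation round-trips through the pipeline.

## Read model

A read is `6 nt barcode + 1 ligation base + genomic sequence` (default
read length 50, so 43 genomic bases).  Barcodes are drawn from {A,G,T}
(IUPAC D); the ligation base is fixed to "T", the first base of the TA
overhang — it is trimmed together with the barcode, so the choice is
inert.  Base qualities are constant ("I"); no sequencing-error model is
applied by default (an optional uniform substitution rate exists but is
off).

Two read-length regimes exist:

* **Noise-free (default).**  The genomic portion continues at full read
  length past the transposon junction, so every emitted read is uniquely
  alignable and the truth sidecar is recovered exactly.  This is the mode
  behind the recovery guarantees in the test suite.
* **`clip_at_junction=True`.**  The read stops at the junction and runs
  into a fixed library adapter.  This reproduces the real failure modes of
  a 4-cutter splinkerette assay: fragments shorter than ~16 bp align
  non-uniquely, sub-7 bp fragments fall under the retention floor, and
  adapter remnants shorter than the 5 nt removal overlap block alignment.
  The sidecar's `detectable` flag (computed by re-running the exact
  trim/align contract per site) marks which sites survive, and the
  round-trip tests assert exact recovery of that subset.

Trimming removes the first 7 bases, then the longest 3′ suffix exactly
matching a prefix of the adapter (minimum overlap 5 nt — deterministic and
oracle-checkable, in place of heuristic adapter trimmers), and retains
reads of 7 bp or longer; every discard carries a reason code, and counts
are conserved at every stage (assigned + unmatched = input; retained +
discarded = assigned; accepted + off-site + multi-mapped + unmapped =
trimmed).

## Alignment

Site calling requires exact, unique alignment across both genome strands —
a deliberate simplification standing in for a short-read aligner, adequate
because the synthetic genomes are uniform-random and the reads error-free.
The contract (5′ coordinate, strand, uniqueness) is what matters; an
external aligner can be substituted behind the same interface for real
data.  Two implementations exist and are tested against each other: an
exhaustive string scan, and a batch path that seeds each pattern with its
first 20 bases as an exact 2-bit-packed integer, scans the genome's packed
words once, and verifies candidates by direct comparison (seeding can only
generate candidates, never wrong answers).  Identical read sequences are
collapsed before alignment; multiplicities are restored when counting.

## Synthetic screen generator

The generator's defaults are the study conditions the pipeline is designed
around, and the acceptance tests run at these values:

| parameter | default | rationale |
|---|---|---|
| clones per library | 10⁴ | large enough for tens-to-hundreds of resistant clones per screen |
| insertions per clone | Poisson(6) truncated to [1, 11] | simplest law matching the observed range 1–11 and mean ≈6 |
| orientation balance | 0.5 | sense/antisense insertions are observed in equal proportion |
| activation window | 64 kb upstream of the first coding base, gene's own strand | longest distance at which activation has been observed |
| signal depth | log-normal, median 300, σ=0.5, floor 100 | only ">100 reads" is constrained; the law above it is a free choice |
| background | 10³ sites, Poisson(5) truncated to [1, 50] | low-count mis-ligation/carry-over family, distinct from signal |
| genome | 5 Mb uniform-random, 12 genes of 20 kb, one per slot | desk-scale stand-in for a mammalian genome; slots keep each gene's activation window and 25 kb assignment margin disjoint |

Gene placement guarantees at least one TTAA and one GTAC inside every
activation window (motifs are injected in the vanishingly rare case the
random sequence lacks one) and exactly one `resistance_driver` per
scenario.  Selection: a clone survives iff it carries a sense-orientation
insertion whose TTAA lies within the window upstream of the driver's
first coding base ("upstream" measured from the first coding base because
reported activation distances are quoted relative to the open reading
frame); the cooperative rule additionally requires any insertion inside
the modifier's gene body.  A truth table records the causal insertions.

What the generator does **not** emulate: PCR amplification bias, chimeric
reads, sequencing errors (by default), diploidy/copy number, insertion
hotspots or chromatin accessibility.  Passing tests therefore demonstrate
the correctness and statistical behaviour of the analysis under the
assay's idealised statistical structure, not robustness to every artefact
of real libraries.

## Background model and enrichment

Background counts are modelled as Poisson truncated to [1, 50]; the mean
is fitted by maximum likelihood (bounded scalar minimisation of the
truncated negative log-likelihood, converged well below 10⁻⁶) on counts
≤50 only, so signal sites cannot leak into the fit; at least 10 background
counts are required, otherwise the caller is directed to fixed-threshold
mode.  The enrichment threshold is the smallest integer k with
P(X ≥ k | μ) < α (α = 0.05), computed by summing the mass function
upward; `fixed_threshold` mode returns 101, reproducing the ">100 reads"
convention literally.  Whether the p < 0.05 filter refers to a fitted tail
or the fixed count convention is ambiguous in practice, so both modes are
provided.  No multiple-testing correction is applied by default (matching
the screen convention); Benjamini–Hochberg q-values are available as an
optional annotation.

Replicate screens of the same library re-sample the same clones, so a
site key — (chromosome, Csp6I coordinate, read strand) is the insertion
identity throughout — appearing in several replicates of one library
counts as one independent event; the same key in different libraries
counts once per library.

## Gene assignment and effect prediction

Events annotate every gene whose span ±25 kb contains them (measured from
the gene span, an interval-tree query verified against a linear scan);
multi-gene assignment is deliberate and events with no gene are kept
unassigned as potential non-coding hits.  Orientation is sense when the
insertion orientation matches the gene strand.  Position is upstream /
intragenic / downstream; upstream distances are measured to the first
coding base, downstream distances to the annotated gene end (a stand-in
for the poly-adenylation site).  Effect prediction is a total function:
sense + upstream + ≤64 kb → activation; intragenic → disruption
(either orientation); everything else → ambiguous, because antisense
upstream insertions have been observed to either raise or lower
expression.  Gene ranking is (number of cell lines, number of independent
insertions, total reads) descending.

## Clonal deconvolution

Per-colony fractions are computed over the colony's total reads; sites
strictly below 1% are removed and the 10 highest-fraction sites kept
(ties to the smaller coordinate), matching the expected 1–10 true
insertions per cell.  Colonies are clustered by single-linkage on Jaccard
similarity of retained site sets with threshold 0.5 — high enough to
separate disjoint signatures, tolerant of one dropped site in small ones;
a cluster's signature is the union of member sets so a site lost to
sampling in one colony is retained.  Cluster output order is
permutation-invariant (sorted by smallest member site).

Multi-clone colonies (mixtures) have no published detection procedure, so
one is formalised here: a colony is excluded when, after clustering the
remaining colonies, its retained set is a strict superset of the
signatures of two or more distinct clusters (each allowed one missing
site) and is fully explained by their union.  A colony identical to
another colony is structurally never flagged: the duplicate links the
would-be components into a single cluster.

Founder signatures are annotated to genes with the activation window
(default padded to 66 kb in the clonal flow, because a site's Csp6I
anchor sits up to a few hundred bases further from the gene than the
insertion it represents).  A gene is a `standalone_driver` when some
founder carries it alone; a `co_occurring_modifier` when it appears in at
least one founder, never alone, and some other gene is present in every
founder that carries it.  The classifier is intentionally strict; its
known fragile case — a clone at the 11-insertion maximum whose
lowest-coverage site is the driver's, which the top-10 filter then drops —
is visible in the seeded acceptance runs at the expected low rate.

## Coverage calculator

Two conventions for the required mean λ coexist deliberately: a 0.01-step
upward grid scan (the form in which design means like 3.0 and 4.75 are
quoted) and the continuous root of P(X ≤ k−1 | λ) = p by bisection to
10⁻⁹ (used when unrounded values feed downstream arithmetic).  Both use
direct mass-function summation and are tested against closed forms
(λ = −ln p for k = 1) and against scipy.  Spacing is gap = window/λ;
insertions = strand_factor × genome/gap with strand_factor 2 encoding
that only one orientation activates; clones = insertions / mean per
clone.  Headline figures are rounded to two significant figures
(half-up) at the reporting layer only, and sequentially — the clone count
is derived from the already-rounded insertion count, the way such figures
are normally quoted; raw values are always retained.  The 21.3 kb gap is
read as the spacing between *activating* (sense-orientation) insertions.

## Problem sizes

The test suite runs everything at desk scale: 1 Mb genomes with 3 genes
for unit tests, and the full default conditions (5 Mb, 12 genes, 10⁴
clones) for the 20-seed recovery studies.  These sizes give the recovery
statistics comfortable margins (driver ranked first with ~2× the
insertion count of the best passenger) while keeping a complete 20-run
study to a few minutes.
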