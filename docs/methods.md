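# Methods

`lrbin` bins metagenomic long reads and assembled contigs onto a taxonomy
and onto functional classification systems, starting from DNA-to-protein
alignments produced by a frame-shift-aware aligner such as LAST. This
note records the models and rules implemented, the parameters that
matter, the numerical conventions, and the design choices made where the
problem statement left the design open.

## Why interval unions

The short-read ("naive") LCA rule places a read on the lowest common
ancestor of the taxa carrying its near-best alignments. Its implicit
assumption — that all alignments compete for one gene — breaks on reads
of tens of kilobases that span many genes: pooling near-best alignments
across genes drives every multi-gene read toward high, uninformative
taxa.

The interval-union rule treats the read as a one-dimensional space
instead:

1. **Partition.** The read is cut at every alignment start and end,
   producing atomic pieces; each alignment interval is an exact union of
   pieces. Pieces covered by no alignment are discarded.
2. **Local significance.** On each piece, an alignment is *significant*
   when its bit score lies within `topPercent` (default 10%) of the best
   bit score among alignments covering that piece, boundary inclusive
   (`bit >= (1 - topPercent/100) * best`). Because significance is
   local, one alignment can be significant over some of its span and
   outcompeted elsewhere.
3. **Interval unions.** Each taxon `t` with alignments gets
   `I(t)` = the union of pieces carrying a significant alignment of `t`.
   A post-order traversal merges each node's union into its parent, so
   an inner node's `I(s)` is the union over its subtree, with
   overlapping and abutting intervals merged.
4. **Placement.** Let `D` be the measure of the union of *all* alignment
   intervals of the read (its covered portion). A node qualifies when
   `|I(s)| >= (percentToCover/100) * D` (default 80%, boundary
   inclusive) and none of its children qualifies. Since `I` only grows
   toward the root, nodes meeting the coverage bar form an
   ancestor-closed set and the qualifying nodes are its minimal
   elements. A unique qualifying node receives the read; several resolve
   to their LCA; a read with no taxon-mapped alignment is unassigned.

All coordinates are 0-based half-open on the forward strand of the read;
GFF3 export converts at the boundary. Strand is ignored for interval
unions (the placement rule is strand-free) but honored where the rules
below require it.

### Conventions and edge cases

- **Denominator.** `D` includes alignments whose reference accession has
  no taxon mapping — they attest real homology even when the database
  row is unresolvable. Consequently a read rich in unmapped alignments
  may offer no node that reaches the coverage bar; such a read (if it
  has at least one mapped alignment) is binned to the root, the most
  conservative placement, rather than dropped. With fully mapped
  alignments the root always covers 100% of `D` and this fallback never
  triggers.
- **Boundaries.** `topPercent` and `percentToCover` comparisons are
  inclusive ("within 10%" reads as `>=`); the behavior at both
  boundaries is pinned by tests.
- **Monotonicity.** Raising `percentToCover` moves a read's placement
  rootward *when its qualifying node is unique* (the covering set is
  then a root chain). With tied sibling qualifiers the LCA rule can
  legitimately move the read deeper when one sibling drops below the
  higher bar, so no global monotonicity is claimed.
- **Reduction.** When all alignments of a read span one identical
  interval and map to leaf taxa, the interval-union rule reproduces the
  naive LCA for every `topPercent`. (If one significant taxon is a
  strict ancestor of another, the two rules differ by design: the
  interval-union rule prefers the more specific node.)

## Strong-domination filtering

Aligning long reads against a comprehensive protein database yields many
near-duplicate alignments per read segment. Before binning, an alignment
`b` is discarded when some alignment `a` of the same read *strongly
dominates* it: the overlap covers at least
`MinPercentCoverToStronglyDominate` (default 90%) of `b` and
`(TopPercentScoreToStronglyDominate/100) * bit(a) > bit(b)` (default
90%, strict). Strictness makes mutual domination impossible, so judging
every alignment against the original set is order-independent and
idempotent; the per-read best alignment always survives. The definition
states no strand condition and the filter is strand-blind by default; a
`require_same_strand` switch is provided for sensitivity analyses.

## Functional binning

An alignment `a` *dominates* `b` for functional purposes when (all
strict) it covers more than `MinPercentCoverToDominate` (default 50%) of
the read covered by `b`, scores strictly higher, and lies on the same
read strand. The strand clause keeps genes on opposite strands from
suppressing each other. A read's classes are the union, per namespace
(InterPro, eggNOG, KEGG, ...), of the classes of its non-dominated
("representative") alignments; a read can belong to many classes, and
contributes its full weight to each. Optionally a dominating alignment
must be taxonomically *compatible* with the read's taxonomic bin —
compatible meaning on the same lineage, in either direction: a
family-level reference is compatible with a species-level bin and a
strain-level reference with a genus-level bin. (Restricting
compatibility to descendants only would silently discard conserved,
high-level references; the symmetric reading is the package's choice.)

The short-read *best-hit* baseline assigns the classes of the
highest-scoring alignment that has any class in the namespace —
unclassified alignments never block a classified one.

## Reporting weights and minimum support

Four weight modes are supported per read: `read_count` (1),
`total_length` (read length), `aligned_bases` (measure of the union of
its alignment intervals — the default, as it down-weights long unaligned
stretches), and `contig_reads` (the number of reads contained in an
assigned contig, for binning assemblies).

A taxon is only reported when it accumulates at least `minSupport`
(default 0.05%) of the total *assigned* weight; unassigned reads are
excluded from the total so that database gaps do not deflate the
threshold. Under-supported nodes are processed in post-order: each
transfers its accumulated weight (its own plus anything pushed into it)
to its parent, and a parent is re-tested after receiving pushed weight,
so deficits cascade until an ancestor — ultimately the root — retains
them. Total weight is conserved exactly. The alternative convention of
testing subtree-summarized weights was considered and rejected because
cascading direct weights keeps the invariant "every reported node
individually meets the threshold" inspectable per node.

## Evaluation

Against per-read truth, *sensitivity* is the percentage of all reads
assigned to the correct taxon or one of its descendants; *precision* is
the percentage of correctly assigned reads among reads binned to any
node that is not a strict ancestor of the correct taxon (assignments to
ancestors are uninformative rather than wrong). Unassigned reads count
in neither numerator; precision is reported as missing when its
denominator is empty. "Correct" includes descendants in both metrics,
by symmetry.

## Synthetic data

The **worked-example fixture** is an 8-species taxonomy (genera P and Q
under family R) and a 120 bp read with one equal-score alignment per
species: A [0,80), B [30,100), C [10,70), D [40,90), E [50,90),
F [45,80), G [55,85), H [50,70). The covered portion is [0,100);
species coverages run from 80% (A) down to 20% (H); `I(P)` and `I(R)`
both cover 100% and `I(Q)` 45%. These intervals were chosen to satisfy
all of the stated constraints of the example simultaneously; with
defaults the read is placed on A, and shrinking A's alignment to [0,60)
moves it to genus P.

The **random generator** emulates a leave-one-out database-completeness
benchmark. Defaults, chosen once as a desk-scale but realistic shape:
12 species in genera of 2-4 under one family; 100 reads of 5-20 kb
tiled with 3-8 genes; per gene, a full-length alignment to the source
species, partial alignments (60-85% of the gene, probability 0.7 per
sister) to sister species, and off-target alignments to other genera at
rate 0.05; score noise SD 2 bits. Bit scores are 2 bits per codon times
the aligned length, so partial homologs score proportionally lower —
the property that makes local significance work. Chimeric reads (rate
0 by default) join two sources at the read midpoint; their truth label
is the LCA of the sources, a reporting convention for reads with no
single correct species. `leave_out` suppresses every alignment to the
listed taxa without consuming different random draws, so a left-out run
is identical to its reference run except for the suppressed alignments.

What the generator does *not* emulate: base-level sequencing errors and
frame-shift structure (alignments are simulated directly, so aligner
robustness is out of scope), unequal species abundances, horizontal
transfer, and reference mislabeling. Passing tests therefore validate
the binning algebra and its implementation, not end-to-end accuracy on
real noisy reads.

## Problem sizes in the test and acceptance suites

Property suites run on 100-200 random instances with integer coordinates
up to 200 and up to 12-15 alignments per read — small enough for the
per-base brute-force oracles to be exact and fast, large enough to cover
the combinatorics of piece/score/taxon interactions. Simulation-recovery
checks use 30-40 reads over 12-24 species, which the noise-free
construction makes deterministic in outcome. The acceptance script
reports quantities of the worked-example fixture, which are exact.

## Known limitations

- All per-read processing is in-memory; there is no streamed two-pass
  conversion for very large alignment files.
- Scores parsed from MAF are converted to bits only when the header
  supplies `lambda` and `K`; otherwise raw scores pass through (ratio
  thresholds remain meaningful under any monotone score, but absolute
  score comparisons across files do not).
- No handling of merged/deleted taxon ids or taxonomy versioning; the
  taxonomy supplied is taken as-is.
- Functional class hierarchies (pathway rollups, ontology closures) are
  out of scope; classes are opaque identifiers.
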