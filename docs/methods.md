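# Methods

## Data model

Coordinates are 0-based half-open everywhere except human-readable reports
and VCF output (1-based, per spec).  A *breakend* is `(chrom, pos, side)`:
`head` means the rearranged allele arrives at `pos` from smaller reference
coordinates (the retained flank is at coordinates <= pos), `tail` means it
continues from `pos` toward larger coordinates.  A junction is an unordered
pair of breakends, stored canonically (lexicographic) so the same physical
adjacency compares equal regardless of read direction.

## Junction extraction

A read's alignment records are chained along the read.  Segments shorter
than `min_seg_len` (default 200 bp) are dropped; among segments overlapping
on the read by more than `max_overlap` (50 bp), the higher identity x
length score wins.  Secondary/supplementary status is ignored — all records
of a read compete.

Adjacent segments are *colinear* when they share chromosome and strand and
the reference advance is consistent with the read advance within
`colinear_gap_tol` (default 1000 bp).  This single rule covers both small
indels (consistent advances) and rejects large unaligned inserts (read
advance far exceeds reference advance).  Every non-colinear adjacency emits
one junction; the left segment contributes its exit breakend, the right its
entry breakend.  With junction micro-homology the two alignments may
overlap slightly on the reference; each breakend is taken from its own
segment's alignment edge, so the left segment defines the left breakend
(a deliberate, documented asymmetry of at most the homology length).

Defaults were chosen to tolerate nanopore indel noise while keeping >= 1 kb
events visible; they are surfaced in `DetectionThresholds`, with two
shipped presets: `EXACT_PRESET` (match tolerance 200 bp, for clean
alignments) and `NOISY_PRESET` (1000 bp, for error-prone reads).  A
consequence worth noting: insertions shorter than the colinearity tolerance
(e.g. solitary Alu-sized inserts at the default 1 kb) are absorbed as
colinear and not detected; detecting them requires lowering the tolerance.

## Grouping and control subtraction

Two reads are linked iff they share one junction — both breakends within
`match_tol`, identical sides.  Groups are connected components of this
relation; components with fewer than `min_reads` (default 3, configurable
down to 1) are discarded.  Junction clustering is single-linkage within a
(chrom, side, chrom, side) bucket, sorted by position so only nearby pairs
are compared.

A group is removed when any control read carries any of its signature
junctions within tolerance — removal by a single shared junction, not the
whole signature (the stricter variant is a config away).  Controls are
applied successively and the remaining count recorded after each, giving
the familiar decreasing subtraction curve; the surviving set is provably
independent of control order, and the suite asserts this by permutation.

## Breakpoint-level consensus

Each group becomes one ordered, oriented walk over the reference.  This is
deliberately a coordinate-level stand-in for assembling the reads into a
consensus sequence and realigning it: the linking stage consumes only
coordinates, orders, and orientations, so no base-level consensus is
computed.

Junction observations are clustered at `match_tol`; the clusters must form
a simple path under within-read co-occurrence.  Members traverse the event
in both directions, so each read is oriented onto the path (multi-junction
reads by cluster order; single-junction reads by breakend side, and — for
inversion-type junctions whose two breakends share a side — by breakend
position).  Consensus coordinates are per-cluster medians with even-count
ties broken toward the smaller coordinate, for robustness to alignment-end
wobble and determinism.  Interior segments are pinned between consecutive
consensus breakends; outer segments extend to the furthest member
alignment.  Groups whose members disagree on order after reorientation are
emitted to an `unresolved` report, never guessed.

## Linking into derivative chromosomes

Each consensus yields two open ends (position + extension direction into
unrearranged sequence).  Link candidates are facing end pairs — one
extending toward larger coordinates at p1, one toward smaller at p2, same
chromosome — with no breakpoint of any group strictly inside the interval
between them.  A breakend exactly at an open-end position does not block
(strict interiority; degenerate in practice).  Member read extents from the
two sides of a short fragment may overlap (p1 > p2); this is still a valid
link — both extents cover identical reference — and the overlap is trimmed
during path assembly so colinear merging sees exact contiguity.  An open
end with no breakpoint between it and a chromosome end may instead be
closed at that terminus; chromosome-arm structure (centromeres,
acentric/dicentric questions) is out of scope, so derivatives simply extend
to toy-chromosome ends.

The solver enumerates complete assignments (every end linked once or closed
at a terminus) by backtracking with union-find cycle pruning.  Zero valid
assignments is an inconsistency error; more than one is an ambiguity error
listing the alternatives (`--enumerate` prints them).  Uniqueness is the
scientific point: a reconstruction is only trustworthy when the data admit
exactly one arrangement.  The test suite contains an independent
brute-force oracle — recursive enumeration of all end pairings with
independently re-derived validity rules — and asserts agreement on 200
random consensus sets of up to 8 groups plus the canonical fixture.

Maximal fragments come from merging colinear adjacent path segments
(default tolerance 100 bp; seams are exact on both clean and jittered
data because interior boundaries are pinned by consensus coordinates).
Deletions are interior gaps of at least `min_size` (default 10 kb) in the
per-chromosome union of fragment intervals; terminal gaps are not deletions.
Overlapping fragment claims by two consensuses violate the single
rearranged allele assumption and surface as linking errors rather than
silently merged coverage.

## Classification, gene impact, expression

Event categories apply in order: (1) inter-chromosomal junctions or
membership in a linked multi-group component → chromothripsis member;
(2) backward reference loops → tandem multiplication (span > 500 bp) or
repeat expansion (<= 500 bp; the two differ in unit size, not geometry, and
the cutoff is a configurable design choice); (3) unaligned inserts matching
a mobile-element consensus at >= 80% identity over >= 50% of the insert →
mobile-element insertion (the matcher is edlib infix alignment against a
user-supplied element library — adequate for toy consensus libraries, and a
stand-in for genome-wide repeat annotation, which is out of scope); (4)
otherwise `other`.

Gene impact: a gene wholly inside a deletion is `deleted`; a gene containing
a breakend strictly inside it, or cut by a deletion boundary, is
`disrupted`; otherwise `intact`.  Expression uses the ddCt closed form:
per-sample ΔCt = Ct_gene − Ct_reference, ΔΔCt = patient mean ΔCt − control
mean ΔCt, fold = 2^−ΔΔCt, with the replicate SD taken over per-replicate
fold changes.

## The simulator

The toy reference is uniform-random sequence (no repeat structure — toy
chromosomes cannot model mappability artifacts, reference gaps, or
segmental duplications, so passing tests say nothing about alignment
difficulty on real genomes; alignment itself is consumed, not produced).
Chromosomes are 12 Mb and 6 Mb — large enough to host deletions at their
true printed scale (hundreds of kb to Mb) while keeping a full replay under
a few seconds — and the canonical fixture's deletion sizes, fragment
counts, and chromosome-of-origin assignments match the published event
exactly.  True breakpoint coordinates of the real patient are not public;
the fixture's coordinates are synthetic, and the fixed orientation vector
(8 of 19 fragments inverted, at least the published minimum of inversions)
is a documented constant — none of the reconstruction counts depend on
which fragments are inverted.  Three fragments are < 50 kb so single reads
span them, merging their flanking junctions into shared read groups (17
junctions → 14 groups), mirroring how tiny fragments behave in real data.

Reads are sampled uniformly per derivative with log-normal lengths
(defaults mean 11,451 bp / sd 9,000 bp, echoing a real nanopore run;
the fixture replay uses mean 15 kb so tiny fragments are reliably spanned
at x20), truncated to [500 bp, sequence length], on a uniformly random
strand.  In error-free mode each read's exact reference segment chain is
emitted — the alignment oracle.  With nonzero error rates, base errors are
applied to emitted sequences, and the chains receive alignment-endpoint
wobble: junction-facing segment ends are trimmed by up to
`min(300, 4000 x total error rate)` bases (200 bp at 5% error), consistently
on read and reference, emulating how aligners stop short of breakpoints in
noisy reads.  This is a model of alignment behavior, not of a specific
aligner; it produces the inward-biased breakend scatter the tolerance-based
matching is designed to absorb.

Control cohorts carry each pooled polymorphic event independently at its
allele frequency; event loci are drawn away from plan breakpoints, so by
construction controls never carry planted chromothripsis junctions.  Random
plans tile two chromosomes into fragments and interior deletions, anchor
derivative 1 from chromosome 1's left terminus to chromosome 2's right
terminus (derivative 2 the reciprocal), scramble and orient the interior
fragments, and reject layouts with colinear adjacencies (unobservable
junctions) — drawing again up to a bounded retry count.

All randomness flows through named, seeded numpy generators; identical
seeds give byte-identical outputs, which the suite asserts.

## Problem sizes and numerical choices

The fixture replay simulates ~13,000 reads over ~16.5 Mb of derivative
sequence and completes in a few seconds; plan-recovery properties use 200
random plans on 0.6 + 0.4 Mb toy chromosomes at x16 with 9 kb mean reads,
chosen so the whole suite stays interactive while junction support per
breakpoint (~15 reads) matches the fixture's regime.  The linking oracle
runs on consensus sets of at most 8 groups, where exhaustive enumeration is
exact and fast.  Tie-breaks are uniformly toward the smaller coordinate;
reconstruction naming orders derivatives by starting terminus, and walks
are direction-canonical, so reversing every consensus frame yields the
identical fragment set (asserted).

## Known limitations

- No base-level consensus or realignment; breakpoint coordinates are only
  as good as the alignment endpoints.
- Copy-number is ignored: a duplicated fragment used twice by the true
  allele violates the single-use assumption and surfaces as a linking
  error, not a reconstruction.
- Read depth is not used (no CN-based corroboration of deletions).
- The control filter needs the shared event to produce a junction within
  match tolerance; population indels below the colinearity tolerance are
  invisible to both detection and filtering.
- The simulator's error model perturbs alignment endpoints; it does not
  simulate chimeric reads, adapter artifacts, or base-caller-specific error
  profiles.
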