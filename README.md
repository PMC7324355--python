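# chromolink

Reconstruction of complex germline rearrangements — chromothripsis — from
long-read split alignments.

## The problem

A single catastrophic event can shatter parts of two chromosomes into
dozens of fragments that rejoin in scrambled order and orientation, forming
derivative chromosomes.  Karyotyping sees only the gross translocation;
short reads rarely span the breakpoints.  Long reads do: one read can cross
one or more rearrangement junctions, and its alignment splits into a chain
of segments whose adjacencies reveal novel junctions.  `chromolink` turns
those chains into a full derivative-chromosome reconstruction:

1. **Detect** — parse PAF/MAF alignments into per-read segment chains; every
   adjacent, non-colinear segment pair yields a junction between two
   oriented breakends.
2. **Group** — reads sharing a junction (both breakends within tolerance,
   same sides) form connected components: groups of reads over the same
   rearrangement.
3. **Filter** — groups whose junctions also occur in any of a cohort of
   unaffected controls are subtracted, leaving patient-only events.
4. **Consensus** — each group is merged into one ordered, oriented walk over
   the reference with median breakpoint coordinates.
5. **Link** — each consensus has two *open ends* where it runs into
   unrearranged sequence.  Two open ends are joined when they face each
   other along the reference with no breakpoint in between; an end with a
   clear run to a chromosome end is closed at that terminus.  A complete,
   cycle-free assignment of all ends yields the derivative chromosomes —
   and the arrangement must be **unique**, otherwise the ambiguity is
   reported as an error, never guessed away.
6. **Infer deletions** — reference intervals covered by no fragment of any
   derivative.  These are recoverable only from the completed
   reconstruction, not from any single junction.
7. **Annotate** — classify residual events (tandem multiplications, repeat
   expansions, mobile-element insertions by alignment to a consensus
   library), call gene impact (deleted / disrupted / intact), and compare
   expression by the ddCt method (fold change = 2^−ΔΔCt).

A first-class simulator generates toy genomes, planted rearrangement plans
with exact truth tables (fragments, junctions, deletions), log-normal long
reads with oracle alignment chains, and control cohorts carrying
population-polymorphic events — so the whole pipeline is testable without
any external data.  The canonical fixture replays a germline t(8;18)-style
chromothripsis: 19 fragments forming two derivatives (14 + 5), with four
large deletions on the chr8 analog (456, 1957, 520, 3529 kb) and one on the
chr18 analog (1528 kb).

## Worked example

Replay the canonical fixture end to end (simulate error-free reads at x20,
detect, group, consensus, link, infer deletions, report):

```bash
chromolink run-all --seed 1 --out-dir out/
# 2 derivatives, 19 fragments, 5 deletions -> out
```

`out/report.md` then contains, among other sections:

```
## Derivative chromosomes: 2 (19 fragments)

### der1: 5 fragments from 3 groups

| rank | chrom | start | end | strand | length |
|---|---|---|---|---|---|
| 1 | chr18t | 0 | 1200000 | + | 1200000 |
| 2 | chr8t | 11260000 | 11300000 | - | 40000 |
| 3 | chr8t | 6053000 | 6553000 | - | 500000 |
| 4 | chr8t | 11300000 | 11700000 | - | 400000 |
| 5 | chr8t | 11700000 | 12000000 | + | 300000 |
```

Reading the table: derivative 1 starts at the chr18-analog terminus, runs
through its first 1.2 Mb, then jumps into the chr8 analog and traverses
four scrambled fragments (three inverted, one of them a tiny 40 kb piece)
before reaching the chr8-analog terminus.  The deletions section lists the
five uncovered intervals — e.g. `chr18t:2272000-3800000 (1528 kb)` — which
exist only because the *complete* reconstruction shows no derivative claims
them.

The same stages are available piecewise (`simulate`, `detect`, `group`,
`filter`, `link`, `annotate`, `report`) and as library functions
(`chromolink.run_pipeline`, `chromolink.link`, ...).  The `link` stage also
writes consensus junctions as MATEID-paired VCF BND records.

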