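"""Ordering and orienting consensus rearrangements into derivative
chromosomes, with deletion inference from the completed reconstruction.

Each consensus rearrangement has two *open ends* where its outermost
segments continue into unrearranged reference sequence.  Two open ends may
be joined when they face each other along the reference with no other
breakpoint in between; an open end with no breakpoint between it and a
chromosome terminus may instead be closed at that terminus.  A complete
assignment of every open end (one link or one terminus each) that contains
no cycle yields a set of simple paths: the derivative chromosomes.

The arrangement must be unique: zero valid assignments is an inconsistency
error, more than one is an ambiguity error that lists the alternatives —
never a silent guess.  Deletions are the reference intervals covered by no
fragment of any derivative; they are recoverable only from the full
reconstruction, not from any single rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import FORWARD, REVERSE, OrientedInterval
from .consensus import ConsensusRearrangement

TOWARD_LARGER = "toward_larger"
TOWARD_SMALLER = "toward_smaller"

FIRST = "first"
LAST = "last"


class LinkInconsistencyError(ValueError):
    """No valid way to arrange the consensus rearrangements."""


class LinkAmbiguityError(ValueError):
    """More than one valid arrangement exists."""

    def __init__(self, message: str, alternatives: list) -> None:
        super().__init__(message)
        self.alternatives = alternatives


@dataclass(frozen=True)
class OpenEnd:
    """The reference-facing flank of a consensus's outermost segment."""

    group_index: int
    terminal: str  # FIRST or LAST
    chrom: str
    pos: int
    direction: str  # TOWARD_LARGER or TOWARD_SMALLER


@dataclass(frozen=True)
class LinkCandidate:
    """Two facing open ends with no intervening breakpoint.

    ``interval`` is the unrearranged reference between them (empty or
    negative-width when member read extents overlap inside the shared
    fragment; the overlap is trimmed during path assembly).
    """

    end_a: OpenEnd  # extends toward larger coordinates
    end_b: OpenEnd  # extends toward smaller coordinates
    interval: tuple[str, int, int]


@dataclass(frozen=True)
class Fragment:
    """A maximal colinear (breakpoint-to-breakpoint) piece of a derivative."""

    chrom: str
    start: int
    end: int
    strand: str
    derivative: str
    rank: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DerivativeReconstruction:
    name: str
    path: list[OrientedInterval]
    group_ids: list[str]
    start_terminus: tuple[str, int]
    end_terminus: tuple[str, int]
    terminal_status: tuple[str, str] = ("reaches_chromosome_terminus", "reaches_chromosome_terminus")


@dataclass(frozen=True)
class DeletionCall:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def open_ends(cr: ConsensusRearrangement) -> tuple[OpenEnd, OpenEnd]:
    """The two reference-facing flanks of a consensus walk.

    The group index is filled by :func:`build_link_graph`; here it is 0.
    """
    return _open_ends_indexed(cr, 0)


def _open_ends_indexed(cr: ConsensusRearrangement, idx: int) -> tuple[OpenEnd, OpenEnd]:
    first, last = cr.segments[0], cr.segments[-1]
    if first.strand == FORWARD:
        e1 = OpenEnd(idx, FIRST, first.chrom, first.start, TOWARD_SMALLER)
    else:
        e1 = OpenEnd(idx, FIRST, first.chrom, first.end, TOWARD_LARGER)
    if last.strand == FORWARD:
        e2 = OpenEnd(idx, LAST, last.chrom, last.end, TOWARD_LARGER)
    else:
        e2 = OpenEnd(idx, LAST, last.chrom, last.start, TOWARD_SMALLER)
    return e1, e2


@dataclass
class LinkGraph:
    crs: list[ConsensusRearrangement]
    ends: list[OpenEnd]  # 2 * len(crs), ends[2i], ends[2i+1] belong to cr i
    candidates: list[LinkCandidate]
    terminus_capable: dict[int, tuple[str, int]]  # end index -> terminus coordinate
    options: list[list[tuple[str, int]]] = field(init=False)  # per end: ("link", j) / ("terminus", -1)

    def __post_init__(self) -> None:
        end_index = {e: i for i, e in enumerate(self.ends)}
        self.options = [[] for _ in self.ends]
        for cand in self.candidates:
            ia, ib = end_index[cand.end_a], end_index[cand.end_b]
            self.options[ia].append(("link", ib))
            self.options[ib].append(("link", ia))
        for i in self.terminus_capable:
            self.options[i].append(("terminus", -1))


def build_link_graph(
    crs: Sequence[ConsensusRearrangement], chrom_lengths: Mapping[str, int]
) -> LinkGraph:
    """All facing end pairs plus terminus capabilities.

    A breakpoint exactly at an open-end position does not block (strict
    interiority).
    """
    crs = list(crs)
    ends: list[OpenEnd] = []
    for i, cr in enumerate(crs):
        ends.extend(_open_ends_indexed(cr, i))
    breakends: dict[str, list[int]] = {}
    for cr in crs:
        for b in cr.breakends():
            breakends.setdefault(b.chrom, []).append(b.pos)
    for v in breakends.values():
        v.sort()

    def blocked(chrom: str, lo: int, hi: int) -> bool:
        if lo > hi:
            lo, hi = hi, lo
        import bisect

        pos = breakends.get(chrom, [])
        i = bisect.bisect_right(pos, lo)
        return i < len(pos) and pos[i] < hi

    candidates: list[LinkCandidate] = []
    for i, ea in enumerate(ends):
        if ea.direction != TOWARD_LARGER:
            continue
        for j, eb in enumerate(ends):
            if j == i or eb.direction != TOWARD_SMALLER or eb.chrom != ea.chrom:
                continue
            if ea.group_index == eb.group_index:
                continue  # a consensus cannot close on itself
            if blocked(ea.chrom, ea.pos, eb.pos):
                continue
            candidates.append(
                LinkCandidate(end_a=ea, end_b=eb, interval=(ea.chrom, ea.pos, eb.pos))
            )
    terminus_capable: dict[int, tuple[str, int]] = {}
    for i, e in enumerate(ends):
        L = chrom_lengths[e.chrom]
        if e.direction == TOWARD_SMALLER and not blocked(e.chrom, 0, e.pos):
            terminus_capable[i] = (e.chrom, 0)
        elif e.direction == TOWARD_LARGER and not blocked(e.chrom, e.pos, L):
            terminus_capable[i] = (e.chrom, L)
    return LinkGraph(crs=crs, ends=ends, candidates=candidates, terminus_capable=terminus_capable)


Assignment = dict[int, tuple[str, int]]  # end index -> ("link", other) / ("terminus", -1)


def enumerate_arrangements(graph: LinkGraph, limit: int = 64) -> list[Assignment]:
    """All complete, cycle-free assignments of the open ends (up to limit)."""
    n_ends = len(graph.ends)
    parent = list(range(len(graph.crs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    assignment: Assignment = {}
    solutions: list[Assignment] = []

    def backtrack() -> None:
        if len(solutions) >= limit:
            return
        try:
            i = next(k for k in range(n_ends) if k not in assignment)
        except StopIteration:
            solutions.append(dict(assignment))
            return
        for kind, j in graph.options[i]:
            if kind == "link":
                if j in assignment:
                    continue
                ga, gb = graph.ends[i].group_index, graph.ends[j].group_index
                ra, rb = find(ga), find(gb)
                if ra == rb:
                    continue  # would close a cycle
                saved = parent[ra]
                parent[ra] = rb
                assignment[i] = ("link", j)
                assignment[j] = ("link", i)
                backtrack()
                del assignment[i]
                del assignment[j]
                parent[ra] = saved
            else:
                assignment[i] = ("terminus", -1)
                backtrack()
                del assignment[i]

    backtrack()
    return solutions


def _assemble_paths(graph: LinkGraph, assignment: Assignment) -> list[DerivativeReconstruction]:
    """Walk each linked component from terminus to terminus."""
    ends = graph.ends
    crs = graph.crs
    start_ends = sorted(
        (i for i, a in assignment.items() if a[0] == "terminus"),
        key=lambda i: (ends[i].chrom, graph.terminus_capable[i][1], ends[i].pos),
    )
    visited: set[int] = set()
    recons: list[DerivativeReconstruction] = []
    for s in start_ends:
        if s in visited:
            continue
        path: list[OrientedInterval] = []
        group_ids: list[str] = []
        start_terminus = graph.terminus_capable[s]
        chrom, tpos = start_terminus
        e = ends[s]
        # segment from the terminus up to the open end
        if e.direction == TOWARD_SMALLER:
            if e.pos > 0:
                path.append(OrientedInterval(chrom, 0, e.pos, FORWARD))
        else:
            if e.pos < tpos:
                path.append(OrientedInterval(chrom, e.pos, tpos, REVERSE))
        current = s
        while True:
            visited.add(current)
            cr = crs[ends[current].group_index]
            group_ids.append(cr.group_id)
            segs = cr.segments if ends[current].terminal == FIRST else [
                iv.reversed() for iv in reversed(cr.segments)
            ]
            # trim overlap with the previously emitted reference (overlapping
            # facing extents cover identical sequence)
            segs = _trim_entry_overlap(path, segs)
            path.extend(segs)
            other = current + 1 if current % 2 == 0 else current - 1
            visited.add(other)
            kind, j = assignment[other]
            eo = ends[other]
            if kind == "terminus":
                chrom2, tpos2 = graph.terminus_capable[other]
                if eo.direction == TOWARD_LARGER:
                    if eo.pos < tpos2:
                        path.append(OrientedInterval(chrom2, eo.pos, tpos2, FORWARD))
                else:
                    if eo.pos > 0:
                        path.append(OrientedInterval(chrom2, 0, eo.pos, REVERSE))
                end_terminus = (chrom2, tpos2)
                break
            # connecting interval toward the partner end
            ep = ends[j]
            if eo.direction == TOWARD_LARGER and ep.pos > eo.pos:
                path.append(OrientedInterval(eo.chrom, eo.pos, ep.pos, FORWARD))
            elif eo.direction == TOWARD_SMALLER and ep.pos < eo.pos:
                path.append(OrientedInterval(eo.chrom, ep.pos, eo.pos, REVERSE))
            current = j
        recons.append(
            DerivativeReconstruction(
                name=f"der{len(recons) + 1}",
                path=path,
                group_ids=group_ids,
                start_terminus=start_terminus,
                end_terminus=end_terminus,
            )
        )
    return recons


def _trim_entry_overlap(
    path: list[OrientedInterval], segs: list[OrientedInterval]
) -> list[OrientedInterval]:
    """Clip the entering consensus's first segment where member read extents
    overlap the already-emitted flank inside a shared fragment."""
    if not path or not segs:
        return segs
    prev, head = path[-1], segs[0]
    if prev.chrom != head.chrom or prev.strand != head.strand:
        return segs
    if prev.strand == FORWARD and head.start < prev.end:
        if head.end <= prev.end:
            return segs[1:]
        return [OrientedInterval(head.chrom, prev.end, head.end, FORWARD)] + segs[1:]
    if prev.strand == REVERSE and head.end > prev.start:
        if head.start >= prev.start:
            return segs[1:]
        return [OrientedInterval(head.chrom, head.start, prev.start, REVERSE)] + segs[1:]
    return segs


def link(
    crs: Sequence[ConsensusRearrangement],
    chrom_lengths: Mapping[str, int],
) -> list[DerivativeReconstruction]:
    """The unique arrangement of the consensus set into derivative paths.

    Raises :class:`LinkInconsistencyError` when no valid assignment exists
    and :class:`LinkAmbiguityError` (listing alternatives) when several do.
    """
    graph = build_link_graph(crs, chrom_lengths)
    solutions = enumerate_arrangements(graph)
    if not solutions:
        raise LinkInconsistencyError(
            "inconsistent rearrangement: no valid way to arrange the groups"
        )
    if len(solutions) > 1:
        alts = [_assemble_paths(graph, s) for s in solutions]
        raise LinkAmbiguityError(
            f"ambiguous arrangement: {len(solutions)} valid orderings", alts
        )
    recons = _assemble_paths(graph, solutions[0])
    # deterministic naming: order by starting terminus
    recons.sort(key=lambda r: (r.start_terminus[0], r.start_terminus[1]))
    for i, r in enumerate(recons):
        r.name = f"der{i + 1}"
    return recons


def merge_colinear(recon: DerivativeReconstruction, tol: int = 100) -> list[Fragment]:
    """Maximal colinear fragments of a derivative path.

    Adjacent path segments on the same chromosome and strand that are
    reference-contiguous within ``tol`` merge; each output fragment carries
    its derivative name and rank.
    """
    fragments: list[Fragment] = []
    runs: list[list[OrientedInterval]] = []
    for seg in recon.path:
        if runs:
            prev = runs[-1][-1]
            if prev.chrom == seg.chrom and prev.strand == seg.strand:
                gap = (
                    seg.start - prev.end
                    if seg.strand == FORWARD
                    else prev.start - seg.end
                )
                if abs(gap) <= tol:
                    runs[-1].append(seg)
                    continue
        runs.append([seg])
    for rank, run in enumerate(runs, start=1):
        chrom, strand = run[0].chrom, run[0].strand
        start = min(s.start for s in run)
        end = max(s.end for s in run)
        fragments.append(
            Fragment(chrom, start, end, strand, derivative=recon.name, rank=rank)
        )
    return fragments


def infer_deletions(
    reconstructions: Sequence[DerivativeReconstruction],
    chrom_lengths: Mapping[str, int],
    min_size: int = 10_000,
    merge_tol: int = 100,
) -> list[DeletionCall]:
    """Reference intervals covered by no fragment of any reconstruction.

    Per chromosome, fragment source intervals are unioned; interior gaps of
    at least ``min_size`` are deletions.  Gaps at chromosome termini are not
    deletions (the derivative paths claim the termini they reach).
    """
    covered: dict[str, list[tuple[int, int]]] = {}
    for recon in reconstructions:
        for frag in merge_colinear(recon, merge_tol):
            covered.setdefault(frag.chrom, []).append((frag.start, frag.end))
    out: list[DeletionCall] = []
    for chrom in sorted(covered):
        ivs = sorted(covered[chrom])
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            if s2 - e1 >= min_size:
                out.append(DeletionCall(chrom, e1, s2))
    return out


@dataclass(frozen=True)
class ConcordanceRecord:
    deletion: DeletionCall
    array_call: tuple[str, int, int] | None
    reciprocal_overlap: float
    size_difference: int | None  # deletion length minus array length


def interval_concordance(
    deletions: Sequence[DeletionCall],
    array_calls: Sequence[tuple[str, int, int]],
) -> tuple[list[ConcordanceRecord], list[tuple[str, int, int]]]:
    """Match deletion calls to array (CNV) intervals by overlap.

    Each deletion is paired with the array call it overlaps most; reciprocal
    overlap is overlap length over the larger of the two intervals.  Array
    calls matching no deletion are returned separately.
    """
    records: list[ConcordanceRecord] = []
    matched: set[int] = set()
    for d in deletions:
        best, best_ov = None, 0
        for i, (chrom, s, e) in enumerate(array_calls):
            if chrom != d.chrom:
                continue
            ov = min(d.end, e) - max(d.start, s)
            if ov > best_ov:
                best, best_ov = i, ov
        if best is None:
            records.append(ConcordanceRecord(d, None, 0.0, None))
        else:
            chrom, s, e = array_calls[best]
            matched.add(best)
            records.append(
                ConcordanceRecord(
                    d,
                    (chrom, s, e),
                    best_ov / max(d.length, e - s),
                    d.length - (e - s),
                )
            )
    unmatched = [c for i, c in enumerate(array_calls) if i not in matched]
    return records, unmatched
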