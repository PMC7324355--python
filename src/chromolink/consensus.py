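"""Breakpoint-level consensus of a group of rearranged reads.

Each read group is merged into a single ordered, oriented walk over the
reference with one consensus junction per adjacent segment pair.  This is a
coordinate-level analog of assembling the group into a consensus sequence
and realigning it: the downstream linking stage needs only coordinates,
orders, and orientations, so no base-level consensus is computed.

Reads traverse the same rearrangement in both directions; members are
reoriented into a common frame before ordering.  Groups whose members imply
inconsistent segment orders after reorientation are reported as
unresolvable rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import (
    FORWARD,
    HEAD,
    REVERSE,
    TAIL,
    Breakend,
    Junction,
    OrientedInterval,
    ReadChain,
    junctions_match,
    make_junction,
    reverse_path,
)
from .alignments import DEFAULT_COLINEAR_GAP_TOL, JunctionObs, junction_observations


class UnresolvableGroupError(ValueError):
    """Members of a group imply inconsistent segment orders."""


@dataclass
class ConsensusRearrangement:
    """One group's merged rearrangement.

    ``segments`` are the reference intervals in the order traversed by the
    rearranged allele; ``junctions[i]`` joins ``segments[i]`` and
    ``segments[i+1]``.  ``spreads[i]`` is the largest distance (bases)
    between any member breakend of junction i and its consensus coordinate.
    """

    group_id: str
    segments: list[OrientedInterval]
    junctions: list[Junction]
    support: int
    spreads: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.segments) - 1:
            raise ValueError("need exactly one junction per adjacent segment pair")

    def reversed(self) -> "ConsensusRearrangement":
        return ConsensusRearrangement(
            group_id=self.group_id,
            segments=reverse_path(self.segments),
            junctions=list(reversed(self.junctions)),
            support=self.support,
            spreads=list(reversed(self.spreads)),
        )

    def breakends(self) -> list[Breakend]:
        out: list[Breakend] = []
        for j in self.junctions:
            out.extend(j.breakends())
        return out


def traversal_frames_equal(a: ConsensusRearrangement, b: ConsensusRearrangement) -> bool:
    """True iff the two walks describe the same allele up to full reversal."""
    if a.segments == b.segments:
        return True
    return reverse_path(a.segments) == b.segments


def _median_low(vals: Sequence[int]) -> int:
    """Median with even-count ties broken toward the smaller value."""
    vals = sorted(vals)
    return vals[(len(vals) - 1) // 2]


def _flip_seg(s):
    """The segment as seen from the reverse-complemented read."""
    from dataclasses import replace

    return replace(s, strand=FORWARD if s.strand == REVERSE else REVERSE)


@dataclass
class _Walk:
    """One member chain's junction observations, orientable as a unit."""

    clusters: list[int]
    obs: list[JunctionObs]

    def flipped(self) -> "_Walk":
        """The walk as its reverse-complemented read would report it."""
        return _Walk(
            clusters=list(reversed(self.clusters)),
            obs=[
                JunctionObs(o.junction, _flip_seg(o.right), _flip_seg(o.left), o.read_gap, o.ref_gap)
                for o in reversed(self.obs)
            ],
        )


def _left_side(o: JunctionObs) -> tuple[str, str]:
    """(chrom, side) of the breakend contributed by the observation's left segment."""
    s = o.left
    if s.strand == FORWARD:
        return (s.ref_chrom, HEAD)
    return (s.ref_chrom, TAIL)


def _left_pos(o: JunctionObs) -> int:
    s = o.left
    return s.ref_end if s.strand == FORWARD else s.ref_start


def _right_pos(o: JunctionObs) -> int:
    s = o.right
    return s.ref_start if s.strand == FORWARD else s.ref_end


def _cluster_observations(
    chains: Sequence[ReadChain], match_tol: int, colinear_gap_tol: int
) -> list[_Walk]:
    """Extract walks and assign every observation a junction-cluster id."""
    walks = [
        _Walk(clusters=[], obs=junction_observations(c, colinear_gap_tol))
        for c in chains
    ]
    reps: list[Junction] = []  # one representative per cluster
    for w in walks:
        for o in w.obs:
            k = next(
                (i for i, r in enumerate(reps) if junctions_match(o.junction, r, match_tol)),
                None,
            )
            if k is None:
                reps.append(o.junction)
                k = len(reps) - 1
            w.clusters.append(k)
    return [w for w in walks if w.obs]


def consensus_rearrangement(
    group_id: str,
    chains: Sequence[ReadChain],
    match_tol: int,
    colinear_gap_tol: int = DEFAULT_COLINEAR_GAP_TOL,
) -> ConsensusRearrangement:
    """Merge the member chains of one group into a consensus walk.

    Junction observations are clustered at ``match_tol``; consensus breakend
    coordinates are per-cluster medians (ties toward the smaller value).  The
    clusters must form a simple path when linked by co-occurrence within
    reads; each member is oriented onto that path and its segments pooled.
    Interior segment boundaries are pinned by consensus junction coordinates;
    the two outer segments extend to the furthest member alignment.
    """
    chains = sorted(chains, key=lambda c: c.read_id)
    if not chains:
        raise ValueError("empty group")
    walks = _cluster_observations(chains, match_tol, colinear_gap_tol)
    if not walks:
        raise ValueError(f"group {group_id}: no member carries a junction")
    nodes = sorted({k for w in walks for k in w.clusters})

    # order clusters into a simple path using within-read adjacencies
    adj: dict[int, set[int]] = {k: set() for k in nodes}
    for w in walks:
        for ka, kb in zip(w.clusters, w.clusters[1:]):
            if ka == kb:
                raise UnresolvableGroupError(
                    f"group {group_id}: a read visits one junction cluster twice in a row"
                )
            adj[ka].add(kb)
            adj[kb].add(ka)
    if len(nodes) == 1:
        order = nodes
    else:
        ends = [k for k in nodes if len(adj[k]) == 1]
        if len(ends) != 2 or any(len(adj[k]) > 2 for k in nodes):
            raise UnresolvableGroupError(
                f"group {group_id}: junction co-occurrence is not a simple path"
            )
        order = [min(ends)]
        prev = None
        while len(order) < len(nodes):
            nxt = [k for k in adj[order[-1]] if k != prev]
            if len(nxt) != 1:
                raise UnresolvableGroupError(f"group {group_id}: broken junction path")
            prev = order[-1]
            order.append(nxt[0])
    rank = {k: i for i, k in enumerate(order)}

    # orient multi-junction walks by path order; they fix each cluster's frame
    ref_frame: dict[int, tuple[tuple[str, str], int]] = {}  # cluster -> ((chrom, side), pos)
    oriented: list[_Walk] = []
    lone: list[_Walk] = []
    for w in walks:
        if len(w.clusters) == 1:
            lone.append(w)
            continue
        pos = [rank[k] for k in w.clusters]
        if pos == sorted(pos):
            pass
        elif pos == sorted(pos, reverse=True):
            w = w.flipped()
        else:
            raise UnresolvableGroupError(
                f"group {group_id}: a member visits junctions out of path order"
            )
        for k, o in zip(w.clusters, w.obs):
            side = _left_side(o)
            if ref_frame.setdefault(k, (side, _left_pos(o)))[0] != side:
                raise UnresolvableGroupError(
                    f"group {group_id}: members disagree on junction orientation"
                )
        oriented.append(w)
    # lone observations adopt the cluster frame, flipping as needed.  For
    # inversion-type junctions both breakends share a side, so the frame is
    # resolved by breakend position, not side alone.  When nothing fixed the
    # frame yet, the first lone member does.
    for w in lone:
        k = w.clusters[0]
        if k in ref_frame:
            (side, pos) = ref_frame[k]

            def frame_score(cand: _Walk) -> tuple[int, int]:
                o = cand.obs[0]
                return (
                    0 if _left_side(o) == side else 1,
                    abs(_left_pos(o) - pos),
                )

            w = min((w, w.flipped()), key=frame_score)
            if _left_side(w.obs[0]) != side:
                raise UnresolvableGroupError(
                    f"group {group_id}: members disagree on junction orientation"
                )
        else:
            ref_frame[k] = (_left_side(w.obs[0]), _left_pos(w.obs[0]))
        oriented.append(w)

    # consensus breakends per cluster: median of member positions
    left_bnd: dict[int, Breakend] = {}
    right_bnd: dict[int, Breakend] = {}
    spreads: dict[int, int] = {}
    obs_of: dict[int, list[JunctionObs]] = {k: [] for k in nodes}
    for w in oriented:
        for k, o in zip(w.clusters, w.obs):
            obs_of[k].append(o)
    for k in nodes:
        obs = obs_of[k]
        lpos = [_left_pos(o) for o in obs]
        rpos = [_right_pos(o) for o in obs]
        lchrom, lside = ref_frame[k][0]
        r0 = obs[0].right
        rchrom = r0.ref_chrom
        rside = TAIL if r0.strand == FORWARD else HEAD
        lp, rp = _median_low(lpos), _median_low(rpos)
        left_bnd[k] = Breakend(lchrom, lp, lside)
        right_bnd[k] = Breakend(rchrom, rp, rside)
        spreads[k] = max(
            max(abs(p - lp) for p in lpos), max(abs(p - rp) for p in rpos)
        )

    def seg_iv(s, flip: bool) -> OrientedInterval:
        iv = OrientedInterval(s.ref_chrom, s.ref_start, s.ref_end, s.strand)
        return iv.reversed() if flip else iv

    # pool outer member segments (walks whose first/last cluster is terminal)
    outer_left = [
        seg_iv(w.obs[0].left, False) for w in oriented if rank[w.clusters[0]] == 0
    ]
    outer_right = [
        seg_iv(w.obs[-1].right, False)
        for w in oriented
        if rank[w.clusters[-1]] == len(order) - 1
    ]
    if not outer_left or not outer_right:
        raise UnresolvableGroupError(f"group {group_id}: no member spans a terminal junction")

    def segment_between(b_from: Breakend, b_to: Breakend) -> OrientedInterval:
        if b_from.chrom != b_to.chrom:
            raise UnresolvableGroupError(
                f"group {group_id}: interior segment spans two chromosomes"
            )
        if b_from.side == TAIL and b_to.side == HEAD and b_from.pos < b_to.pos:
            return OrientedInterval(b_from.chrom, b_from.pos, b_to.pos, FORWARD)
        if b_from.side == HEAD and b_to.side == TAIL and b_to.pos < b_from.pos:
            return OrientedInterval(b_from.chrom, b_to.pos, b_from.pos, REVERSE)
        raise UnresolvableGroupError(
            f"group {group_id}: interior breakends do not face each other"
        )

    segments: list[OrientedInterval] = []
    b0 = left_bnd[order[0]]
    if b0.side == HEAD:
        start = min(s.start for s in outer_left)
        segments.append(OrientedInterval(b0.chrom, min(start, b0.pos - 1), b0.pos, FORWARD))
    else:
        end = max(s.end for s in outer_left)
        segments.append(OrientedInterval(b0.chrom, b0.pos, max(end, b0.pos + 1), REVERSE))
    for k_prev, k_next in zip(order, order[1:]):
        segments.append(segment_between(right_bnd[k_prev], left_bnd[k_next]))
    bz = right_bnd[order[-1]]
    if bz.side == TAIL:
        end = max(s.end for s in outer_right)
        segments.append(OrientedInterval(bz.chrom, bz.pos, max(end, bz.pos + 1), FORWARD))
    else:
        start = min(s.start for s in outer_right)
        segments.append(OrientedInterval(bz.chrom, min(start, bz.pos - 1), bz.pos, REVERSE))

    cr = ConsensusRearrangement(
        group_id=group_id,
        segments=segments,
        junctions=[make_junction(left_bnd[k], right_bnd[k]) for k in order],
        support=len(chains),
        spreads=[spreads[k] for k in order],
    )
    return _canonical_frame(cr)


def _canonical_frame(cr: ConsensusRearrangement) -> ConsensusRearrangement:
    """Deterministic traversal direction (gives member-order invariance)."""
    rev = cr.reversed()

    def key(c: ConsensusRearrangement):
        return [(s.chrom, s.start, s.end, s.strand) for s in c.segments]

    return cr if key(cr) <= key(rev) else rev


def dedupe_by_frame(crs: Sequence[ConsensusRearrangement]) -> list[ConsensusRearrangement]:
    """Drop consensuses equal to an earlier one up to full reversal."""
    out: list[ConsensusRearrangement] = []
    for cr in crs:
        if not any(traversal_frames_equal(cr, seen) for seen in out):
            out.append(cr)
    return out


def write_consensus_tsv(crs: Sequence[ConsensusRearrangement], handle) -> None:
    handle.write("group_id\tsupport\tsegments\tjunctions\tmax_spread\n")
    for cr in crs:
        segs = ";".join(f"{s.chrom}:{s.start}-{s.end}:{s.strand}" for s in cr.segments)
        juncs = ";".join(str(j) for j in cr.junctions)
        spread = max(cr.spreads) if cr.spreads else 0
        handle.write(f"{cr.group_id}\t{cr.support}\t{segs}\t{juncs}\t{spread}\n")


def consensus_to_dict(cr: ConsensusRearrangement) -> dict:
    return {
        "group_id": cr.group_id,
        "support": cr.support,
        "segments": [
            {"chrom": s.chrom, "start": s.start, "end": s.end, "strand": s.strand}
            for s in cr.segments
        ],
        "junctions": [str(j) for j in cr.junctions],
        "spreads": list(cr.spreads),
    }
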