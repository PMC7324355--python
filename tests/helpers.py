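"""Shared test utilities, including a brute-force linking oracle.

The oracle re-derives open ends and validity rules directly from their
definitions and enumerates end pairings recursively, independent of the
candidate graph and union-find search used by the implementation.
"""

from __future__ import annotations

import networkx as nx

from chromolink.model import FORWARD
from chromolink.linking import (
    LinkAmbiguityError,
    LinkInconsistencyError,
    link,
)


def oracle_ends(crs):
    """(group index, terminal, chrom, pos, direction) for every open end."""
    ends = []
    for gi, cr in enumerate(crs):
        first, last = cr.segments[0], cr.segments[-1]
        if first.strand == FORWARD:
            ends.append((gi, "first", first.chrom, first.start, "smaller"))
        else:
            ends.append((gi, "first", first.chrom, first.end, "larger"))
        if last.strand == FORWARD:
            ends.append((gi, "last", last.chrom, last.end, "larger"))
        else:
            ends.append((gi, "last", last.chrom, last.start, "smaller"))
    return ends


def _breakend_positions(crs):
    pos = {}
    for cr in crs:
        for b in cr.breakends():
            pos.setdefault(b.chrom, set()).add(b.pos)
    return pos


def _blocked(bpos, chrom, lo, hi):
    if lo > hi:
        lo, hi = hi, lo
    return any(lo < p < hi for p in bpos.get(chrom, ()))


def oracle_pair_valid(ea, eb, bpos):
    """Two ends face each other with no strictly intervening breakend."""
    if ea[2] != eb[2] or ea[0] == eb[0]:
        return False
    if ea[4] == eb[4]:
        return False
    larger, smaller = (ea, eb) if ea[4] == "larger" else (eb, ea)
    return not _blocked(bpos, ea[2], larger[3], smaller[3])


def oracle_terminus_valid(e, chrom_lengths, bpos):
    if e[4] == "smaller":
        return not _blocked(bpos, e[2], 0, e[3])
    return not _blocked(bpos, e[2], e[3], chrom_lengths[e[2]])


def oracle_arrangements(crs, chrom_lengths):
    """All valid complete end assignments, each canonicalized as
    (frozenset of linked end pairs, frozenset of terminus ends)."""
    ends = oracle_ends(crs)
    bpos = _breakend_positions(crs)
    n = len(ends)
    solutions = []

    def ekey(i):
        return (ends[i][0], ends[i][1])

    def recurse(assigned, links, termini):
        if len(assigned) == n:
            g = nx.Graph()
            g.add_nodes_from(range(len(crs)))
            for i, j in links:
                g.add_edge(ends[i][0], ends[j][0])
            if len(list(nx.cycle_basis(g))) == 0:
                solutions.append(
                    (
                        frozenset(frozenset((ekey(i), ekey(j))) for i, j in links),
                        frozenset(ekey(i) for i in termini),
                    )
                )
            return
        i = next(k for k in range(n) if k not in assigned)
        for j in range(n):
            if j in assigned or j == i:
                continue
            if oracle_pair_valid(ends[i], ends[j], bpos):
                recurse(assigned | {i, j}, links + [(i, j)], termini)
        if oracle_terminus_valid(ends[i], chrom_lengths, bpos):
            recurse(assigned | {i}, links, termini + [i])

    recurse(frozenset(), [], [])
    return sorted(set(solutions))


def link_outcome(crs, chrom_lengths):
    """(status, payload) from the implementation: unique/ambiguous/inconsistent."""
    try:
        recons = link(crs, chrom_lengths)
        return "unique", recons
    except LinkAmbiguityError as exc:
        return "ambiguous", exc.alternatives
    except LinkInconsistencyError:
        return "inconsistent", None


def derivative_layouts(plan):
    """Truth layouts as ordered oriented fragment tuples, one per derivative."""
    out = []
    for d in plan.derivatives:
        path = [
            (f.chrom, f.start, f.end, f.strand)
            for f in (plan.fragment_by_id(i) for i in d.fragment_ids)
        ]
        out.append(tuple(path))
    return out


def reconstruction_layouts(fragments):
    """Reconstructed layouts grouped by derivative, in rank order."""
    by_der = {}
    for f in fragments:
        by_der.setdefault(f.derivative, []).append(f)
    out = []
    for name in sorted(by_der):
        frs = sorted(by_der[name], key=lambda f: f.rank)
        out.append(tuple((f.chrom, f.start, f.end, f.strand) for f in frs))
    return out


def same_layout_up_to_reversal(a, b):
    if a == b:
        return True
    flip = {"+": "-", "-": "+"}
    rev = tuple((c, s, e, flip[st]) for c, s, e, st in reversed(b))
    return a == rev


def layout_sets_equal(truth_layouts, recon_layouts):
    if len(truth_layouts) != len(recon_layouts):
        return False
    remaining = list(recon_layouts)
    for t in truth_layouts:
        hit = next((r for r in remaining if same_layout_up_to_reversal(t, r)), None)
        if hit is None:
            return False
        remaining.remove(hit)
    return True
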