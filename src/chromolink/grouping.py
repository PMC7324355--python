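"""Rearranged-read detection, grouping, and control-cohort subtraction.

A read is rearranged iff its chain yields at least one junction.  Reads
sharing a junction (both breakends within tolerance, same sides) are linked,
and groups are the connected components of that relation.  Groups whose
junctions also occur in any control individual are subtracted, leaving
patient-only rearrangements; the per-control trace of surviving group counts
mirrors the successive-subtraction curve of the control filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .model import Junction, ReadChain, junctions_match
from .alignments import (
    DEFAULT_COLINEAR_GAP_TOL,
    JunctionObs,
    junction_observations,
)

#: junction categories by local geometry
INTER_CHROMOSOMAL = "inter_chromosomal"
INVERSION = "inversion"
LONG_GAP = "long_gap"
DUPLICATION_LOOP = "duplication_loop"
UNALIGNED_INSERT = "unaligned_insert"


@dataclass(frozen=True)
class DetectionThresholds:
    """Detection profile; two presets are shipped (see below)."""

    match_tol: int = 200
    colinear_gap_tol: int = DEFAULT_COLINEAR_GAP_TOL
    gap_min: int = 10_000
    insert_min: int = 300
    min_reads: int = 3


#: error-free alignments: tight breakend agreement
EXACT_PRESET = DetectionThresholds(match_tol=200)
#: noisy long reads: breakends wobble by alignment trimming
NOISY_PRESET = DetectionThresholds(match_tol=1000)


def categorize_observation(obs: JunctionObs, thresholds: DetectionThresholds) -> str:
    """Category of one junction observation from its local geometry."""
    a, b = obs.left, obs.right
    if a.ref_chrom != b.ref_chrom:
        return INTER_CHROMOSOMAL
    if a.strand != b.strand:
        return INVERSION
    # same chromosome, same strand: look at the signed reference advance
    ref_gap = obs.ref_gap
    assert ref_gap is not None  # same chrom and strand -> geometry is defined
    if ref_gap < 0:
        # the reference steps backward along the read: tandem signature
        return DUPLICATION_LOOP
    if obs.read_gap - ref_gap > thresholds.insert_min and ref_gap <= thresholds.colinear_gap_tol:
        # unaligned read sequence with no reference advance: insertion
        return UNALIGNED_INSERT
    # any remaining forward reference gap exceeded the colinearity tolerance
    return LONG_GAP


def is_rearranged(
    chain: ReadChain, thresholds: DetectionThresholds = EXACT_PRESET
) -> tuple[bool, set[str]]:
    """Flag a chain as rearranged and report its junction categories."""
    obs = junction_observations(chain, thresholds.colinear_gap_tol)
    if not obs:
        return False, set()
    return True, {categorize_observation(o, thresholds) for o in obs}


@dataclass
class RearrangementGroup:
    """Reads that overlap the same rearrangement.

    ``signature`` holds one representative (tolerance-merged) junction per
    distinct breakpoint observed in the member reads.
    """

    group_id: str
    members: list[ReadChain]
    signature: list[Junction]
    categories: set[str] = field(default_factory=set)

    @property
    def support(self) -> int:
        return len(self.members)


def _cluster_junctions(
    tagged: Sequence[tuple[int, JunctionObs]], match_tol: int
) -> tuple[list[list[int]], list[Junction]]:
    """Single-linkage clusters of junction observations within tolerance.

    Observations are bucketed by (chrom, side, chrom, side) and sorted by
    position so only nearby pairs are compared.  Returns, per cluster, the
    member chain indices and a representative junction.
    """
    by_key: dict[tuple, list[int]] = {}
    for i, (_, o) in enumerate(tagged):
        a, b = o.junction.breakends()
        by_key.setdefault(((a.chrom, a.side), (b.chrom, b.side)), []).append(i)
    g = nx.Graph()
    g.add_nodes_from(range(len(tagged)))
    for key, idxs in by_key.items():
        idxs = sorted(idxs, key=lambda i: tagged[i][1].junction.breakend_a.pos)
        for x, i in enumerate(idxs):
            ji = tagged[i][1].junction
            for jdx in idxs[x + 1 :]:
                jj = tagged[jdx][1].junction
                if jj.breakend_a.pos - ji.breakend_a.pos > match_tol:
                    break
                if junctions_match(ji, jj, match_tol):
                    g.add_edge(i, jdx)
    clusters: list[list[int]] = []
    reps: list[Junction] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        clusters.append(comp)
        reps.append(min(tagged[i][1].junction for i in comp))
    order = sorted(range(len(reps)), key=lambda k: reps[k])
    return [clusters[k] for k in order], [reps[k] for k in order]


def group_reads(
    chains: Sequence[ReadChain],
    thresholds: DetectionThresholds = EXACT_PRESET,
) -> list[RearrangementGroup]:
    """Cluster rearranged reads into groups by shared junctions.

    Two reads are linked iff they share at least one junction with both
    breakends within ``match_tol`` and identical sides; groups are connected
    components, and components with fewer than ``min_reads`` members are
    discarded.
    """
    chains = sorted(chains, key=lambda c: c.read_id)
    tagged: list[tuple[int, JunctionObs]] = []
    for ci, chain in enumerate(chains):
        for o in junction_observations(chain, thresholds.colinear_gap_tol):
            tagged.append((ci, o))
    clusters, reps = _cluster_junctions(tagged, thresholds.match_tol)
    g = nx.Graph()
    g.add_nodes_from(range(len(chains)))
    cluster_of_obs: dict[int, int] = {}
    for k, comp in enumerate(clusters):
        for i in comp:
            cluster_of_obs[i] = k
        members = sorted({tagged[i][0] for i in comp})
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
    groups: list[RearrangementGroup] = []
    comps = [
        sorted(c)
        for c in nx.connected_components(g)
        if len(c) >= thresholds.min_reads and any(len(junction_observations(chains[i], thresholds.colinear_gap_tol)) for i in c)
    ]
    comps.sort(key=lambda c: chains[c[0]].read_id)
    for n, comp in enumerate(comps):
        comp_set = set(comp)
        sig_ids = sorted(
            {cluster_of_obs[i] for i, (ci, _) in enumerate(tagged) if ci in comp_set}
        )
        members = [chains[i] for i in comp]
        group = RearrangementGroup(
            group_id=f"grp{n:03d}",
            members=members,
            signature=[reps[k] for k in sig_ids],
        )
        for m in members:
            _, cats = is_rearranged(m, thresholds)
            group.categories |= cats
        groups.append(group)
    return groups


@dataclass
class FilterTrace:
    """Groups remaining after each successive control subtraction."""

    counts: list[tuple[int, int]]  # (control index starting at 1, groups remaining)

    def __post_init__(self) -> None:
        values = [n for _, n in self.counts]
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValueError("filter trace must be monotone non-increasing")


def control_junctions(
    chain_set: Iterable[ReadChain], colinear_gap_tol: int = DEFAULT_COLINEAR_GAP_TOL
) -> list[Junction]:
    out = []
    for chain in chain_set:
        out.extend(o.junction for o in junction_observations(chain, colinear_gap_tol))
    return out


def subtract_controls(
    groups: Sequence[RearrangementGroup],
    control_chain_sets: Sequence[Sequence[ReadChain]],
    thresholds: DetectionThresholds = EXACT_PRESET,
) -> tuple[list[RearrangementGroup], FilterTrace]:
    """Remove groups whose junctions are shared with any control.

    A single shared junction suffices for removal (one control read with a
    junction matching any signature junction within ``match_tol`` and with
    the same sides).  Controls are applied in order and the remaining group
    count recorded after each; the surviving set does not depend on that
    order.
    """
    surviving = list(groups)
    counts: list[tuple[int, int]] = []
    for ci, chain_set in enumerate(control_chain_sets, start=1):
        cjs = control_junctions(chain_set, thresholds.colinear_gap_tol)
        surviving = [
            grp
            for grp in surviving
            if not any(
                junctions_match(sig, cj, thresholds.match_tol)
                for sig in grp.signature
                for cj in cjs
            )
        ]
        counts.append((ci, len(surviving)))
    return surviving, FilterTrace(counts=counts)


def write_group_table(groups: Iterable[RearrangementGroup], handle) -> None:
    handle.write("group_id\tsupport\tn_junctions\tcategories\tsignature\n")
    for grp in groups:
        cats = ",".join(sorted(grp.categories)) or "."
        sig = ";".join(str(j) for j in grp.signature)
        handle.write(f"{grp.group_id}\t{grp.support}\t{len(grp.signature)}\t{cats}\t{sig}\n")


def write_filter_trace(trace: FilterTrace, handle) -> None:
    handle.write("control_index\tgroups_remaining\n")
    for ci, n in trace.counts:
        handle.write(f"{ci}\t{n}\n")
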