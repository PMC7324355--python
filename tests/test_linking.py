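import pytest

from helpers import (
    derivative_layouts,
    layout_sets_equal,
    link_outcome,
    oracle_arrangements,
    reconstruction_layouts,
)

from chromolink import simulate as sim
from chromolink.model import FORWARD, REVERSE, OrientedInterval, path_junctions
from chromolink.consensus import ConsensusRearrangement
from chromolink.linking import (
    DeletionCall,
    LinkAmbiguityError,
    LinkInconsistencyError,
    build_link_graph,
    enumerate_arrangements,
    infer_deletions,
    interval_concordance,
    link,
    merge_colinear,
    open_ends,
)


def make_cr(gid, segments):
    return ConsensusRearrangement(
        group_id=gid,
        segments=list(segments),
        junctions=path_junctions(segments),
        support=1,
        spreads=[0] * (len(segments) - 1),
    )


class TestOpenEnds:
    def test_forward_segment_ends(self):
        cr = make_cr("g", [
            OrientedInterval("c", 100, 200, FORWARD),
            OrientedInterval("c", 700, 800, FORWARD),
        ])
        e1, e2 = open_ends(cr)
        assert (e1.chrom, e1.pos, e1.direction) == ("c", 100, "toward_smaller")
        assert (e2.chrom, e2.pos, e2.direction) == ("c", 800, "toward_larger")

    def test_reverse_segment_flips_directions(self):
        cr = make_cr("g", [
            OrientedInterval("c", 700, 800, REVERSE),
            OrientedInterval("c", 100, 200, REVERSE),
        ])
        e1, e2 = open_ends(cr)
        assert (e1.pos, e1.direction) == (800, "toward_larger")
        assert (e2.pos, e2.direction) == (100, "toward_smaller")

    def test_fixture_truth_consensus_ends_sit_inside_flanking_fragments(
        self, fixture_plan
    ):
        crs = sim.truth_consensus(fixture_plan)
        frags = [(f.chrom, f.start, f.end) for f in fixture_plan.fragments]
        for cr in crs:
            for e in open_ends(cr):
                assert any(c == e.chrom and s < e.pos < en for c, s, en in frags)


def two_facing_crs(blocker=False):
    """Two consensuses facing each other across c:[20_000, 80_000]."""
    crs = [
        make_cr("g1", [
            OrientedInterval("d", 50_000, 60_000, FORWARD),
            OrientedInterval("c", 10_000, 20_000, FORWARD),
        ]),
        make_cr("g2", [
            OrientedInterval("c", 80_000, 90_000, FORWARD),
            OrientedInterval("e", 0, 10_000, FORWARD),
        ]),
    ]
    if blocker:
        crs.append(
            make_cr("g3", [
                OrientedInterval("c", 40_000, 50_000, FORWARD),
                OrientedInterval("e", 40_000, 50_000, FORWARD),
            ])
        )
    return crs


class TestLinkGraph:
    def test_facing_pair_with_nothing_between_yields_one_candidate(self):
        crs = two_facing_crs()
        graph = build_link_graph(crs, {"c": 200_000, "d": 200_000, "e": 200_000})
        between = [
            cand
            for cand in graph.candidates
            if {cand.end_a.group_index, cand.end_b.group_index} == {0, 1}
        ]
        assert len(between) == 1
        assert between[0].interval == ("c", 20_000, 80_000)

    def test_intervening_breakend_blocks_candidate(self):
        crs = two_facing_crs(blocker=True)
        graph = build_link_graph(crs, {"c": 200_000, "d": 200_000, "e": 200_000})
        between = [
            cand
            for cand in graph.candidates
            if {cand.end_a.group_index, cand.end_b.group_index} == {0, 1}
        ]
        assert between == []

    def test_fixture_graph_every_end_is_determined(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        graph = build_link_graph(crs, fixture_plan.genome.lengths)
        for i, opts in enumerate(graph.options):
            assert len(opts) == 1, f"end {graph.ends[i]} has options {opts}"


class TestLinkFixture:
    def test_unique_arrangement_of_fixture_consensuses(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        recons = link(crs, fixture_plan.genome.lengths)
        assert len(recons) == 2
        assert sum(len(r.group_ids) for r in recons) == len(crs)

    def test_fragment_counts_after_colinear_merge(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        recons = link(crs, fixture_plan.genome.lengths)
        counts = sorted(len(merge_colinear(r)) for r in recons)
        assert counts == [5, 14]

    def test_removing_an_interior_consensus_is_an_error_not_a_guess(
        self, fixture_plan
    ):
        crs = sim.truth_consensus(fixture_plan)
        # drop a consensus that is not adjacent to any terminus
        graph = build_link_graph(crs, fixture_plan.genome.lengths)
        interior = next(
            i
            for i, cr in enumerate(crs)
            if not any(
                idx in graph.terminus_capable
                for idx in (2 * i, 2 * i + 1)
            )
        )
        depleted = crs[:interior] + crs[interior + 1 :]
        with pytest.raises((LinkAmbiguityError, LinkInconsistencyError)):
            link(depleted, fixture_plan.genome.lengths)

    def test_single_consensus_with_free_ends_spans_terminus_to_terminus(self):
        cr = make_cr("g", [
            OrientedInterval("c", 40_000, 50_000, FORWARD),
            OrientedInterval("d", 10_000, 20_000, FORWARD),
        ])
        (recon,) = link([cr], {"c": 100_000, "d": 100_000})
        assert recon.start_terminus == ("c", 0)
        assert recon.end_terminus == ("d", 100_000)
        frags = merge_colinear(recon)
        assert [(f.chrom, f.start, f.end) for f in frags] == [
            ("c", 0, 50_000),
            ("d", 10_000, 100_000),
        ]

    def test_reversing_every_consensus_frame_gives_same_fragments(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        recons_a = link(crs, fixture_plan.genome.lengths)
        recons_b = link([cr.reversed() for cr in crs], fixture_plan.genome.lengths)
        frags_a = sorted(
            (f.chrom, f.start, f.end) for r in recons_a for f in merge_colinear(r)
        )
        frags_b = sorted(
            (f.chrom, f.start, f.end) for r in recons_b for f in merge_colinear(r)
        )
        assert frags_a == frags_b


class TestLinkOracle:
    """`link` agrees with brute-force enumeration of valid end pairings."""

    @pytest.mark.parametrize("seed", range(60))
    def test_random_consensus_sets_match_oracle(self, seed):
        plan = sim.random_plan(
            {"cA": 500_000, "cB": 400_000}, seed=seed, n_fragments=(2, 4)
        )
        crs = sim.truth_consensus(plan, flank=5_000)
        if len(crs) > 8:
            crs = crs[:0]  # keep the oracle tractable; skip oversized draws
        if not crs:
            return
        lengths = plan.genome.lengths
        oracle = oracle_arrangements(crs, lengths)
        graph = build_link_graph(crs, lengths)
        impl = canonical_solutions(graph)
        assert impl == oracle
        status, payload = link_outcome(crs, lengths)
        assert status == {0: "inconsistent", 1: "unique"}.get(len(oracle), "ambiguous")

    def test_fixture_consensuses_match_oracle(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        lengths = fixture_plan.genome.lengths
        oracle = oracle_arrangements(crs, lengths)
        graph = build_link_graph(crs, lengths)
        assert canonical_solutions(graph) == oracle
        assert len(oracle) == 1


def canonical_solutions(graph):
    sols = enumerate_arrangements(graph)
    out = set()
    for sol in sols:
        links = set()
        termini = set()
        for i, (kind, j) in sol.items():
            ei = graph.ends[i]
            if kind == "terminus":
                termini.add((ei.group_index, ei.terminal))
            else:
                ej = graph.ends[j]
                links.add(
                    frozenset(
                        ((ei.group_index, ei.terminal), (ej.group_index, ej.terminal))
                    )
                )
        out.add((frozenset(links), frozenset(termini)))
    return sorted(out)


class TestMergeColinear:
    def _recon(self, path):
        from chromolink.linking import DerivativeReconstruction

        return DerivativeReconstruction(
            name="der1", path=path, group_ids=[],
            start_terminus=("c", 0), end_terminus=("c", 0),
        )

    def test_contiguous_same_strand_segments_merge(self):
        frags = merge_colinear(self._recon([
            OrientedInterval("c", 0, 100, FORWARD),
            OrientedInterval("c", 100, 300, FORWARD),
        ]))
        assert [(f.chrom, f.start, f.end, f.strand) for f in frags] == [
            ("c", 0, 300, FORWARD)
        ]

    def test_strand_break_keeps_fragments_apart(self):
        frags = merge_colinear(self._recon([
            OrientedInterval("c", 0, 100, FORWARD),
            OrientedInterval("c", 200, 300, REVERSE),
        ]))
        assert len(frags) == 2
        assert [f.rank for f in frags] == [1, 2]

    def test_reverse_runs_merge_in_traversal_order(self):
        frags = merge_colinear(self._recon([
            OrientedInterval("c", 500, 600, REVERSE),
            OrientedInterval("c", 300, 500, REVERSE),
        ]))
        assert [(f.start, f.end, f.strand) for f in frags] == [(300, 600, REVERSE)]


class TestInferDeletions:
    def test_identity_reconstruction_has_no_deletions(self):
        cr = make_cr("g", [
            OrientedInterval("c", 40_000, 50_000, FORWARD),
            OrientedInterval("d", 10_000, 20_000, FORWARD),
        ])
        recons = link([cr], {"c": 100_000, "d": 100_000})
        assert infer_deletions(recons, {"c": 100_000, "d": 100_000}) == []

    def test_fixture_deletions_recovered_exactly(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        recons = link(crs, fixture_plan.genome.lengths)
        dels = infer_deletions(recons, fixture_plan.genome.lengths)
        got = sorted((d.chrom, d.start, d.end) for d in dels)
        assert got == sorted(fixture_plan.truth_deletions)

    def test_chr18_analog_deletion_is_1528_kb(self, fixture_plan):
        crs = sim.truth_consensus(fixture_plan)
        recons = link(crs, fixture_plan.genome.lengths)
        dels = infer_deletions(recons, fixture_plan.genome.lengths)
        by_chrom = {}
        for d in dels:
            by_chrom.setdefault(d.chrom, []).append(d.length)
        (single,) = [v for v in by_chrom.values() if len(v) == 1]
        assert single == [1_528_000]

    @pytest.mark.parametrize(
        "min_size, expected",
        [(10_000, []), (1_000, [("c", 30_000, 33_000)])],
    )
    def test_min_size_threshold_filters_small_gaps(self, min_size, expected):
        # the two paths leave c:30000-33000 (3 kb) uncovered
        from chromolink.linking import DerivativeReconstruction

        recons = [
            DerivativeReconstruction(
                name="der1",
                path=[
                    OrientedInterval("c", 0, 30_000, FORWARD),
                    OrientedInterval("d", 0, 100_000, FORWARD),
                ],
                group_ids=["g1"],
                start_terminus=("c", 0),
                end_terminus=("d", 100_000),
            ),
            DerivativeReconstruction(
                name="der2",
                path=[OrientedInterval("c", 33_000, 100_000, FORWARD)],
                group_ids=["g2"],
                start_terminus=("c", 100_000),
                end_terminus=("c", 100_000),
            ),
        ]
        lengths = {"c": 100_000, "d": 100_000}
        dels = infer_deletions(recons, lengths, min_size=min_size)
        assert [(d.chrom, d.start, d.end) for d in dels] == expected


class TestIntervalConcordance:
    def test_identical_sets_fully_match(self):
        dels = [DeletionCall("c", 100, 200), DeletionCall("c", 500, 900)]
        calls = [("c", 100, 200), ("c", 500, 900)]
        records, unmatched = interval_concordance(dels, calls)
        assert unmatched == []
        assert all(r.reciprocal_overlap == 1.0 and r.size_difference == 0 for r in records)

    def test_array_call_inside_deletion_has_positive_size_difference(self):
        records, unmatched = interval_concordance(
            [DeletionCall("c", 100, 1100)], [("c", 300, 800)]
        )
        (r,) = records
        assert r.size_difference == 500
        assert 0 < r.reciprocal_overlap < 1

    def test_disjoint_sets_all_unmatched(self):
        records, unmatched = interval_concordance(
            [DeletionCall("c", 0, 100)], [("c", 5_000, 6_000)]
        )
        assert records[0].array_call is None
        assert unmatched == [("c", 5_000, 6_000)]


class TestPlanRecovery:
    @pytest.mark.parametrize("seed", range(25))
    def test_truth_consensus_recovers_layout_exactly(self, seed):
        plan = sim.random_plan({"cA": 700_000, "cB": 500_000}, seed=seed)
        crs = sim.truth_consensus(plan)
        recons = link(crs, plan.genome.lengths)
        fragments = [f for r in recons for f in merge_colinear(r)]
        assert layout_sets_equal(
            derivative_layouts(plan), reconstruction_layouts(fragments)
        )
        dels = infer_deletions(recons, plan.genome.lengths)
        assert sorted((d.chrom, d.start, d.end) for d in dels) == sorted(
            plan.truth_deletions
        )
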