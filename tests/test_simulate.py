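import numpy as np
import pytest

from chromolink import simulate as sim
from chromolink.model import FORWARD, REVERSE, OrientedInterval
from chromolink.alignments import junctions_of


class TestToyGenome:
    def test_lengths_echo_input(self):
        g = sim.build_toy_genome({"chr8t": 20_000, "chr18t": 10_000}, seed=1)
        assert g.lengths == {"chr8t": 20_000, "chr18t": 10_000}
        assert set(g.chromosomes["chr8t"]) <= set("ACGT")

    def test_same_seed_is_byte_identical(self):
        a = sim.build_toy_genome({"c": 15_000}, seed=7)
        b = sim.build_toy_genome({"c": 15_000}, seed=7)
        assert a.chromosomes == b.chromosomes

    def test_different_seed_differs(self):
        a = sim.build_toy_genome({"c": 15_000}, seed=7)
        b = sim.build_toy_genome({"c": 15_000}, seed=8)
        assert a.chromosomes != b.chromosomes

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            sim.build_toy_genome({"c": 0}, seed=1)


class TestFixturePlan:
    def test_nineteen_fragments_split_fifteen_four(self, fixture_plan):
        assert len(fixture_plan.fragments) == 19
        by_chrom = {}
        for f in fixture_plan.fragments:
            by_chrom[f.chrom] = by_chrom.get(f.chrom, 0) + 1
        assert sorted(by_chrom.values(), reverse=True) == [15, 4]

    def test_derivative_sizes_fourteen_and_five(self, fixture_plan):
        sizes = sorted(len(d.fragment_ids) for d in fixture_plan.derivatives)
        assert sizes == [5, 14]

    def test_deletion_count_and_sizes(self, fixture_plan):
        dels = fixture_plan.truth_deletions
        assert len(dels) == 5
        by_chrom = {}
        for chrom, s, e in dels:
            by_chrom.setdefault(chrom, []).append(e - s)
        (chr8_like,) = [c for c, v in by_chrom.items() if len(v) == 4]
        (chr18_like,) = [c for c, v in by_chrom.items() if len(v) == 1]
        assert sorted(by_chrom[chr8_like]) == [456_000, 520_000, 1_957_000, 3_529_000]
        assert by_chrom[chr18_like] == [1_528_000]

    def test_seventeen_truth_junctions(self, fixture_plan):
        # 13 internal adjacencies in a 14-fragment path + 4 in a 5-fragment path
        assert len(fixture_plan.truth_junctions) == 17

    def test_at_least_four_inversions_and_two_tiny_fragments(self, fixture_plan):
        assert sum(f.strand == REVERSE for f in fixture_plan.fragments) >= 4
        assert sum(f.length < 50_000 for f in fixture_plan.fragments) >= 2

    def test_too_small_genome_rejected(self):
        g = sim.build_toy_genome({"a": 100_000, "b": 50_000}, seed=1)
        with pytest.raises(ValueError, match="too small"):
            sim.chromothripsis_fixture(g)


class TestPlanInvariants:
    def test_conservation_on_fixture(self, fixture_plan):
        self._check_conservation(fixture_plan)

    @pytest.mark.parametrize("seed", range(100))
    def test_conservation_on_random_plans(self, seed):
        plan = sim.random_plan({"cA": 400_000, "cB": 300_000}, seed=seed)
        self._check_conservation(plan)

    @staticmethod
    def _check_conservation(plan):
        """Fragment lengths plus deletion lengths tile each chromosome's
        first-to-last fragment span."""
        by_chrom = {}
        for f in plan.fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        del_by_chrom = {}
        for chrom, s, e in plan.truth_deletions:
            del_by_chrom[chrom] = del_by_chrom.get(chrom, 0) + (e - s)
        for chrom, frs in by_chrom.items():
            span = max(f.end for f in frs) - min(f.start for f in frs)
            total = sum(f.length for f in frs) + del_by_chrom.get(chrom, 0)
            assert total == span

    def test_overlapping_fragments_rejected(self, toy_genome):
        frs = [
            sim.FragmentSpec(1, "chr8t", 0, 6_000_000, FORWARD),
            sim.FragmentSpec(2, "chr8t", 5_000_000, 12_000_000, FORWARD),
            sim.FragmentSpec(3, "chr18t", 0, 6_000_000, FORWARD),
        ]
        ders = [
            sim.DerivativeLayout("d1", (1, 2)),
            sim.DerivativeLayout("d2", (3,)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sim.RearrangementPlan(genome=toy_genome, fragments=frs, derivatives=ders)


class TestRealizeDerivatives:
    def test_identity_layout_reproduces_reference(self):
        g = sim.build_toy_genome({"c1": 5_000, "c2": 4_000}, seed=3)
        plan = sim.RearrangementPlan(
            genome=g,
            fragments=[
                sim.FragmentSpec(1, "c1", 0, 5_000, FORWARD),
                sim.FragmentSpec(2, "c2", 0, 4_000, FORWARD),
            ],
            derivatives=[
                sim.DerivativeLayout("d1", (1,)),
                sim.DerivativeLayout("d2", (2,)),
            ],
        )
        rg = sim.realize_derivatives(plan)
        assert rg.sequence("d1") == g.chromosomes["c1"]
        assert plan.truth_deletions == []

    def test_reverse_fragment_is_reverse_complemented(self):
        g = sim.build_toy_genome({"c1": 6_000, "c2": 4_000}, seed=3)
        # derivative runs backward through c1: [4000,6000] then [0,1000], both "-"
        plan = sim.RearrangementPlan(
            genome=g,
            fragments=[
                sim.FragmentSpec(1, "c1", 0, 1_000, REVERSE),
                sim.FragmentSpec(2, "c1", 4_000, 6_000, REVERSE),
                sim.FragmentSpec(3, "c2", 0, 4_000, FORWARD),
            ],
            derivatives=[
                sim.DerivativeLayout("d1", (2, 1)),
                sim.DerivativeLayout("d2", (3,)),
            ],
        )
        rg = sim.realize_derivatives(plan)
        expect = sim.revcomp(g.chromosomes["c1"][4_000:6_000]) + sim.revcomp(
            g.chromosomes["c1"][:1_000]
        )
        assert rg.sequence("d1") == expect
        assert len(rg.sequence("d1")) == 2_000 + 1_000

    def test_fixture_length_conservation(self, fixture_plan):
        rg = sim.realize_derivatives(fixture_plan)
        total_der = sum(rg.lengths.values())
        total_ref = sum(fixture_plan.genome.lengths.values())
        total_del = sum(e - s for _, s, e in fixture_plan.truth_deletions)
        assert total_der == total_ref - total_del


class TestSimulateReads:
    def test_total_bases_near_target_coverage(self):
        path = {"d": [OrientedInterval("c", 0, 1_000_000, FORWARD)]}
        cfg = sim.SimReadConfig(coverage=20, length_mean=15_000, length_sd=5_000, seed=7)
        reads = sim.simulate_reads(path, cfg)
        total = sum(r.length for r in reads)
        assert abs(total - 20_000_000) / 20_000_000 < 0.10

    def test_error_free_reads_are_exact_substrings(self):
        g = sim.build_toy_genome({"c1": 30_000, "c2": 20_000}, seed=5)
        plan = sim.RearrangementPlan(
            genome=g,
            fragments=[
                sim.FragmentSpec(1, "c1", 0, 30_000, FORWARD),
                sim.FragmentSpec(2, "c2", 0, 20_000, FORWARD),
            ],
            derivatives=[
                sim.DerivativeLayout("d1", (1,)),
                sim.DerivativeLayout("d2", (2,)),
            ],
        )
        rg = sim.realize_derivatives(plan)
        cfg = sim.SimReadConfig(coverage=3, length_mean=2_000, length_sd=500, seed=9)
        for r in sim.simulate_reads(rg, cfg, emit_sequence=True):
            der = rg.sequence(r.source)
            expect = der[r.start : r.start + r.length]
            if r.strand == REVERSE:
                expect = sim.revcomp(expect)
            assert r.sequence == expect

    def test_reads_spanning_junctions_have_multiple_segments(self, fixture_plan):
        rg = sim.realize_derivatives(fixture_plan)
        cfg = sim.SimReadConfig(coverage=2, length_mean=15_000, length_sd=8_000, seed=11)
        reads = sim.simulate_reads(rg, cfg)
        multi = [r for r in reads if len(r.chain) >= 2]
        assert multi, "x2 coverage should produce junction-spanning reads"
        for r in multi[:50]:
            assert junctions_of(r.chain), "junction-spanning chains must yield junctions"

    def test_same_seed_reproduces_reads(self, fixture_plan):
        rg = sim.realize_derivatives(fixture_plan)
        cfg = sim.SimReadConfig(coverage=1, seed=13)
        a = sim.simulate_reads(rg, cfg)
        b = sim.simulate_reads(rg, cfg)
        assert [(r.read_id, r.source, r.start, r.length, r.strand) for r in a] == [
            (r.read_id, r.source, r.start, r.length, r.strand) for r in b
        ]

    def test_empty_source_set_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_reads({}, sim.SimReadConfig(seed=1))

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(ValueError):
            sim.SimReadConfig(sub_rate=0.5)


class TestControlCohort:
    def test_frequency_one_carried_by_all(self, toy_genome):
        ev = sim.CohortEvent("mobile_element_insertion", "chr8t", 4_000_000, 6_000, 1.0)
        cohort = sim.simulate_control_cohort(
            toy_genome, sim.ControlCohortSpec(5, (ev,), seed=2)
        )
        assert all(len(c) == 1 for c in cohort.carriers.values())
        for chains in cohort.chain_sets:
            junctions = {j for ch in chains for j in junctions_of(ch)}
            assert ev.junction() in junctions

    def test_half_frequency_carrier_count_within_binomial_bounds(self, toy_genome):
        ev = sim.CohortEvent("tandem_multiplication", "chr8t", 4_000_000, 4_000, 0.5)
        spec = sim.ControlCohortSpec(33, (ev,), seed=4)
        first = sim.simulate_control_cohort(toy_genome, spec)
        second = sim.simulate_control_cohort(toy_genome, spec)
        n_carriers = sum(bool(v) for v in first.carriers.values())
        assert first.carriers == second.carriers
        assert 5 <= n_carriers <= 28  # >99.9% binomial mass at p=0.5, n=33

    def test_empty_pool_gives_no_rearranged_reads(self, toy_genome):
        cohort = sim.simulate_control_cohort(
            toy_genome, sim.ControlCohortSpec(3, (), seed=5)
        )
        assert all(chains == [] for chains in cohort.chain_sets)

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortEvent("tandem_expansion", "c", 100, 2_000, 0.0)

    def test_events_avoid_plan_breakpoints(self, toy_genome, fixture_plan):
        events = sim.default_polymorphic_events(toy_genome, seed=6, plan=fixture_plan)
        truth_positions = {
            (b.chrom, b.pos)
            for j in fixture_plan.truth_junctions
            for b in j.breakends()
        }
        for ev in events:
            for b in ev.junction().breakends():
                assert all(
                    c != b.chrom or abs(p - b.pos) > 10_000 for c, p in truth_positions
                )
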