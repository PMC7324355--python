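"""End-to-end orchestration: chains -> groups -> filter -> consensus ->
derivative reconstruction -> deletions."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import ReadChain
from .alignments import chain_all, parse_paf, write_paf
from .grouping import (
    DetectionThresholds,
    EXACT_PRESET,
    FilterTrace,
    RearrangementGroup,
    group_reads,
    subtract_controls,
)
from .consensus import (
    ConsensusRearrangement,
    UnresolvableGroupError,
    consensus_rearrangement,
    dedupe_by_frame,
)
from .linking import (
    DeletionCall,
    DerivativeReconstruction,
    Fragment,
    infer_deletions,
    link,
    merge_colinear,
)
from . import simulate as sim


@dataclass
class PipelineResult:
    groups: list[RearrangementGroup]
    surviving: list[RearrangementGroup]
    trace: FilterTrace | None
    consensuses: list[ConsensusRearrangement]
    unresolved: list[tuple[str, str]]  # (group_id, reason)
    reconstructions: list[DerivativeReconstruction]
    fragments: list[Fragment]
    deletions: list[DeletionCall]
    n_input_chains: int = 0


def run_pipeline(
    chains: Sequence[ReadChain],
    chrom_lengths: Mapping[str, int],
    thresholds: DetectionThresholds = EXACT_PRESET,
    control_chain_sets: Sequence[Sequence[ReadChain]] = (),
    min_deletion: int = 10_000,
    merge_tol: int = 100,
    link_groups: bool = True,
) -> PipelineResult:
    """Run detection through reconstruction on pre-chained alignments.

    Groups whose members cannot be merged into a consistent consensus are
    reported in ``unresolved`` (never silently dropped); linking uses the
    remaining consensuses.
    """
    groups = group_reads(chains, thresholds)
    if control_chain_sets:
        surviving, trace = subtract_controls(groups, control_chain_sets, thresholds)
    else:
        surviving, trace = list(groups), None
    consensuses: list[ConsensusRearrangement] = []
    unresolved: list[tuple[str, str]] = []
    for grp in surviving:
        try:
            consensuses.append(
                consensus_rearrangement(
                    grp.group_id,
                    grp.members,
                    match_tol=thresholds.match_tol,
                    colinear_gap_tol=thresholds.colinear_gap_tol,
                )
            )
        except UnresolvableGroupError as exc:
            unresolved.append((grp.group_id, str(exc)))
    consensuses = dedupe_by_frame(consensuses)
    reconstructions: list[DerivativeReconstruction] = []
    fragments: list[Fragment] = []
    deletions: list[DeletionCall] = []
    if link_groups and consensuses:
        reconstructions = link(consensuses, chrom_lengths)
        for recon in reconstructions:
            fragments.extend(merge_colinear(recon, merge_tol))
        deletions = infer_deletions(
            reconstructions, chrom_lengths, min_size=min_deletion, merge_tol=merge_tol
        )
    return PipelineResult(
        groups=groups,
        surviving=surviving,
        trace=trace,
        consensuses=consensuses,
        unresolved=unresolved,
        reconstructions=reconstructions,
        fragments=fragments,
        deletions=deletions,
        n_input_chains=len(chains),
    )


def paf_round_trip(
    chains: Sequence[ReadChain], min_seg_len: int = 200, max_overlap: int = 50
) -> list[ReadChain]:
    """Serialize chains to PAF text and re-chain the parsed records.

    Exercises the same text path a real alignment file would take.
    """
    buf = io.StringIO()
    write_paf(chains, buf)
    buf.seek(0)
    return chain_all(parse_paf(buf), min_seg_len=min_seg_len, max_overlap=max_overlap)


def fixture_replay(
    genome_seed: int = 1,
    read_seed: int = 1,
    coverage: float = 20.0,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    thresholds: DetectionThresholds | None = None,
    via_paf: bool = True,
    control_chain_sets: Sequence[Sequence[ReadChain]] = (),
) -> tuple[sim.RearrangementPlan, PipelineResult]:
    """Simulate the canonical chromothripsis fixture and run the pipeline.

    Error-free by default; with nonzero error rates the noisy detection
    preset (match tolerance 1 kb) is used unless thresholds are given.
    """
    from .grouping import NOISY_PRESET

    genome = sim.fixture_genome(genome_seed)
    plan = sim.chromothripsis_fixture(genome)
    rg = sim.realize_derivatives(plan)
    cfg = sim.SimReadConfig(
        coverage=coverage,
        length_mean=15_000,
        length_sd=10_000,
        sub_rate=sub_rate,
        ins_rate=ins_rate,
        del_rate=del_rate,
        seed=read_seed,
    )
    reads = sim.simulate_reads(rg, cfg)
    chains = [r.chain for r in reads]
    if thresholds is None:
        thresholds = EXACT_PRESET if cfg.total_error == 0 else NOISY_PRESET
    if via_paf:
        chains = paf_round_trip(chains)
    result = run_pipeline(
        chains,
        plan.genome.lengths,
        thresholds=thresholds,
        control_chain_sets=control_chain_sets,
    )
    return plan, result
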