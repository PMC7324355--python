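"""Synthetic genomes, planted chromothripsis, simulated long reads, and
control cohorts.

Everything downstream of alignment is testable without external data: the
simulator emits a toy two-chromosome reference, derivative chromosomes built
from a fragment plan, long reads with known (oracle) segment chains, and
control read sets carrying population-polymorphic events (mobile-element
insertions, tandem expansions/multiplications) that the control filter must
remove.

The canonical fixture replays a germline t(8;18)-style chromothripsis: 19
fragments across two derivative chromosomes (14 + 5), with four large
deletions on the chr8 analog (456, 1957, 520 and 3529 kb) and one on the
chr18 analog (1528 kb).  The toy chromosomes are 12 Mb and 6 Mb so the whole
pipeline runs at desk scale while deletion sizes stay at their true printed
scale.

All randomness flows through named, seeded ``numpy`` generators; no global
RNG state is touched.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .model import (
    FORWARD,
    REVERSE,
    AlignedSegment,
    Junction,
    OrientedInterval,
    ReadChain,
    make_junction,
    path_junctions,
    reverse_chain,
)
from .consensus import ConsensusRearrangement

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: junctions flanking a fragment shorter than this merge into one read group
#: (a read spanning the whole fragment sees both junctions)
DEFAULT_GROUP_SPAN = 50_000

#: truth junctions closer than this to reference contiguity are rejected as
#: colinear (they would not be observable as rearrangements)
COLINEARITY_GUARD = 2_000


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class ToyGenome:
    """Uniform-random toy reference (a stand-in for a real assembly).

    Uniform base sampling means repeated k-mers are possible for small k; no
    uniqueness guarantee is made (irrelevant here because alignment itself is
    out of scope).
    """

    chromosomes: dict[str, str]
    seed: int

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]


def build_toy_genome(chrom_lengths: Mapping[str, int], seed: int) -> ToyGenome:
    """Reproducible uniform-random chromosomes (>= 1 kb each)."""
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"chromosome {name!r}: length must be >= 1 kb, got {length}")
    rng = np.random.default_rng(seed)
    chromosomes = {
        name: _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for name, length in chrom_lengths.items()
    }
    return ToyGenome(chromosomes=chromosomes, seed=seed)


# ---------------------------------------------------------------------------
# rearrangement plans


@dataclass(frozen=True)
class FragmentSpec:
    """One breakpoint-to-breakpoint reference fragment and the orientation
    with which its derivative traverses it."""

    id: int
    chrom: str
    start: int
    end: int
    strand: str  # "+" = forward, "-" = reverse

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"fragment {self.id}: invalid interval")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"fragment {self.id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> OrientedInterval:
        return OrientedInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class DerivativeLayout:
    name: str
    fragment_ids: tuple[int, ...]


@dataclass
class RearrangementPlan:
    """Ground truth for a simulated rearranged genome.

    ``truth_deletions`` are the maximal reference intervals covered by no
    fragment and interior to each chromosome's fragment span;
    ``truth_junctions`` are exactly the adjacencies between consecutive
    fragments of each derivative.  ``truth_groups`` partitions the junction
    indices into expected read groups: junctions flanking a fragment shorter
    than ``group_span`` are co-spanned by single reads and merge.
    """

    genome: ToyGenome
    fragments: list[FragmentSpec]
    derivatives: list[DerivativeLayout]
    group_span: int = DEFAULT_GROUP_SPAN
    truth_junctions: list[Junction] = field(init=False)
    truth_deletions: list[tuple[str, int, int]] = field(init=False)
    truth_groups: list[list[int]] = field(init=False)

    def __post_init__(self) -> None:
        self._validate()
        self.truth_junctions = self._junctions()
        self.truth_deletions = self._deletions()
        self.truth_groups = self._groups()

    # -- derived views ---------------------------------------------------

    def fragment_by_id(self, fid: int) -> FragmentSpec:
        return self._by_id[fid]

    def derivative_path(self, name: str) -> list[OrientedInterval]:
        layout = next(d for d in self.derivatives if d.name == name)
        return [self._by_id[fid].interval() for fid in layout.fragment_ids]

    def derivative_junctions(self, name: str) -> list[Junction]:
        return path_junctions(self.derivative_path(name))

    # -- construction helpers --------------------------------------------

    def _validate(self) -> None:
        self._by_id = {f.id: f for f in self.fragments}
        if len(self._by_id) != len(self.fragments):
            raise ValueError("fragment ids are not unique")
        lengths = self.genome.lengths
        for f in self.fragments:
            if f.chrom not in lengths:
                raise ValueError(f"fragment {f.id}: unknown chromosome {f.chrom!r}")
            if f.end > lengths[f.chrom]:
                raise ValueError(f"fragment {f.id}: extends past chromosome end")
        by_chrom: dict[str, list[FragmentSpec]] = {}
        for f in self.fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        for chrom, frs in by_chrom.items():
            frs = sorted(frs, key=lambda f: f.start)
            for a, b in zip(frs, frs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"fragments {a.id} and {b.id} overlap on {chrom}: a single "
                        "germline rearranged allele cannot use a region twice"
                    )
        used = [fid for d in self.derivatives for fid in d.fragment_ids]
        if sorted(used) != sorted(self._by_id):
            raise ValueError("each fragment id must appear in exactly one derivative")
        for d in self.derivatives:
            first = self._by_id[d.fragment_ids[0]]
            last = self._by_id[d.fragment_ids[-1]]
            if not self._at_terminus(first, entry=True):
                raise ValueError(f"{d.name}: first fragment must reach a chromosome terminus")
            if not self._at_terminus(last, entry=False):
                raise ValueError(f"{d.name}: last fragment must reach a chromosome terminus")
            for j in path_junctions([self._by_id[f].interval() for f in d.fragment_ids]):
                a, b = j.breakends()
                if (
                    a.chrom == b.chrom
                    and a.side != b.side
                    and abs(a.pos - b.pos) <= COLINEARITY_GUARD
                ):
                    raise ValueError(f"{d.name}: colinear adjacency {j} is not a junction")

    def _at_terminus(self, f: FragmentSpec, entry: bool) -> bool:
        L = self.genome.lengths[f.chrom]
        b = f.interval().entry_breakend() if entry else f.interval().exit_breakend()
        return b.pos in (0, L)

    def _junctions(self) -> list[Junction]:
        out: list[Junction] = []
        for d in self.derivatives:
            out.extend(self.derivative_junctions(d.name))
        return out

    def _deletions(self) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[FragmentSpec]] = {}
        for f in self.fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        for chrom in sorted(by_chrom):
            frs = sorted(by_chrom[chrom], key=lambda f: f.start)
            for a, b in zip(frs, frs[1:]):
                if b.start > a.end:
                    out.append((chrom, a.end, b.start))
        return out

    def _groups(self) -> list[list[int]]:
        groups: list[list[int]] = []
        idx = 0
        for d in self.derivatives:
            ids = d.fragment_ids
            n_j = len(ids) - 1
            current = [idx]
            for k in range(1, n_j):
                # junction k shares a fragment (ids[k]) with junction k-1
                if self._by_id[ids[k]].length < self.group_span:
                    current.append(idx + k)
                else:
                    groups.append(current)
                    current = [idx + k]
            if current:
                groups.append(current)
            idx += n_j
        return groups


# ---------------------------------------------------------------------------
# the canonical two-derivative fixture

CHR_A = "chr8t"
CHR_B = "chr18t"
FIXTURE_LENGTHS = {CHR_A: 12_000_000, CHR_B: 6_000_000}

# reference tiling of the chr8 analog, in kb: fragment pieces a1..a15 with the
# four deletions (456, 1957, 520, 3529 kb) between them, and of the chr18
# analog: b1..b4 around the single 1528 kb deletion.  Three pieces (a4, a9,
# a13) are tiny (< 50 kb) so that single reads span them entirely.
_PIECES_KB = {
    "a1": (CHR_A, 0, 500),
    "a2": (CHR_A, 500, 900),
    # deletion 900-1356 (456 kb)
    "a3": (CHR_A, 1356, 1806),
    "a4": (CHR_A, 1806, 1836),
    "a5": (CHR_A, 1836, 2336),
    # deletion 2336-4293 (1957 kb)
    "a6": (CHR_A, 4293, 4713),
    "a7": (CHR_A, 4713, 5113),
    # deletion 5113-5633 (520 kb)
    "a8": (CHR_A, 5633, 6033),
    "a9": (CHR_A, 6033, 6053),
    "a10": (CHR_A, 6053, 6553),
    "a11": (CHR_A, 6553, 6953),
    # deletion 6953-10482 (3529 kb)
    "a12": (CHR_A, 10482, 11260),
    "a13": (CHR_A, 11260, 11300),
    "a14": (CHR_A, 11300, 11700),
    "a15": (CHR_A, 11700, 12_000),
    "b1": (CHR_B, 0, 1200),
    "b2": (CHR_B, 1200, 2272),
    # deletion 2272-3800 (1528 kb)
    "b3": (CHR_B, 3800, 4900),
    "b4": (CHR_B, 4900, 6000),
}

# derivative layouts: fragment id -> (piece, orientation).  The scramble and
# the orientation vector (8 of 19 fragments inverted) are fixed constants;
# the printed source text does not pin per-fragment orientations, and none of
# the reconstruction counts depend on which fragments are inverted.
_FIXTURE_LAYOUT: dict[int, tuple[str, str]] = {
    1: ("a1", FORWARD),
    2: ("a7", REVERSE),
    3: ("a4", FORWARD),
    4: ("a11", FORWARD),
    5: ("a2", REVERSE),
    6: ("b3", REVERSE),
    7: ("b2", FORWARD),
    8: ("a9", FORWARD),
    9: ("a5", REVERSE),
    10: ("a12", FORWARD),
    11: ("a3", REVERSE),
    12: ("a8", FORWARD),
    13: ("a6", FORWARD),
    14: ("b4", FORWARD),
    15: ("b1", FORWARD),
    16: ("a13", REVERSE),
    17: ("a10", REVERSE),
    18: ("a14", REVERSE),
    19: ("a15", FORWARD),
}
_FIXTURE_DERIVATIVES = {
    "derA": tuple(range(1, 15)),
    "derB": tuple(range(15, 20)),
}


def chromothripsis_fixture(genome: ToyGenome) -> RearrangementPlan:
    """The canonical t(8;18)-style chromothripsis plan on ``genome``.

    The genome's largest chromosome (>= 12 Mb) hosts the chr8-analog
    fragments and the second (>= 6 Mb) the chr18-analog fragments; terminal
    fragments extend to the actual chromosome ends.
    """
    by_len = sorted(genome.lengths.items(), key=lambda kv: -kv[1])
    if len(by_len) < 2:
        raise ValueError("fixture needs two chromosomes")
    (name_a, len_a), (name_b, len_b) = by_len[0], by_len[1]
    if len_a < FIXTURE_LENGTHS[CHR_A] or len_b < FIXTURE_LENGTHS[CHR_B]:
        raise ValueError(
            "genome too small to host the fixture deletions: needs >= 12 Mb and >= 6 Mb"
        )
    rename = {CHR_A: name_a, CHR_B: name_b}
    fragments = []
    for fid, (piece, strand) in sorted(_FIXTURE_LAYOUT.items()):
        chrom, start_kb, end_kb = _PIECES_KB[piece]
        start, end = start_kb * 1000, end_kb * 1000
        # terminal pieces stretch to the true chromosome end
        if (chrom, end) == (CHR_A, 12_000_000):
            end = len_a
        if (chrom, end) == (CHR_B, 6_000_000):
            end = len_b
        fragments.append(FragmentSpec(fid, rename[chrom], start, end, strand))
    derivatives = [
        DerivativeLayout(name, ids) for name, ids in _FIXTURE_DERIVATIVES.items()
    ]
    return RearrangementPlan(genome=genome, fragments=fragments, derivatives=derivatives)


def fixture_genome(seed: int = 1) -> ToyGenome:
    return build_toy_genome(FIXTURE_LENGTHS, seed)


# ---------------------------------------------------------------------------
# realized derivatives


@dataclass
class RearrangedGenome:
    """Derivative chromosomes realized from a plan (sequences on demand)."""

    plan: RearrangementPlan
    paths: dict[str, list[OrientedInterval]]
    _seq_cache: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: sum(iv.length for iv in path) for name, path in self.paths.items()}

    def sequence(self, name: str) -> str:
        if name not in self._seq_cache:
            genome = self.plan.genome
            parts = []
            for iv in self.paths[name]:
                s = genome.fetch(iv.chrom, iv.start, iv.end)
                parts.append(s if iv.strand == FORWARD else revcomp(s))
            self._seq_cache[name] = "".join(parts)
        return self._seq_cache[name]


def realize_derivatives(plan: RearrangementPlan) -> RearrangedGenome:
    """Concatenate fragment subsequences (reverse-complemented on "-")."""
    paths = {d.name: plan.derivative_path(d.name) for d in plan.derivatives}
    return RearrangedGenome(plan=plan, paths=paths)


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class SimReadConfig:
    """Long-read simulation settings.

    Lengths are log-normal with the given real-space mean/sd, truncated to
    [500, sequence length]; defaults echo a nanopore run with mean read
    length ~11.5 kb.  Error rates are per-base; all-zero rates give the
    exact error-free mode in which every read is a perfect substring of its
    derivative and its true segment chain is emitted.
    """

    coverage: float = 20.0
    length_mean: float = 11_451.0
    length_sd: float = 9_000.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")

    @property
    def total_error(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass
class SimRead:
    read_id: str
    source: str
    start: int
    length: int
    strand: str
    chain: ReadChain
    sequence: str | None = None


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _true_chain(
    read_id: str,
    path: Sequence[OrientedInterval],
    offsets: Sequence[int],
    start: int,
    end: int,
) -> ReadChain:
    """Exact reference segment chain of derivative interval [start, end)."""
    segs: list[AlignedSegment] = []
    for iv, off in zip(path, offsets):
        lo = max(start, off)
        hi = min(end, off + iv.length)
        if lo >= hi:
            continue
        if iv.strand == FORWARD:
            ref_start = iv.start + (lo - off)
            ref_end = iv.start + (hi - off)
        else:
            ref_end = iv.end - (lo - off)
            ref_start = iv.end - (hi - off)
        segs.append(
            AlignedSegment(
                read_id=read_id,
                read_start=lo - start,
                read_end=hi - start,
                ref_chrom=iv.chrom,
                ref_start=ref_start,
                ref_end=ref_end,
                strand=iv.strand,
                identity=1.0,
                read_length=end - start,
            )
        )
    return ReadChain(read_id=read_id, segments=segs, read_length=end - start)


def _jitter_chain(chain: ReadChain, max_jitter: int, rng: np.random.Generator) -> ReadChain:
    """Emulate alignment-endpoint wobble under sequencing error.

    Aligners trim noisy alignments short of the true breakpoint, so each
    junction-facing segment end is trimmed by up to ``max_jitter`` bases
    (consistently on read and reference); segments too short to trim safely
    are left alone.  Reference breakpoints therefore wobble inward by up to
    ``max_jitter``, which the match tolerance downstream must absorb.
    """
    if max_jitter <= 0 or len(chain.segments) < 2:
        return chain
    segs = list(chain.segments)
    out: list[AlignedSegment] = []
    for i, s in enumerate(segs):
        d_left = int(rng.integers(0, max_jitter + 1)) if i > 0 else 0
        d_right = int(rng.integers(0, max_jitter + 1)) if i < len(segs) - 1 else 0
        if s.read_span <= d_left + d_right + 300:
            d_left = d_right = 0
        read_start = s.read_start + d_left
        read_end = s.read_end - d_right
        if s.strand == FORWARD:
            ref_start, ref_end = s.ref_start + d_left, s.ref_end - d_right
        else:
            ref_start, ref_end = s.ref_start + d_right, s.ref_end - d_left
        out.append(
            AlignedSegment(
                read_id=s.read_id,
                read_start=read_start,
                read_end=read_end,
                ref_chrom=s.ref_chrom,
                ref_start=ref_start,
                ref_end=ref_end,
                strand=s.strand,
                identity=s.identity,
                read_length=s.read_length,
            )
        )
    return ReadChain(read_id=chain.read_id, segments=out, read_length=chain.read_length)


def _apply_errors(seq: str, cfg: SimReadConfig, rng: np.random.Generator) -> str:
    if cfg.total_error == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    subs = rng.random(n) < cfg.sub_rate
    if subs.any():
        arr[subs] = _BASES[rng.integers(0, 4, size=int(subs.sum()))]
    keep = rng.random(n) >= cfg.del_rate
    arr = arr[keep]
    n_ins = rng.binomial(len(arr), cfg.ins_rate)
    if n_ins:
        at = np.sort(rng.integers(0, len(arr) + 1, size=n_ins))
        arr = np.insert(arr, at, _BASES[rng.integers(0, 4, size=n_ins)])
    return arr.tobytes().decode("ascii")


def simulate_reads(
    rearranged: RearrangedGenome | Mapping[str, Sequence[OrientedInterval]],
    config: SimReadConfig,
    emit_sequence: bool = False,
    read_prefix: str = "read",
) -> list[SimRead]:
    """Sample reads uniformly over each source sequence with oracle chains.

    Read start positions are uniform; lengths log-normal truncated to
    [500, source length]; each read is sampled on a uniformly random strand.
    In error-free mode the returned chain is the exact reference segment
    chain of the read; with nonzero error rates, alignment-endpoint wobble
    proportional to the total error rate is applied to the chain and base
    errors (if ``emit_sequence``) to the sequence.
    """
    if isinstance(rearranged, RearrangedGenome):
        rg: RearrangedGenome | None = rearranged
        paths = rearranged.paths
    else:
        rg = None
        paths = dict(rearranged)
    if not paths:
        raise ValueError("no source sequences to simulate from")
    rng = np.random.default_rng(config.seed)
    mu, sigma = _lognormal_params(config.length_mean, config.length_sd)
    max_jitter = min(300, int(round(config.total_error * 4000)))
    reads: list[SimRead] = []
    idx = 0
    for name in sorted(paths):
        path = list(paths[name])
        total = sum(iv.length for iv in path)
        offsets = list(np.cumsum([0] + [iv.length for iv in path])[:-1])
        n_reads = int(round(config.coverage * total / config.length_mean))
        if n_reads < 1:
            raise ValueError("coverage x length / mean read length must be >= 1")
        lengths = np.clip(
            rng.lognormal(mu, sigma, size=n_reads).astype(np.int64), 500, total
        )
        starts = rng.integers(0, np.maximum(1, total - lengths + 1))
        strands = rng.integers(0, 2, size=n_reads)
        for L, s0, fl in zip(lengths, starts, strands):
            read_id = f"{read_prefix}{idx:06d}"
            idx += 1
            chain = _true_chain(read_id, path, offsets, int(s0), int(s0 + L))
            strand = REVERSE if fl else FORWARD
            if strand == REVERSE:
                chain = reverse_chain(chain)
            if config.total_error > 0:
                chain = _jitter_chain(chain, max_jitter, rng)
            seq = None
            if emit_sequence:
                if rg is None:
                    raise ValueError("sequence emission needs a RearrangedGenome")
                seq = rg.sequence(name)[int(s0) : int(s0 + L)]
                if strand == REVERSE:
                    seq = revcomp(seq)
                seq = _apply_errors(seq, config, rng)
            reads.append(
                SimRead(
                    read_id=read_id,
                    source=name,
                    start=int(s0),
                    length=int(L),
                    strand=strand,
                    chain=chain,
                    sequence=seq,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# control cohorts

EVENT_KINDS = ("mobile_element_insertion", "tandem_expansion", "tandem_multiplication")


@dataclass(frozen=True)
class CohortEvent:
    """A population-polymorphic rearrangement shared across samples."""

    kind: str
    chrom: str
    pos: int
    size: int  # inserted length, or duplicated unit span for tandem events
    frequency: float
    element: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0 < self.frequency <= 1:
            raise ValueError("event frequency must be in (0, 1]")
        if self.size <= 0:
            raise ValueError("event size must be positive")

    def junction(self) -> Junction:
        """The canonical junction signature this event leaves in reads."""
        from .model import Breakend, HEAD, TAIL

        if self.kind == "mobile_element_insertion":
            # unaligned insert: reference resumes where it stopped
            return make_junction(
                Breakend(self.chrom, self.pos, HEAD), Breakend(self.chrom, self.pos, TAIL)
            )
        # tandem events: the reference steps backward by one unit
        return make_junction(
            Breakend(self.chrom, self.pos + self.size, HEAD),
            Breakend(self.chrom, self.pos, TAIL),
        )


@dataclass(frozen=True)
class ControlCohortSpec:
    n_controls: int
    events: tuple[CohortEvent, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("need at least one control")


def event_read_chains(
    event: CohortEvent,
    n_reads: int,
    rng: np.random.Generator,
    read_prefix: str,
    flank_range: tuple[int, int] = (3_000, 9_000),
) -> list[ReadChain]:
    """Read chains supporting one polymorphic event (error-free geometry)."""
    chains = []
    for i in range(n_reads):
        fl1 = int(rng.integers(*flank_range))
        fl2 = int(rng.integers(*flank_range))
        rid = f"{read_prefix}_e{i}"
        if event.kind == "mobile_element_insertion":
            gap = event.size
            total = fl1 + gap + fl2
            segs = [
                AlignedSegment(rid, 0, fl1, event.chrom, event.pos - fl1, event.pos, FORWARD, 1.0, total),
                AlignedSegment(rid, fl1 + gap, total, event.chrom, event.pos, event.pos + fl2, FORWARD, 1.0, total),
            ]
        else:
            u = event.size
            total = fl1 + 2 * u + fl2
            segs = [
                AlignedSegment(rid, 0, fl1 + u, event.chrom, event.pos - fl1, event.pos + u, FORWARD, 1.0, total),
                AlignedSegment(rid, fl1 + u, total, event.chrom, event.pos, event.pos + u + fl2, FORWARD, 1.0, total),
            ]
        chain = ReadChain(rid, segs, read_length=total)
        if rng.integers(0, 2):
            chain = reverse_chain(chain)
        chains.append(chain)
    return chains


@dataclass
class ControlCohort:
    spec: ControlCohortSpec
    carriers: dict[int, list[CohortEvent]]  # control index -> carried events
    chain_sets: list[list[ReadChain]]  # one list of read chains per control


def simulate_control_cohort(
    genome: ToyGenome,
    spec: ControlCohortSpec,
    reads_per_event: int = 4,
) -> ControlCohort:
    """Each control carries each pooled event independently at its frequency.

    By construction controls never carry planted chromothripsis junctions:
    the only rearranged reads they contain support the pooled polymorphic
    events.
    """
    lengths = genome.lengths
    for ev in spec.events:
        if ev.chrom not in lengths:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if not 0 < ev.pos < lengths[ev.chrom]:
            raise ValueError("event locus outside chromosome")
    rng = np.random.default_rng(spec.seed)
    carriers: dict[int, list[CohortEvent]] = {}
    chain_sets: list[list[ReadChain]] = []
    for c in range(spec.n_controls):
        carried = [ev for ev in spec.events if rng.random() < ev.frequency]
        carriers[c] = carried
        chains: list[ReadChain] = []
        for k, ev in enumerate(carried):
            chains.extend(
                event_read_chains(ev, reads_per_event, rng, read_prefix=f"ctl{c}_ev{k}")
            )
        chain_sets.append(chains)
    return ControlCohort(spec=spec, carriers=carriers, chain_sets=chain_sets)


def default_polymorphic_events(
    genome: ToyGenome,
    seed: int,
    n_events: int = 6,
    plan: "RearrangementPlan | None" = None,
) -> tuple[CohortEvent, ...]:
    """A small pool of toy population-polymorphic events.

    Kinds cycle through the supported types; loci are drawn uniformly with a
    50 kb margin from chromosome ends and at least 20 kb from any plan
    breakpoint, so cohort events never collide with planted chromothripsis
    junctions.
    """
    rng = np.random.default_rng(seed)
    forbidden: dict[str, list[int]] = {}
    if plan is not None:
        for j in plan.truth_junctions:
            for b in j.breakends():
                forbidden.setdefault(b.chrom, []).append(b.pos)
    chroms = sorted(genome.lengths)
    events: list[CohortEvent] = []
    kinds = ["mobile_element_insertion", "tandem_expansion", "tandem_multiplication"]
    sizes = {"mobile_element_insertion": 6000, "tandem_expansion": 2000, "tandem_multiplication": 4000}
    while len(events) < n_events:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = genome.lengths[chrom]
        pos = int(rng.integers(50_000, L - 50_000))
        if any(abs(pos - p) < 20_000 for p in forbidden.get(chrom, [])):
            continue
        kind = kinds[len(events) % len(kinds)]
        freq = float(rng.uniform(0.3, 0.95))
        events.append(CohortEvent(kind=kind, chrom=chrom, pos=pos, size=sizes[kind], frequency=freq))
    return tuple(events)


def patient_event_chains(
    events: Sequence[CohortEvent],
    reads_per_event: int,
    seed: int,
    read_prefix: str = "pat",
) -> list[ReadChain]:
    """Chains planting the pooled polymorphic events in the patient sample."""
    rng = np.random.default_rng(seed)
    chains: list[ReadChain] = []
    for k, ev in enumerate(events):
        chains.extend(
            event_read_chains(ev, reads_per_event, rng, read_prefix=f"{read_prefix}_ev{k}")
        )
    return chains


# ---------------------------------------------------------------------------
# truth-derived consensus (for linking the plan without read simulation)


def truth_consensus(
    plan: RearrangementPlan, flank: int = 10_000
) -> list[ConsensusRearrangement]:
    """One ConsensusRearrangement per truth group, built from the plan.

    Outer segments extend ``flank`` bases into the flanking fragments (at
    most half a fragment, so open ends stay strictly inside fragments);
    fragments interior to a group are included whole.
    """
    crs: list[ConsensusRearrangement] = []
    # map junction global index -> (derivative, local adjacency index)
    locate: list[tuple[str, int]] = []
    for d in plan.derivatives:
        for k in range(len(d.fragment_ids) - 1):
            locate.append((d.name, k))
    for g, jidx in enumerate(plan.truth_groups):
        dname, first = locate[jidx[0]]
        layout = next(d for d in plan.derivatives if d.name == dname)
        frag_ids = layout.fragment_ids[first : first + len(jidx) + 1]
        ivs = [plan.fragment_by_id(f).interval() for f in frag_ids]
        segments: list[OrientedInterval] = []
        for i, iv in enumerate(ivs):
            ext = max(1, min(flank, iv.length // 2))
            if i == 0:  # keep the exit-adjacent part
                iv = (
                    OrientedInterval(iv.chrom, iv.end - ext, iv.end, iv.strand)
                    if iv.strand == FORWARD
                    else OrientedInterval(iv.chrom, iv.start, iv.start + ext, iv.strand)
                )
            elif i == len(ivs) - 1:  # keep the entry-adjacent part
                iv = (
                    OrientedInterval(iv.chrom, iv.start, iv.start + ext, iv.strand)
                    if iv.strand == FORWARD
                    else OrientedInterval(iv.chrom, iv.end - ext, iv.end, iv.strand)
                )
            segments.append(iv)
        crs.append(
            ConsensusRearrangement(
                group_id=f"G{g}",
                segments=segments,
                junctions=path_junctions(segments),
                support=1,
                spreads=[0] * len(jidx),
            )
        )
    return crs


# ---------------------------------------------------------------------------
# random plans


def random_plan(
    chrom_lengths: Mapping[str, int],
    seed: int,
    n_fragments: tuple[int, int] = (2, 5),
    min_piece: int = 30_000,
    deletion_prob: float = 0.4,
    max_tries: int = 200,
) -> RearrangementPlan:
    """A random two-derivative plan with scrambled orders and orientations.

    Each of the two chromosomes is tiled into fragments and optional interior
    deletions; derivative 1 runs from chromosome 1's left terminus to
    chromosome 2's right terminus, derivative 2 the reciprocal.  Layouts
    whose adjacencies would be colinear (unobservable junctions) are
    rejected and redrawn.
    """
    names = sorted(chrom_lengths)
    if len(names) != 2:
        raise ValueError("random_plan expects exactly two chromosomes")
    rng = np.random.default_rng(seed)
    genome_seed = int(rng.integers(0, 2**31 - 1))
    genome = build_toy_genome(chrom_lengths, genome_seed)
    for _ in range(max_tries):
        try:
            fragments, derivatives = _random_layout(
                genome, rng, n_fragments, min_piece, deletion_prob
            )
            return RearrangementPlan(genome=genome, fragments=fragments, derivatives=derivatives)
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid random plan")


def _random_layout(genome, rng, n_fragments, min_piece, deletion_prob):
    names = sorted(genome.lengths)
    pieces: dict[str, list[tuple[str, int, int, bool]]] = {}
    for chrom in names:
        L = genome.lengths[chrom]
        n = int(rng.integers(n_fragments[0], n_fragments[1] + 1))
        n_pieces = n + int(rng.integers(0, 3))  # up to 2 interior deletions
        weights = rng.dirichlet(np.ones(n_pieces))
        sizes = (min_piece + weights * (L - n_pieces * min_piece)).astype(np.int64)
        sizes[-1] = L - int(sizes[:-1].sum())
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        deleted = set()
        interior = list(range(1, n_pieces - 1))
        rng.shuffle(interior)
        for i in interior[: n_pieces - n]:
            deleted.add(i)
        pieces[chrom] = [
            (chrom, int(bounds[i]), int(bounds[i + 1]), i in deleted)
            for i in range(n_pieces)
        ]
    frag_pieces = {c: [p for p in pv if not p[3]] for c, pv in pieces.items()}
    c1, c2 = names
    first1, last1 = frag_pieces[c1][0], frag_pieces[c1][-1]
    first2, last2 = frag_pieces[c2][0], frag_pieces[c2][-1]
    middles = [p for c in names for p in frag_pieces[c][1:-1] if p not in (first1, first2, last1, last2)]
    rng.shuffle(middles)
    n_mid_1 = int(rng.integers(0, len(middles) + 1))
    path1 = [(first1, FORWARD)] + [
        (p, REVERSE if rng.integers(0, 2) else FORWARD) for p in middles[:n_mid_1]
    ] + [(last2, FORWARD)]
    path2 = [(first2, FORWARD)] + [
        (p, REVERSE if rng.integers(0, 2) else FORWARD) for p in middles[n_mid_1:]
    ] + [(last1, REVERSE)]
    # last1 reversed: derivative 2 ends by running back into chromosome 1's
    # right terminus; its exit breakend must reach a terminus, and the right
    # terminal piece traversed "-" exits at pos == L only when flipped again.
    # Simpler: traverse it forward and put it last -> exit at L.
    path2[-1] = (last1, FORWARD)
    fragments = []
    fid = 1
    layouts = []
    for dname, path in (("der1", path1), ("der2", path2)):
        ids = []
        for (chrom, start, end, _), strand in path:
            fragments.append(FragmentSpec(fid, chrom, start, end, strand))
            ids.append(fid)
            fid += 1
        layouts.append(DerivativeLayout(dname, tuple(ids)))
    return fragments, layouts


# ---------------------------------------------------------------------------
# serialization


def write_fasta(sequences: Mapping[str, str], handle: IO[str], width: int = 80) -> None:
    for name in sequences:
        handle.write(f">{name}\n")
        seq = sequences[name]
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[SimRead], handle: IO[str]) -> None:
    for r in reads:
        if r.sequence is None:
            raise ValueError(f"read {r.read_id} has no sequence; simulate with emit_sequence")
        handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_tables(plan: RearrangementPlan, prefix: str) -> None:
    """Fragments/junctions TSV, deletions BED6, and the whole plan as JSON."""
    with open(f"{prefix}.fragments.tsv", "w") as fh:
        fh.write("id\tchrom\tstart\tend\torientation\tderivative\trank\n")
        for d in plan.derivatives:
            for rank, fid in enumerate(d.fragment_ids, start=1):
                f = plan.fragment_by_id(fid)
                fh.write(
                    f"{f.id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{d.name}\t{rank}\n"
                )
    with open(f"{prefix}.junctions.tsv", "w") as fh:
        fh.write("chromA\tposA\tsideA\tchromB\tposB\tsideB\n")
        for j in plan.truth_junctions:
            a, b = j.breakends()
            fh.write(f"{a.chrom}\t{a.pos}\t{a.side}\t{b.chrom}\t{b.pos}\t{b.side}\n")
    with open(f"{prefix}.deletions.bed", "w") as fh:
        for i, (chrom, start, end) in enumerate(plan.truth_deletions, start=1):
            fh.write(f"{chrom}\t{start}\t{end}\tdeletion_{i}\t{end - start}\t.\n")
    with open(f"{prefix}.plan.json", "w") as fh:
        json.dump(plan_to_dict(plan), fh, indent=1)


def plan_to_dict(plan: RearrangementPlan) -> dict:
    return {
        "chromosomes": plan.genome.lengths,
        "genome_seed": plan.genome.seed,
        "fragments": [
            {"id": f.id, "chrom": f.chrom, "start": f.start, "end": f.end, "strand": f.strand}
            for f in plan.fragments
        ],
        "derivatives": {d.name: list(d.fragment_ids) for d in plan.derivatives},
        "truth_junctions": [str(j) for j in plan.truth_junctions],
        "truth_deletions": [list(d) for d in plan.truth_deletions],
        "truth_groups": plan.truth_groups,
    }
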