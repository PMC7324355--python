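"""Core data model shared by every pipeline stage.

Coordinates are 0-based half-open throughout; 1-based inclusive appears only
in human-readable reports and VCF output.

A *breakend* is one oriented side of a rearrangement breakpoint.  The side
encodes which reference flank is retained in the rearranged allele:

``head``
    the allele arrives at ``pos`` from smaller reference coordinates, i.e.
    the retained flank lies at coordinates <= pos (the breakend sits at the
    3' end of the retained segment on the forward reference strand).
``tail``
    the allele continues from ``pos`` toward larger coordinates, i.e. the
    retained flank lies at coordinates >= pos.

A junction joins two breakends.  Junctions are stored in a canonical order
so that the same physical adjacency compares equal no matter which direction
a read traversed it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

HEAD = "head"
TAIL = "tail"

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    pos: int
    side: str  # HEAD or TAIL

    def __post_init__(self) -> None:
        if self.side not in (HEAD, TAIL):
            raise ValueError(f"invalid breakend side: {self.side!r}")


@dataclass(frozen=True, order=True)
class Junction:
    """A canonical adjacency between two oriented reference breakends.

    ``breakend_a <= breakend_b`` lexicographically by (chrom, pos, side);
    use :func:`make_junction` rather than the constructor to guarantee it.
    """

    breakend_a: Breakend
    breakend_b: Breakend

    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.breakend_a, self.breakend_b)

    def is_interchromosomal(self) -> bool:
        return self.breakend_a.chrom != self.breakend_b.chrom

    def __str__(self) -> str:  # breakend notation used in TSV output
        a, b = self.breakend_a, self.breakend_b
        return f"{a.chrom}:{a.pos}:{a.side}-{b.chrom}:{b.pos}:{b.side}"


def make_junction(a: Breakend, b: Breakend) -> Junction:
    if (b.chrom, b.pos, b.side) < (a.chrom, a.pos, a.side):
        a, b = b, a
    return Junction(a, b)


def junctions_match(x: Junction, y: Junction, tol: int) -> bool:
    """True if both breakends agree in chrom and side and lie within ``tol``.

    Both pairings are tried because canonical order can differ between two
    noisy observations of the same junction.
    """

    def bmatch(p: Breakend, q: Breakend) -> bool:
        return p.chrom == q.chrom and p.side == q.side and abs(p.pos - q.pos) <= tol

    xa, xb = x.breakends()
    ya, yb = y.breakends()
    return (bmatch(xa, ya) and bmatch(xb, yb)) or (bmatch(xa, yb) and bmatch(xb, ya))


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned block of a read.

    Read coordinates are always on the read's forward orientation (the PAF
    convention); ``strand`` records which reference strand that forward read
    matched.
    """

    read_id: str
    read_start: int
    read_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float = 1.0
    read_length: int = 0  # full read length when the source format carries it

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError(f"{self.read_id}: read_start must be < read_end")
        if not self.ref_start < self.ref_end:
            raise ValueError(f"{self.read_id}: ref_start must be < ref_end")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"{self.read_id}: invalid strand {self.strand!r}")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ReadChain:
    """A read's aligned segments ordered along the read."""

    read_id: str
    segments: list[AlignedSegment]
    read_length: int = 0

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.read_start, s.read_end))
        if self.read_length == 0 and self.segments:
            self.read_length = max(s.read_end for s in self.segments)

    def __len__(self) -> int:
        return len(self.segments)


def reverse_chain(chain: ReadChain) -> ReadChain:
    """The chain as it would appear if the read were reverse-complemented."""
    L = chain.read_length
    segs = [
        AlignedSegment(
            read_id=s.read_id,
            read_start=L - s.read_end,
            read_end=L - s.read_start,
            ref_chrom=s.ref_chrom,
            ref_start=s.ref_start,
            ref_end=s.ref_end,
            strand=FORWARD if s.strand == REVERSE else REVERSE,
            identity=s.identity,
        )
        for s in chain.segments
    ]
    return ReadChain(chain.read_id, segs, read_length=L)


@dataclass(frozen=True)
class OrientedInterval:
    """A reference interval traversed in a given direction."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def reversed(self) -> "OrientedInterval":
        return OrientedInterval(
            self.chrom,
            self.start,
            self.end,
            FORWARD if self.strand == REVERSE else REVERSE,
        )

    def entry_breakend(self) -> Breakend:
        """Breakend at which the allele enters this interval."""
        if self.strand == FORWARD:
            return Breakend(self.chrom, self.start, TAIL)
        return Breakend(self.chrom, self.end, HEAD)

    def exit_breakend(self) -> Breakend:
        """Breakend at which the allele leaves this interval."""
        if self.strand == FORWARD:
            return Breakend(self.chrom, self.end, HEAD)
        return Breakend(self.chrom, self.start, TAIL)


def path_junctions(path: Sequence[OrientedInterval]) -> list[Junction]:
    """Canonical junction for each adjacent pair of a traversal path."""
    return [
        make_junction(a.exit_breakend(), b.entry_breakend())
        for a, b in zip(path, path[1:])
    ]


def reverse_path(path: Sequence[OrientedInterval]) -> list[OrientedInterval]:
    return [iv.reversed() for iv in reversed(path)]
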