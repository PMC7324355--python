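"""Reading split alignments and extracting rearrangement junctions.

Alignments arrive as PAF (minimap2/LAST ``last-split | maf-convert paf``
dialects) or MAF (LAST dialect).  No alignment is computed here: each read's
records are chained along the read, and every adjacent pair of segments that
is not colinear with the reference yields one junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

from Bio import AlignIO

from .model import (
    FORWARD,
    HEAD,
    REVERSE,
    TAIL,
    AlignedSegment,
    Breakend,
    Junction,
    ReadChain,
    make_junction,
)

#: defaults tolerate nanopore indel noise while keeping >= 1 kb events
DEFAULT_MIN_SEG_LEN = 200
DEFAULT_MAX_OVERLAP = 50
DEFAULT_COLINEAR_GAP_TOL = 1000


def parse_paf(lines: Iterable[str]) -> list[AlignedSegment]:
    """Parse PAF records into aligned segments.

    Query coordinates in PAF are already on the read's forward orientation,
    so they are taken as-is; ``identity`` is residue matches over alignment
    block length.  Extra SAM-style tag columns are ignored.
    """
    segments: list[AlignedSegment] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"PAF line {lineno}: expected >= 12 columns, got {len(fields)}")
        try:
            qlen = int(fields[1])
            qstart = int(fields[2])
            qend = int(fields[3])
            tstart = int(fields[7])
            tend = int(fields[8])
            matches = int(fields[9])
            block = int(fields[10])
        except ValueError as exc:
            raise ValueError(f"PAF line {lineno}: non-integer coordinate field") from exc
        strand = fields[4]
        if strand not in (FORWARD, REVERSE):
            raise ValueError(f"PAF line {lineno}: unknown strand {strand!r}")
        segments.append(
            AlignedSegment(
                read_id=fields[0],
                read_start=qstart,
                read_end=qend,
                ref_chrom=fields[5],
                ref_start=tstart,
                ref_end=tend,
                strand=strand,
                identity=matches / block if block > 0 else 0.0,
                read_length=qlen,
            )
        )
    return segments


def write_paf(chains: Iterable[ReadChain], handle: IO[str]) -> None:
    """Serialize chains as minimal 12-column PAF."""
    for chain in chains:
        for s in chain.segments:
            block = max(s.read_span, s.ref_span)
            matches = round(s.identity * block)
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        chain.read_id,
                        chain.read_length,
                        s.read_start,
                        s.read_end,
                        s.strand,
                        s.ref_chrom,
                        0,
                        s.ref_start,
                        s.ref_end,
                        matches,
                        block,
                        60,
                    )
                )
                + "\n"
            )


def parse_maf(handle: IO[str]) -> list[AlignedSegment]:
    """Parse LAST-style MAF blocks; the second s-line of each block is the query.

    MAF records coordinates on the annotated strand; minus-strand query
    coordinates are converted to forward-read coordinates
    ``[read_len - start - size, read_len - start)``.
    """
    segments: list[AlignedSegment] = []
    for block in AlignIO.parse(handle, "maf"):
        if len(block) < 2:
            raise ValueError("MAF block with fewer than two s-lines")
        ref, qry = block[0], block[1]
        rann, qann = ref.annotations, qry.annotations
        rstart, rsize, rstrand = rann["start"], rann["size"], rann["strand"]
        qstart, qsize, qstrand, qsrc = (
            qann["start"],
            qann["size"],
            qann["strand"],
            qann["srcSize"],
        )
        if rstrand not in (1, -1) or qstrand not in (1, -1):
            raise ValueError("MAF s-line with unknown strand")
        if rstrand == -1:
            # normalize the reference line to forward coordinates and fold
            # the flip into the segment strand
            rsrc = rann["srcSize"]
            rstart = rsrc - rstart - rsize
        if qstrand == 1:
            read_start = qstart
        else:
            read_start = qsrc - qstart - qsize
        cols = len(ref.seq)
        matches = sum(
            1 for a, b in zip(str(ref.seq).upper(), str(qry.seq).upper()) if a == b and a != "-"
        )
        segments.append(
            AlignedSegment(
                read_id=qry.id,
                read_start=read_start,
                read_end=read_start + qsize,
                ref_chrom=ref.id,
                ref_start=rstart,
                ref_end=rstart + rsize,
                strand=FORWARD if rstrand == qstrand else REVERSE,
                identity=matches / cols if cols else 0.0,
                read_length=qsrc,
            )
        )
    return segments


def chain_segments(
    segments: Iterable[AlignedSegment],
    min_seg_len: int = DEFAULT_MIN_SEG_LEN,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> ReadChain:
    """Chain one read's segments along the read.

    Segments shorter than ``min_seg_len`` on the read are dropped; among
    segments overlapping on the read by more than ``max_overlap`` bases the
    higher identity x length score wins.  Secondary/supplementary status is
    not distinguished: all records of the read compete.
    """
    segs = [s for s in segments if s.read_span >= min_seg_len]
    if not segs:
        return ReadChain(read_id="", segments=[], read_length=0)
    read_ids = {s.read_id for s in segs}
    if len(read_ids) != 1:
        raise ValueError(f"chain_segments got multiple read ids: {sorted(read_ids)}")
    read_len = max(max(s.read_end for s in segs), max(s.read_length for s in segs))
    kept: list[AlignedSegment] = []
    for s in sorted(segs, key=lambda s: (-s.identity * s.read_span, s.read_start)):
        if all(
            min(s.read_end, k.read_end) - max(s.read_start, k.read_start) <= max_overlap
            for k in kept
        ):
            kept.append(s)
    return ReadChain(read_id=segs[0].read_id, segments=kept, read_length=read_len)


def group_by_read(segments: Iterable[AlignedSegment]) -> dict[str, list[AlignedSegment]]:
    by_read: dict[str, list[AlignedSegment]] = {}
    for s in segments:
        by_read.setdefault(s.read_id, []).append(s)
    return by_read


def chain_all(
    segments: Iterable[AlignedSegment],
    min_seg_len: int = DEFAULT_MIN_SEG_LEN,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[ReadChain]:
    chains = []
    for read_id, segs in sorted(group_by_read(segments).items()):
        chain = chain_segments(segs, min_seg_len, max_overlap)
        if chain.segments:
            chains.append(chain)
    return chains


@dataclass(frozen=True)
class JunctionObs:
    """One junction as observed in one read, with local geometry.

    ``ref_gap`` is the signed reference advance between the two segments in
    the read's direction of travel (None across chromosomes or strands);
    ``read_gap`` is the unaligned read length between them.
    """

    junction: Junction
    left: AlignedSegment
    right: AlignedSegment
    read_gap: int
    ref_gap: int | None


def _pair_geometry(a: AlignedSegment, b: AlignedSegment) -> tuple[int, int | None]:
    read_gap = b.read_start - a.read_end
    if a.ref_chrom != b.ref_chrom or a.strand != b.strand:
        return read_gap, None
    if a.strand == FORWARD:
        ref_gap = b.ref_start - a.ref_end
    else:
        ref_gap = a.ref_start - b.ref_end
    return read_gap, ref_gap


def is_colinear(a: AlignedSegment, b: AlignedSegment, tol: int) -> bool:
    """Adjacent segments consistent with unrearranged reference.

    Same chromosome, same strand, and reference advance consistent with the
    read advance within ``tol`` (this also rejects large unaligned inserts,
    whose read gap far exceeds the reference gap).
    """
    read_gap, ref_gap = _pair_geometry(a, b)
    return ref_gap is not None and abs(ref_gap - read_gap) <= tol


def junction_observations(
    chain: ReadChain, colinear_gap_tol: int = DEFAULT_COLINEAR_GAP_TOL
) -> list[JunctionObs]:
    """One observation per non-colinear adjacent segment pair of the chain.

    Breakend sides follow the strand of each flanking segment: the left
    segment contributes its exit breakend (ref_end/head on "+", ref_start/tail
    on "-"), the right segment its entry breakend (ref_start/tail on "+",
    ref_end/head on "-").  With junction micro-homology the breakend position
    comes from each segment's own alignment edge, so the left segment defines
    the left breakend even when the two alignments overlap slightly on the
    reference.
    """
    obs: list[JunctionObs] = []
    for a, b in zip(chain.segments, chain.segments[1:]):
        if is_colinear(a, b, colinear_gap_tol):
            continue
        left = (
            Breakend(a.ref_chrom, a.ref_end, HEAD)
            if a.strand == FORWARD
            else Breakend(a.ref_chrom, a.ref_start, TAIL)
        )
        right = (
            Breakend(b.ref_chrom, b.ref_start, TAIL)
            if b.strand == FORWARD
            else Breakend(b.ref_chrom, b.ref_end, HEAD)
        )
        read_gap, ref_gap = _pair_geometry(a, b)
        obs.append(
            JunctionObs(
                junction=make_junction(left, right),
                left=a,
                right=b,
                read_gap=read_gap,
                ref_gap=ref_gap,
            )
        )
    return obs


def junctions_of(
    chain: ReadChain, colinear_gap_tol: int = DEFAULT_COLINEAR_GAP_TOL
) -> list[Junction]:
    return [o.junction for o in junction_observations(chain, colinear_gap_tol)]


def write_junction_table(chains: Iterable[ReadChain], handle: IO[str], tol: int = DEFAULT_COLINEAR_GAP_TOL) -> None:
    handle.write("read_id\tchromA\tposA\tsideA\tchromB\tposB\tsideB\n")
    for chain in chains:
        for j in junctions_of(chain, tol):
            a, b = j.breakends()
            handle.write(
                f"{chain.read_id}\t{a.chrom}\t{a.pos}\t{a.side}\t{b.chrom}\t{b.pos}\t{b.side}\n"
            )
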