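"""Breakend (BND) VCF output for consensus junctions.

Each junction becomes one MATEID-paired pair of BND records.  Positions are
1-based per the VCF spec; the bracket notation encodes which side of each
breakend joins the mate:

* retained flank toward smaller coordinates (side ``head``) joined to a mate
  whose retained flank is also toward smaller -> ``N]mate]``
* head joined to a tail-side mate -> ``N[mate[``
* tail joined to a head-side mate -> ``]mate]N``
* tail joined to a tail-side mate -> ``[mate[N``
"""

from __future__ import annotations

from typing import IO, Mapping, Sequence

from .model import HEAD
from .consensus import ConsensusRearrangement


def write_bnd_vcf(
    crs: Sequence[ConsensusRearrangement],
    chrom_lengths: Mapping[str, int],
    handle: IO[str],
    sample_name: str = "sample",
) -> None:
    handle.write("##fileformat=VCFv4.2\n")
    for chrom in sorted(chrom_lengths):
        handle.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
    handle.write('##ALT=<ID=BND,Description="Breakend">\n')
    handle.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
    handle.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
    handle.write('##INFO=<ID=GROUPID,Number=1,Type=String,Description="Read group">\n')
    handle.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n')
    handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    rows = []
    k = 0
    for cr in crs:
        for j in cr.junctions:
            a, b = j.breakends()
            ida, idb = f"bnd_{k}a", f"bnd_{k}b"
            k += 1
            for this, mate, this_id, mate_id in ((a, b, ida, idb), (b, a, idb, ida)):
                pos = this.pos if this.side == HEAD else this.pos + 1
                mate_pos = mate.pos if mate.side == HEAD else mate.pos + 1
                mate_str = f"{mate.chrom}:{mate_pos}"
                if this.side == HEAD:
                    alt = f"N]{mate_str}]" if mate.side == HEAD else f"N[{mate_str}["
                else:
                    alt = f"]{mate_str}]N" if mate.side == HEAD else f"[{mate_str}[N"
                rows.append(
                    (
                        this.chrom,
                        pos,
                        f"{this.chrom}\t{pos}\t{this_id}\tN\t{alt}\t.\tPASS\t"
                        f"SVTYPE=BND;MATEID={mate_id};GROUPID={cr.group_id};"
                        f"SUPPORT={cr.support}\n",
                    )
                )
    for _, _, line in sorted(rows):
        handle.write(line)
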