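"""Event classification, gene impact, and relative expression (ddCt).

Patient-only rearrangements fall into a small set of recurring classes:
members of a multi-breakpoint chromothripsis event, tandem multiplications
and repeat expansions (the reference steps backward at the junction),
retrotransposon insertions (unaligned read sequence matching a mobile
element consensus), and a residual class.  Gene impact is read off the
reconstruction: a gene wholly inside a deletion is lost, a gene containing
a breakpoint is disrupted, anything else is intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import pandas as pd

from .model import HEAD, Breakend, Junction
from .consensus import ConsensusRearrangement
from .linking import DeletionCall

CHROMOTHRIPSIS_MEMBER = "chromothripsis_member"
TANDEM_MULTIPLICATION = "tandem_multiplication"
REPEAT_EXPANSION = "repeat_expansion"
MOBILE_ELEMENT_INSERTION = "mobile_element_insertion"
OTHER = "other"

#: backward loops up to this span are repeat expansions, larger ones tandem
#: multiplications (the two phenomena differ in unit size, not geometry)
DEFAULT_UNIT_THRESHOLD = 500


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.name}: start must be < end")


@dataclass(frozen=True)
class GeneImpact:
    gene: str
    status: str  # deleted | disrupted | intact
    evidence: str


@dataclass(frozen=True)
class ElementLibrary:
    """Consensus sequences of mobile-element families (toy L1/Alu/SVA analogs)."""

    elements: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.elements or any(not s for s in self.elements.values()):
            raise ValueError("element library needs nonempty sequences")


def _loop_span(j: Junction) -> int | None:
    """Backward reference step of a strand-preserving junction, if any."""
    a, b = j.breakends()
    if a.chrom != b.chrom or a.side == b.side:
        return None
    head, tail = (a, b) if a.side == HEAD else (b, a)
    span = head.pos - tail.pos
    return span if span > 0 else None


def match_element(
    insert_seq: str, library: ElementLibrary, id_threshold: float
) -> str | None:
    """Best library element matching the insert at the identity threshold.

    The element consensus is aligned infix-style within the insert; a hit
    needs identity >= threshold over at least half of the insert's length.
    """
    best_name, best_id = None, 0.0
    for name in sorted(library.elements):
        elem = library.elements[name]
        res = edlib.align(elem, insert_seq, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        identity = 1.0 - res["editDistance"] / len(elem)
        loc = res["locations"][0]
        covered = loc[1] - loc[0] + 1
        if identity >= id_threshold and covered >= 0.5 * len(insert_seq) and identity > best_id:
            best_name, best_id = name, identity
    return best_name


def classify_event(
    cr: ConsensusRearrangement,
    library: ElementLibrary | None = None,
    id_threshold: float = 0.8,
    linked_group_ids: Sequence[str] = (),
    insert_seq: str | None = None,
    unit_threshold: int = DEFAULT_UNIT_THRESHOLD,
) -> str:
    """Category of one patient-only consensus rearrangement.

    Rules apply in order: (1) inter-chromosomal junctions or membership in a
    linked multi-group component mean chromothripsis; (2) backward reference
    loops are tandem multiplications (span > unit threshold) or repeat
    expansions; (3) an unaligned insert matching a library element is a
    mobile-element insertion (category suffixed with the element name);
    (4) anything else is ``other``.  The rule order makes the classification
    total: every consensus gets exactly one category.
    """
    if cr.group_id in set(linked_group_ids) or any(
        j.is_interchromosomal() for j in cr.junctions
    ):
        return CHROMOTHRIPSIS_MEMBER
    spans = [s for j in cr.junctions if (s := _loop_span(j)) is not None]
    if spans:
        span = max(spans)
        return TANDEM_MULTIPLICATION if span > unit_threshold else REPEAT_EXPANSION
    if insert_seq and library is not None:
        name = match_element(insert_seq, library, id_threshold)
        if name is not None:
            return f"{MOBILE_ELEMENT_INSERTION}:{name}"
    return OTHER


def gene_impact(
    deletions: Sequence[DeletionCall],
    junctions: Sequence[Junction],
    genes: Sequence[GeneModel],
) -> list[GeneImpact]:
    """Impact of the reconstruction on each gene (deterministic).

    deleted: the gene interval lies fully inside one deletion; disrupted: a
    breakend falls strictly inside the gene, or a deletion boundary cuts
    through it; intact: neither.
    """
    breakends: list[Breakend] = []
    for j in junctions:
        breakends.extend(j.breakends())
    out: list[GeneImpact] = []
    for g in genes:
        status, evidence = "intact", "no overlapping deletion or breakpoint"
        for d in deletions:
            if d.chrom != g.chrom:
                continue
            if d.start <= g.start and g.end <= d.end:
                status, evidence = "deleted", f"inside deletion {d.chrom}:{d.start}-{d.end}"
                break
            if g.start < d.end and d.start < g.end:
                status, evidence = (
                    "disrupted",
                    f"cut by deletion boundary {d.chrom}:{d.start}-{d.end}",
                )
        if status == "intact":
            for b in breakends:
                if b.chrom == g.chrom and g.start < b.pos < g.end:
                    status, evidence = "disrupted", f"breakpoint {b.chrom}:{b.pos} inside gene"
                    break
        out.append(GeneImpact(gene=g.name, status=status, evidence=evidence))
    return out


def read_gene_bed(handle) -> list[GeneModel]:
    """BED4 (chrom, start, end, name)."""
    genes = []
    for line in handle:
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, name = line.split()[:4]
        genes.append(GeneModel(name=name, chrom=chrom, start=int(start), end=int(end)))
    return genes


def delta_delta_ct(
    table: pd.DataFrame, patient_sample: str = "patient"
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    Per row, dCt = Ct_gene - Ct_reference.  For each gene, ddCt is the
    patient's mean dCt minus the mean dCt of all control samples, and the
    fold change is 2**(-ddCt).  The replicate SD is the standard deviation of
    per-replicate fold changes (each patient replicate's dCt against the
    control mean).

    ``table`` needs columns sample, gene, reference_gene, ct_gene,
    ct_reference (and optionally replicate).
    """
    required = {"sample", "gene", "reference_gene", "ct_gene", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    for idx, row in table.iterrows():
        for col in ("ct_gene", "ct_reference"):
            v = row[col]
            if pd.isna(v):
                raise ValueError(
                    f"row {idx} (sample={row['sample']}, gene={row['gene']}): missing {col}"
                )
            if v <= 0:
                raise ValueError(
                    f"row {idx} (sample={row['sample']}, gene={row['gene']}): Ct must be positive"
                )
    df = table.copy()
    df["dct"] = df["ct_gene"] - df["ct_reference"]
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        pat = sub[sub["sample"] == patient_sample]
        ctl = sub[sub["sample"] != patient_sample]
        if pat.empty:
            raise ValueError(f"gene {gene}: no patient rows")
        if ctl.empty:
            raise ValueError(f"gene {gene}: no control samples")
        control_mean = ctl["dct"].mean()
        ddct = pat["dct"].mean() - control_mean
        folds = 2.0 ** -(pat["dct"] - control_mean)
        rows.append(
            {
                "gene": gene,
                "delta_delta_ct": float(ddct),
                "fold_change": float(2.0**-ddct),
                "fold_sd": float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                "n_patient_replicates": int(len(pat)),
                "n_control_samples": int(ctl["sample"].nunique()),
            }
        )
    return pd.DataFrame(rows)
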