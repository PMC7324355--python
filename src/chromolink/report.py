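"""End-to-end report rendering (JSON + Markdown summary).

The report joins whatever stages completed: group counts by category, the
control-filter trace, per-derivative fragment tables, deletion calls, gene
impacts, and the expression table.  Missing stages are listed rather than
fabricated, and rendering is deterministic (byte-identical across reruns of
the same inputs).
"""

from __future__ import annotations

import json
from typing import Any, Mapping, Sequence

import pandas as pd

from .grouping import FilterTrace, RearrangementGroup
from .linking import DeletionCall, DerivativeReconstruction, Fragment
from .annotate import GeneImpact


def build_report(
    groups: Sequence[RearrangementGroup] | None = None,
    categories: Mapping[str, str] | None = None,
    trace: FilterTrace | None = None,
    reconstructions: Sequence[DerivativeReconstruction] | None = None,
    fragments: Sequence[Fragment] | None = None,
    deletions: Sequence[DeletionCall] | None = None,
    gene_impacts: Sequence[GeneImpact] | None = None,
    expression: pd.DataFrame | None = None,
) -> dict[str, Any]:
    report: dict[str, Any] = {"missing_sections": []}

    if groups is not None:
        by_cat: dict[str, int] = {}
        for grp in groups:
            cat = (categories or {}).get(grp.group_id) or ",".join(sorted(grp.categories)) or "uncategorized"
            by_cat[cat] = by_cat.get(cat, 0) + 1
        report["groups"] = {
            "n_groups": len(groups),
            "by_category": dict(sorted(by_cat.items())),
            "support": {g.group_id: g.support for g in groups},
        }
    else:
        report["missing_sections"].append("groups")

    if trace is not None:
        report["filter_trace"] = [list(t) for t in trace.counts]
    else:
        report["missing_sections"].append("filter_trace")

    if reconstructions is not None:
        report["derivatives"] = {}
        for recon in reconstructions:
            frs = [f for f in (fragments or []) if f.derivative == recon.name]
            report["derivatives"][recon.name] = {
                "start_terminus": list(recon.start_terminus),
                "end_terminus": list(recon.end_terminus),
                "n_groups": len(recon.group_ids),
                "n_fragments": len(frs),
                "fragments": [
                    {
                        "rank": f.rank,
                        "chrom": f.chrom,
                        "start": f.start,
                        "end": f.end,
                        "strand": f.strand,
                        "length": f.length,
                    }
                    for f in sorted(frs, key=lambda f: f.rank)
                ],
            }
        report["n_derivatives"] = len(reconstructions)
        report["n_fragments_total"] = len(fragments or [])
    else:
        report["missing_sections"].append("derivatives")

    if deletions is not None:
        report["deletions"] = [
            {"chrom": d.chrom, "start": d.start, "end": d.end, "length": d.length}
            for d in sorted(deletions, key=lambda d: (d.chrom, d.start))
        ]
    else:
        report["missing_sections"].append("deletions")

    if gene_impacts is not None:
        report["gene_impacts"] = [
            {"gene": gi.gene, "status": gi.status, "evidence": gi.evidence}
            for gi in gene_impacts
        ]
    else:
        report["missing_sections"].append("gene_impacts")

    if expression is not None:
        report["expression"] = expression.to_dict(orient="records")
    else:
        report["missing_sections"].append("expression")

    return report


def report_json(report: Mapping[str, Any]) -> str:
    return json.dumps(report, indent=1, sort_keys=True)


def report_markdown(report: Mapping[str, Any]) -> str:
    lines = ["# Rearrangement reconstruction report", ""]
    groups = report.get("groups")
    if groups:
        lines += [f"## Patient-only groups: {groups['n_groups']}", ""]
        for cat, n in groups["by_category"].items():
            lines.append(f"- {cat}: {n}")
        lines.append("")
    if "filter_trace" in report:
        trace = report["filter_trace"]
        if trace:
            lines += [
                "## Control subtraction",
                "",
                f"{trace[0][1]} groups after control 1, "
                f"{trace[-1][1]} after control {trace[-1][0]}.",
                "",
            ]
    if "derivatives" in report:
        lines += [
            f"## Derivative chromosomes: {report['n_derivatives']} "
            f"({report['n_fragments_total']} fragments)",
            "",
        ]
        for name, d in report["derivatives"].items():
            lines.append(
                f"### {name}: {d['n_fragments']} fragments from {d['n_groups']} groups"
            )
            lines.append("")
            lines.append("| rank | chrom | start | end | strand | length |")
            lines.append("|---|---|---|---|---|---|")
            for f in d["fragments"]:
                lines.append(
                    f"| {f['rank']} | {f['chrom']} | {f['start']} | {f['end']} "
                    f"| {f['strand']} | {f['length']} |"
                )
            lines.append("")
    if "deletions" in report:
        lines += [f"## Deletions: {len(report['deletions'])}", ""]
        for d in report["deletions"]:
            lines.append(f"- {d['chrom']}:{d['start']}-{d['end']} ({d['length'] / 1000:.0f} kb)")
        lines.append("")
    if "gene_impacts" in report:
        lines += ["## Gene impact", ""]
        for gi in report["gene_impacts"]:
            lines.append(f"- {gi['gene']}: {gi['status']} ({gi['evidence']})")
        lines.append("")
    if "expression" in report:
        lines += ["## Relative expression (ddCt)", ""]
        for row in report["expression"]:
            lines.append(
                f"- {row['gene']}: fold {row['fold_change']:.2f} "
                f"(sd {row['fold_sd']:.2f}, ddCt {row['delta_delta_ct']:.2f})"
            )
        lines.append("")
    if report.get("missing_sections"):
        lines += ["## Missing sections", ""]
        for s in report["missing_sections"]:
            lines.append(f"- {s}")
        lines.append("")
    return "\n".join(lines)
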