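"""Run outputs: candidate table, funnel, provenance, insertion report,
network exports, and the human-readable markdown report.

All writers are byte-deterministic given identical inputs and config: rows
are emitted in sorted order and no timestamps are stamped anywhere.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import PipelineConfig
from .io import header_comment
from .model import CandidateTable, FilterFunnel, PatientCallset, SVType, TwoWayReport

CANDIDATE_COLUMNS = [
    "patient", "sv_id", "chrom", "start", "end", "type", "size_bp", "genes",
    "mane_exon_ranges", "exonic_hits", "regulatory_elements", "cns_genes",
    "shared_with", "population_evidence",
]


def write_candidates(
    table: CandidateTable, path: str | Path, config: PipelineConfig
) -> None:
    rows = []
    for r in sorted(
        table.rows,
        key=lambda r: (r.patient_id, r.sv.interval.chrom, r.sv.interval.start, r.sv.sv_id),
    ):
        sv = r.sv
        mane = [h for h in r.annotation.exonic_hits]
        rows.append({
            "patient": r.patient_id,
            "sv_id": sv.sv_id,
            "chrom": sv.interval.chrom,
            "start": sv.interval.start,
            "end": sv.interval.end,
            "type": sv.svtype.value,
            "size_bp": sv.svlen,
            "genes": ",".join(r.annotation.genes),
            "mane_exon_ranges": "|".join(f"{t}:{rg}" for t, rg in mane),
            "exonic_hits": str(len(r.annotation.exonic_hits)),
            "regulatory_elements": ",".join(r.annotation.regulatory_hits),
            "cns_genes": ",".join(r.annotation.cns_genes),
            "shared_with": ",".join(r.shared_with),
            "population_evidence": r.population_evidence,
        })
    with open(path, "w") as fh:
        fh.write(header_comment(config) + "\n")
        pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_candidates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)


def write_funnel(funnel: FilterFunnel, path: str | Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment(config) + "\n")
        fh.write("stage\tcount\n")
        for stage, count in funnel.as_dict().items():
            fh.write(f"{stage}\t{count}\n")


def read_funnel(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["stage"], df["count"].astype(int)))


def write_provenance(callsets: Sequence[PatientCallset], path: str | Path) -> None:
    """JSON-lines: one object per SV with its ordered filter decisions."""
    with open(path, "w") as fh:
        for cs in sorted(callsets, key=lambda c: c.patient_id):
            for sv in sorted(cs.variants, key=lambda v: v.sv_id):
                obj = {
                    "sv_id": sv.sv_id,
                    "patient": sv.patient_id,
                    "type": sv.svtype.value,
                    "rules": [
                        {"rule": d.rule_name, "outcome": d.outcome.value, "detail": d.detail}
                        for d in sv.provenance
                    ],
                }
                fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_provenance(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


INSERTION_COLUMNS = [
    "patient", "sv_id", "site", "site_exonic", "site_regulatory", "hit_chrom",
    "hit_start", "hit_end", "strand", "identity", "aligned_length", "score",
    "self_site", "origin_genes", "origin_elements",
]


def write_insertion_reports(
    reports: Sequence[tuple[str, TwoWayReport]], path: str | Path,
    config: PipelineConfig,
) -> None:
    """One row per (insertion, origin hit); a hit-less insertion gets one
    row with empty hit columns so the site annotation is still on record."""
    rows = []
    for patient, rep in sorted(reports, key=lambda pr: (pr[0], pr[1].sv_id)):
        site_exonic = "|".join(f"{t}:{rg}" for t, rg in rep.site_features.exonic_hits)
        site_reg = ",".join(rep.site_features.regulatory_hits)
        base = {
            "patient": patient, "sv_id": rep.sv_id, "site": "",
            "site_exonic": site_exonic, "site_regulatory": site_reg,
        }
        if not rep.origin_hits:
            rows.append({**base, "hit_chrom": "", "hit_start": "", "hit_end": "",
                         "strand": "", "identity": "", "aligned_length": "",
                         "score": "", "self_site": "", "origin_genes": "",
                         "origin_elements": ""})
        for h in rep.origin_hits:
            rows.append({
                **base,
                "hit_chrom": h.target.chrom,
                "hit_start": h.target.start,
                "hit_end": h.target.end,
                "strand": h.strand,
                "identity": f"{h.identity:.4f}",
                "aligned_length": h.aligned_length,
                "score": h.score,
                "self_site": int(h.is_self_site),
                "origin_genes": ",".join(h.origin_genes),
                "origin_elements": ",".join(h.origin_elements),
            })
    with open(path, "w") as fh:
        fh.write(header_comment(config) + "\n")
        pd.DataFrame(rows, columns=INSERTION_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_insertion_reports(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)


def write_convergence(convergences, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdistinct_sv_count\tlinked_candidates\tis_candidate\n")
        for c in convergences:
            fh.write(
                f"{c.gene}\t{c.distinct_sv_count}\t{','.join(c.linked_candidates)}"
                f"\t{int(c.is_candidate_itself)}\n"
            )


def read_convergence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)


def render_report(
    table: CandidateTable,
    funnel: FilterFunnel,
    insertion_reports: Sequence[tuple[str, TwoWayReport]],
    convergence_by_patient: dict[str, dict[str, list]],
    path: str | Path,
) -> None:
    """Markdown summary: per-patient candidates, funnel, convergence tables."""
    lines = ["# SV prioritization report", ""]
    lines += ["## Filter funnel", "", "| stage | SVs |", "|---|---|"]
    for stage, count in funnel.as_dict().items():
        lines.append(f"| {stage} | {count} |")
    lines.append("")

    patients = sorted({r.patient_id for r in table.rows} | set(convergence_by_patient))
    if not table.rows:
        lines += ["## Candidates", "", "No candidate SVs survived the cascade.", ""]
    for pid in patients:
        rows = [r for r in table.rows if r.patient_id == pid]
        lines += [f"## Patient {pid}", ""]
        if rows:
            lines += [
                "| sv_id | coordinates | type | size (bp) | genes | MANE exons "
                "| regulatory | shared with |",
                "|---|---|---|---|---|---|---|---|",
            ]
            for r in sorted(rows, key=lambda r: r.sv.sv_id):
                sv = r.sv
                mane = "; ".join(f"{t}: {rg}" for t, rg in r.annotation.exonic_hits)
                lines.append(
                    f"| {sv.sv_id} | {sv.interval} | {sv.svtype.value} | {sv.svlen} "
                    f"| {','.join(r.annotation.genes)} | {mane} "
                    f"| {','.join(r.annotation.regulatory_hits)} "
                    f"| {','.join(r.shared_with)} |"
                )
        else:
            lines.append("No candidate SVs for this patient.")
        lines.append("")
        ins = [rep for p, rep in insertion_reports if p == pid]
        if ins:
            lines.append("### Insertion origins")
            lines.append("")
            for rep in sorted(ins, key=lambda r: r.sv_id):
                if rep.origin_hits:
                    for h in rep.origin_hits:
                        lines.append(
                            f"- {rep.sv_id}: origin {h.target} ({h.strand}) "
                            f"identity {h.identity:.3f}, elements "
                            f"{','.join(h.origin_elements) or 'none'}"
                        )
                else:
                    lines.append(f"- {rep.sv_id}: no origin at the identity cutoff")
            lines.append("")
        conv = convergence_by_patient.get(pid, {})
        for source, nodes in sorted(conv.items()):
            lines.append(f"### Convergence nodes ({source})")
            lines.append("")
            if nodes:
                for c in nodes:
                    lines.append(
                        f"- {c.gene}: bridges {c.distinct_sv_count} SVs via "
                        f"{','.join(c.linked_candidates)}"
                    )
            else:
                lines.append("No inter-SV gene connectivity detected.")
            lines.append("")
    Path(path).write_text("\n".join(lines))
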