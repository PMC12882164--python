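"""Run the SV exclusion/inclusion cascade on a synthetic patient cohort.

Generates a miniature world (reference, annotations, population databases,
six patient callsets with planted candidates and decoys), runs the
prioritization cascade, and prints the filter funnel and candidate table.
"""

import tempfile
from pathlib import Path

from svprio.config import PipelineConfig
from svprio.io import (
    read_expression, read_gene_models, read_population_db, read_regulatory,
    read_roi, read_sv_vcf,
)
from svprio.model import PopSource
from svprio.prioritize import ResourceBundle, run_prioritization
from svprio.synth import WorldParams, generate_world

with tempfile.TemporaryDirectory() as tmp:
    world = Path(tmp) / "world"
    generate_world(WorldParams(rng_seed=17), world)

    callsets = [read_sv_vcf(p) for p in sorted((world / "patients").glob("*.vcf"))]
    resources = ResourceBundle(
        roi=read_roi(world / "roi.tsv"),
        dgv=read_population_db(world / "dgv.tsv", PopSource.DGV_GOLD),
        gnomad=read_population_db(world / "gnomad.tsv", PopSource.GNOMAD_CNV),
        transcripts=read_gene_models(world / "genes.gff3"),
        regulatory=read_regulatory(world / "regulatory.tsv"),
        expression=read_expression(world / "expression.tsv"),
    )
    table, funnel = run_prioritization(callsets, resources, PipelineConfig())

print("Filter funnel (SVs surviving each stage):")
for stage, count in funnel.as_dict().items():
    print(f"  {stage:>20}: {count}")
print(f"\n{len(table)} candidate SVs. First five rows:")
for row in table.rows[:5]:
    sv = row.sv
    exons = "; ".join(f"{t}:{r}" for t, r in row.annotation.exonic_hits) or "-"
    print(f"  {row.patient_id} {sv.sv_id:12s} {sv.svtype.value} {sv.interval} "
          f"({sv.svlen} bp) exons[{exons}] reg[{','.join(row.annotation.regulatory_hits) or '-'}]")
print("\nEach surviving SV is rare (no reliable common population match), not"
      "\ncohort-recurrent, under 5 Mb, and carries an inclusion signal: an exon"
      "\noverlap, a regulatory element, or a CNS-expressed gene.")
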