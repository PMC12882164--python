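"""End-to-end orchestration: load inputs, run every stage, write outputs.

A run specification names each input file; the synthetic world layout
produced by :func:`svprio.synth.generate_world` maps onto it directly. A
run is fully deterministic given the inputs and configuration: rerunning
with the same seed and config produces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__, report
from .config import PipelineConfig
from .interactome import convergence_nodes, export_network, load_ppi, patient_network
from .insertion import SeqSearcher, two_way_annotate
from .io import (
    read_expression,
    read_fasta,
    read_gene_models,
    read_population_db,
    read_regulatory,
    read_roi,
    read_sv_vcf,
)
from .model import PopSource, SVType
from .prioritize import ResourceBundle, run_prioritization

log = logging.getLogger(__name__)

_SPEC_FIELDS = (
    "vcfs", "roi", "dgv", "gnomad", "regulatory", "genes", "expression",
    "reference", "ppi_hippie", "ppi_string",
)


@dataclass
class RunSpec:
    """Paths to every pipeline input."""

    vcfs: list[Path]
    roi: Path
    dgv: Path
    gnomad: Path
    regulatory: Path
    genes: Path
    expression: Path
    reference: Path
    ppi_hippie: Path
    ppi_string: Path

    def validate(self) -> None:
        for name in _SPEC_FIELDS:
            value = getattr(self, name)
            paths = value if isinstance(value, list) else [value]
            if name == "vcfs" and not paths:
                raise FileNotFoundError("run spec field 'vcfs' lists no files")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"run spec field '{name}': missing {p}")

    @classmethod
    def from_world(cls, world_dir: str | Path) -> "RunSpec":
        """Map a synthetic-world directory onto a run spec."""
        d = Path(world_dir)
        return cls(
            vcfs=sorted((d / "patients").glob("*.vcf")),
            roi=d / "roi.tsv",
            dgv=d / "dgv.tsv",
            gnomad=d / "gnomad.tsv",
            regulatory=d / "regulatory.tsv",
            genes=d / "genes.gff3",
            expression=d / "expression.tsv",
            reference=d / "reference.fa",
            ppi_hippie=d / "ppi_hippie.tsv",
            ppi_string=d / "ppi_string.tsv",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(_SPEC_FIELDS)
        if unknown:
            raise ValueError(f"run spec {path}: unknown keys {sorted(unknown)}")
        missing = set(_SPEC_FIELDS) - set(data)
        if missing:
            raise ValueError(f"run spec {path}: missing keys {sorted(missing)}")
        base = Path(path).parent
        def resolve(v):  # paths relative to the spec file
            return base / v if not Path(v).is_absolute() else Path(v)
        return cls(
            vcfs=[resolve(v) for v in data["vcfs"]],
            **{k: resolve(data[k]) for k in _SPEC_FIELDS if k != "vcfs"},
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    spec: RunSpec,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> Path:
    """Execute prioritize -> insertion -> interactome -> report.

    Writes candidates.tsv, funnel.tsv, provenance.jsonl, insertions.tsv,
    per-patient network exports with convergence tables, report.md, and a
    run_manifest.json recording the config hash and input checksums.
    """
    config = config or PipelineConfig()
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    callsets = [read_sv_vcf(p) for p in spec.vcfs]
    resources = ResourceBundle(
        roi=read_roi(spec.roi),
        dgv=read_population_db(spec.dgv, PopSource.DGV_GOLD),
        gnomad=read_population_db(spec.gnomad, PopSource.GNOMAD_CNV),
        transcripts=read_gene_models(spec.genes),
        regulatory=read_regulatory(spec.regulatory),
        expression=read_expression(spec.expression),
    )
    table, funnel = run_prioritization(callsets, resources, config)
    log.info("prioritization: %d candidates, funnel %s (%.1fs)",
             len(table), funnel.as_dict(), time.monotonic() - t0)
    report.write_candidates(table, out / "candidates.tsv", config)
    report.write_funnel(funnel, out / "funnel.tsv", config)
    report.write_provenance(callsets, out / "provenance.jsonl")

    # insertion origins for candidate insertions
    t1 = time.monotonic()
    searcher = SeqSearcher(read_fasta(spec.reference))
    ins_reports = []
    for row in table.rows:
        if row.sv.svtype is SVType.INS:
            ins_reports.append(
                (row.patient_id, two_way_annotate(row.sv, resources, searcher, config))
            )
    report.write_insertion_reports(ins_reports, out / "insertions.tsv", config)
    log.info("insertion origin mapping: %d insertions (%.1fs)",
             len(ins_reports), time.monotonic() - t1)

    # patient-specific interactomes, one per PPI source
    t2 = time.monotonic()
    networks = {
        "HIPPIE_LIKE": load_ppi(spec.ppi_hippie, config.hippie_min_conf, "HIPPIE_LIKE"),
        "STRING_LIKE": load_ppi(spec.ppi_string, config.string_min_conf, "STRING_LIKE"),
    }
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    convergence_by_patient: dict[str, dict[str, list]] = {}
    for cs in sorted(callsets, key=lambda c: c.patient_id):
        genes_by_sv = {
            row.sv.sv_id: row.annotation.genes
            for row in table.rows
            if row.patient_id == cs.patient_id and row.annotation.genes
        }
        convergence_by_patient[cs.patient_id] = {}
        for source, g in networks.items():
            conv_path = net_dir / f"{cs.patient_id}_{source}_convergence.tsv"
            if not genes_by_sv:
                report.write_convergence([], conv_path)
                convergence_by_patient[cs.patient_id][source] = []
                continue
            pi = patient_network(g, genes_by_sv)
            conv = convergence_nodes(pi)
            convergence_by_patient[cs.patient_id][source] = conv
            export_network(pi, conv, net_dir, prefix=f"{cs.patient_id}_{source}")
            report.write_convergence(conv, conv_path)
    log.info("interactome analysis (%.1fs)", time.monotonic() - t2)

    report.render_report(
        table, funnel, ins_reports, convergence_by_patient, out / "report.md"
    )

    inputs = {}
    for name in _SPEC_FIELDS:
        value = getattr(spec, name)
        for p in value if isinstance(value, list) else [value]:
            inputs[Path(p).name] = _sha256(Path(p))
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "inputs": inputs,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    log.info("run complete in %.1fs -> %s", time.monotonic() - t0, out)
    return out
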