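"""Readers and writers for every file format the pipeline touches.

VCF parsing goes through pysam; GFF3 through gffutils; tabular inputs
(population SV databases, ROI list, regulatory track, expression flags, PPI
edge lists) through pandas; FASTA through pyfaidx. All writers emit UTF-8
tab-separated text with a commented header naming the producing tool version
and config hash, so a run can be traced back to its exact parameters.

Tabular schemas (header-named columns, tab-separated):

* population DB: record_id, chrom, start, end, type, frequency (percent),
  and for DGV-style files inner_rank and n_samples;
* ROI list: ensembl_id, gene_symbol, chrom, start, end;
* regulatory track: element_id, chrom, start, end, category, elite,
  target_genes (comma-separated symbols);
* expression flags: gene, cns_expressed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from . import __version__
from .config import PipelineConfig
from .model import (
    POP_TYPE_ALIASES,
    ExpressionFlag,
    GenomicInterval,
    PatientCallset,
    PopSource,
    PopulationSVRecord,
    ROISet,
    RegulatoryElement,
    StructuralVariant,
    SVType,
    TranscriptModel,
)

log = logging.getLogger(__name__)


def header_comment(config: Optional[PipelineConfig] = None) -> str:
    tag = f"# svprio {__version__}"
    if config is not None:
        tag += f" config={config.hash()}"
    return tag


# ---------------------------------------------------------------------------
# VCF

def read_sv_vcf(path: str | Path, patient_id: Optional[str] = None) -> PatientCallset:
    """Read an SV VCF (SVTYPE/END/SVLEN dialect) into a patient callset.

    Records whose FILTER is neither PASS nor '.' are skipped (the count is
    logged); records without SVTYPE are collected as record-level errors and
    reported together rather than aborting the whole file.
    """
    path = Path(path)
    if patient_id is None:
        patient_id = path.stem.split(".")[0]
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    variants: list[StructuralVariant] = []
    errors: list[str] = []
    n_nonpass = 0
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_nonpass += 1
                continue
            if "SVTYPE" not in rec.info:
                errors.append(f"{rec.chrom}:{rec.pos}: missing SVTYPE")
                continue
            svtype = SVType(str(rec.info["SVTYPE"]))
            sv_id = rec.id or f"{patient_id}_{rec.chrom}_{rec.pos}"
            if svtype is SVType.INS:
                alt = rec.alts[0] if rec.alts else ""
                if alt.startswith("<"):
                    seq = str(rec.info.get("SEQ", ""))
                else:
                    seq = alt[len(rec.ref):]
                if not seq:
                    errors.append(f"{sv_id}: INS without inserted sequence")
                    continue
                interval = GenomicInterval(rec.chrom, rec.pos, rec.pos)
                svlen = len(seq)
                variants.append(
                    StructuralVariant(sv_id, patient_id, svtype, interval, svlen, seq)
                )
            else:
                end = rec.stop
                if end <= rec.pos and "SVLEN" in rec.info:
                    svlen_info = rec.info["SVLEN"]
                    if isinstance(svlen_info, tuple):
                        svlen_info = svlen_info[0]
                    end = rec.pos + abs(int(svlen_info))
                interval = GenomicInterval(rec.chrom, rec.pos, end)
                variants.append(
                    StructuralVariant(
                        sv_id, patient_id, svtype, interval, interval.length()
                    )
                )
    if n_nonpass:
        log.info("%s: skipped %d non-PASS records", path.name, n_nonpass)
    if errors:
        log.warning("%s: %d records with errors: %s", path.name, len(errors), errors)
    return PatientCallset(patient_id, variants)


def write_sv_vcf(callset: PatientCallset, path: str | Path) -> None:
    """Emit a minimal SV VCF that :func:`read_sv_vcf` round-trips exactly."""
    chroms = sorted({v.interval.chrom for v in callset.variants})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=svprio {__version__}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(callset.variants, key=lambda v: (v.interval.chrom, v.interval.start, v.sv_id)):
        if v.svtype is SVType.INS:
            ref, alt = "N", "N" + v.inserted_seq
            info = f"SVTYPE=INS;END={v.interval.start};SVLEN={v.svlen}"
        else:
            ref, alt = "N", f"<{v.svtype.value}>"
            svlen = -v.svlen if v.svtype is SVType.DEL else v.svlen
            info = f"SVTYPE={v.svtype.value};END={v.interval.end};SVLEN={svlen}"
        lines.append(
            f"{v.interval.chrom}\t{v.interval.start}\t{v.sv_id}\t{ref}\t{alt}"
            f"\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# population SV databases

def read_population_db(path: str | Path, source: PopSource) -> list[PopulationSVRecord]:
    """Read a DGV-gold-style or gnomAD-CNV-style TSV.

    File frequencies are percentages (a value of ``8.82`` means 8.82%) and
    are normalized to fractions; the result is sorted by (chrom, start).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"record_id", "chrom", "start", "end", "type", "frequency"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if source is PopSource.DGV_GOLD and "inner_rank" not in df.columns:
        raise ValueError(f"{path}: DGV source requires inner_rank column")
    records = []
    for row in df.itertuples(index=False):
        freq_pct = float(row.frequency)
        if not 0.0 <= freq_pct <= 100.0:
            raise ValueError(f"{path}: frequency {freq_pct} outside [0,100]")
        raw_type = str(row.type).upper()
        svtype = POP_TYPE_ALIASES.get(raw_type, None)
        if svtype is None:
            svtype = SVType(raw_type)
        records.append(
            PopulationSVRecord(
                source=source,
                record_id=str(row.record_id),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                svtype=svtype,
                frequency=freq_pct / 100.0,
                inner_rank=int(row.inner_rank) if source is PopSource.DGV_GOLD else None,
                n_samples=int(row.n_samples)
                if "n_samples" in df.columns and not pd.isna(row.n_samples)
                else None,
            )
        )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.record_id))
    return records


def write_population_db(
    records: Iterable[PopulationSVRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "type": r.svtype.value,
                "frequency": round(r.frequency * 100.0, 6),
                "inner_rank": r.inner_rank if r.inner_rank is not None else "",
                "n_samples": r.n_samples if r.n_samples is not None else "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "record_id", "chrom", "start", "end", "type",
            "frequency", "inner_rank", "n_samples",
        ],
    )
    with open(path, "w") as fh:
        fh.write(header_comment() + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ROI / regulatory / expression tables

def read_roi(path: str | Path) -> ROISet:
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise ValueError(f"{path}: line {i + 2}: end < start")
        entries.append(
            (str(row.ensembl_id), str(row.gene_symbol),
             GenomicInterval(str(row.chrom), start, end))
        )
    try:
        return ROISet(entries)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_roi(roi: ROISet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment() + "\n")
        fh.write("ensembl_id\tgene_symbol\tchrom\tstart\tend\n")
        for eid, sym, iv in roi.entries:
            fh.write(f"{eid}\t{sym}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_regulatory(path: str | Path) -> list[RegulatoryElement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    elements = []
    for i, row in enumerate(df.itertuples(index=False)):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise ValueError(f"{path}: line {i + 2}: end < start")
        targets = [t for t in str(row.target_genes).split(",") if t and t != "nan"]
        elements.append(
            RegulatoryElement(
                element_id=str(row.element_id),
                interval=GenomicInterval(str(row.chrom), start, end),
                category=str(row.category),
                elite=bool(int(row.elite)),
                target_genes=targets,
            )
        )
    return elements


def write_regulatory(elements: Iterable[RegulatoryElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment() + "\n")
        fh.write("element_id\tchrom\tstart\tend\tcategory\telite\ttarget_genes\n")
        for e in elements:
            fh.write(
                f"{e.element_id}\t{e.interval.chrom}\t{e.interval.start}\t"
                f"{e.interval.end}\t{e.category}\t{int(e.elite)}\t"
                f"{','.join(e.target_genes)}\n"
            )


def read_expression(path: str | Path) -> list[ExpressionFlag]:
    df = pd.read_csv(path, sep="\t", comment="#")
    flags = [
        ExpressionFlag(str(row.gene), bool(int(row.cns_expressed)))
        for row in df.itertuples(index=False)
    ]
    genes = [f.gene for f in flags]
    if len(genes) != len(set(genes)):
        raise ValueError(f"{path}: duplicate gene in expression table")
    return flags


def write_expression(flags: Iterable[ExpressionFlag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment() + "\n")
        fh.write("gene\tcns_expressed\n")
        for f in flags:
            fh.write(f"{f.gene}\t{int(f.cns_expressed)}\n")


# ---------------------------------------------------------------------------
# gene models (GFF3)

def read_gene_models(path: str | Path) -> list[TranscriptModel]:
    """Read transcripts with ordered exons from GFF3; exon 1 is 5'-most.

    Expects mRNA features with ``gene_name`` and optional ``tag=MANE_Select``
    attributes and child exon features. GFF coordinates (1-based inclusive)
    are converted so that interval length equals exon span in bp.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = [
            GenomicInterval(ex.seqid, ex.start - 1, ex.end)
            for ex in db.children(mrna, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        tags = mrna.attributes.get("tag", [])
        models.append(
            TranscriptModel(
                gene=mrna.attributes.get("gene_name", [mrna.id])[0],
                transcript_id=mrna.id,
                is_mane="MANE_Select" in tags,
                strand=mrna.strand,
                exons=exons,
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_gene_models(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Emit GFF3 (1-based inclusive coordinates) for gene/mRNA/exon features."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: m.transcript_id):
        span = m.span()
        gene_id = f"gene:{m.gene}"
        attrs = f"ID={m.transcript_id};Parent={gene_id};gene_name={m.gene}"
        if m.is_mane:
            attrs += ";tag=MANE_Select"
        lines.append(
            f"{span.chrom}\tsvprio\tgene\t{span.start + 1}\t{span.end}\t.\t"
            f"{m.strand}\t.\tID={gene_id};Name={m.gene}"
        )
        lines.append(
            f"{span.chrom}\tsvprio\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
            f"{m.strand}\t.\t{attrs}"
        )
        for i, ex in enumerate(sorted(m.exons, key=lambda e: e.start)):
            lines.append(
                f"{ex.chrom}\tsvprio\texon\t{ex.start + 1}\t{ex.end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id}.exon{i + 1};Parent={m.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
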