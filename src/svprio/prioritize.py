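"""The SV exclusion/inclusion cascade producing the candidate table.

Stages, in canonical order: restrict to the region-of-interest gene set;
drop SVs larger than 5 Mb (pre-excluded by conventional karyotyping/CMA);
drop SVs recurrent in four or more patients of the cohort; drop SVs matching
a common, reliably-delineated population record (DGV gold standard: frequency
and inner rank evaluated together; gnomAD CNV: frequency alone); finally keep
SVs with at least one inclusion signal — exonic overlap, regulatory-element
overlap, or an overlapped CNS-expressed gene — and drop purely intronic SVs
with no regulatory element.

Every exclusion rule is evaluated as a pure predicate against the full
ROI-restricted input, never against the survivors of earlier rules, so the
final candidate set is invariant under permutation of the rule order; the
order only decides which rule a doomed SV's provenance blames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import PipelineConfig
from .intervals import FeatureIndex, format_ranges, reciprocal_overlap
from .model import (
    AnnotationBundle,
    CandidateRow,
    CandidateTable,
    ExpressionFlag,
    FilterDecision,
    FilterFunnel,
    FilterOutcome,
    PatientCallset,
    PopulationSVRecord,
    RecurrenceCluster,
    RegulatoryElement,
    ROISet,
    StructuralVariant,
    SVType,
    TranscriptModel,
)

CANONICAL_RULE_ORDER = ("size", "recurrence", "population", "annotation")


@dataclass
class ResourceBundle:
    """All reference inputs the cascade consults."""

    roi: ROISet
    dgv: list[PopulationSVRecord]
    gnomad: list[PopulationSVRecord]
    transcripts: list[TranscriptModel]
    regulatory: list[RegulatoryElement]
    expression: list[ExpressionFlag]

    _roi_index: Optional[FeatureIndex] = field(default=None, repr=False)
    _tx_index: Optional[FeatureIndex] = field(default=None, repr=False)
    _reg_index: Optional[FeatureIndex] = field(default=None, repr=False)

    def roi_index(self) -> FeatureIndex:
        if self._roi_index is None:
            self._roi_index = FeatureIndex(
                [(iv, eid, sym) for eid, sym, iv in self.roi.entries]
            )
        return self._roi_index

    def transcript_index(self) -> FeatureIndex:
        if self._tx_index is None:
            self._tx_index = FeatureIndex(
                [(m.span(), m.transcript_id, m) for m in self.transcripts]
            )
        return self._tx_index

    def regulatory_index(self) -> FeatureIndex:
        if self._reg_index is None:
            self._reg_index = FeatureIndex(
                [(e.interval, e.element_id, e) for e in self.regulatory]
            )
        return self._reg_index

    def cns_flags(self) -> dict[str, bool]:
        return {f.gene: f.cns_expressed for f in self.expression}


# ---------------------------------------------------------------------------
# individual rules

def restrict_to_roi(callset: PatientCallset, roi: ROISet) -> PatientCallset:
    """Keep SVs intersecting at least one ROI gene; record which genes."""
    if not roi.entries:
        raise ValueError("ROI set is empty")
    index = FeatureIndex([(iv, eid, sym) for eid, sym, iv in roi.entries])
    kept = []
    for sv in callset.variants:
        hits = index.query(sv.interval)
        if hits:
            sv.roi_genes = sorted({sym for _, _, sym in hits})
            kept.append(sv)
        else:
            sv.record(
                FilterDecision(
                    "not_in_roi", FilterOutcome.EXCLUDE, "no ROI gene intersected"
                )
            )
    return PatientCallset(callset.patient_id, kept)


def size_rule(sv: StructuralVariant, config: PipelineConfig) -> FilterDecision:
    """SVs strictly larger than the cutoff are excluded (cutoff itself kept)."""
    if sv.svlen > config.max_sv_size:
        return FilterDecision(
            "size_gt_max", FilterOutcome.EXCLUDE,
            f"svlen {sv.svlen} > {config.max_sv_size}",
        )
    return FilterDecision("size_gt_max", FilterOutcome.PASS, f"svlen {sv.svlen}")


def _svs_match(
    a: StructuralVariant, b: StructuralVariant, config: PipelineConfig
) -> bool:
    if a.svtype is not b.svtype:
        return False
    if a.svtype is SVType.INS:
        if a.interval.chrom != b.interval.chrom:
            return False
        if abs(a.interval.start - b.interval.start) > config.ins_match_window:
            return False
        return abs(a.svlen - b.svlen) <= config.ins_match_len_tol * max(a.svlen, b.svlen)
    return reciprocal_overlap(a.interval, b.interval) >= config.recurrence_ro_min


def cluster_recurrent(
    callsets: Sequence[PatientCallset], config: PipelineConfig
) -> tuple[list[RecurrenceCluster], dict[str, RecurrenceCluster]]:
    """Single-linkage clustering of same-type SVs across patients.

    Returns all clusters plus a map sv_id -> cluster for the SVs that belong
    to a cluster seen in >= ``recurrence_patient_min`` distinct patients.
    """
    if not callsets:
        raise ValueError("no callsets")
    svs = [v for cs in callsets for v in cs.variants]
    svs.sort(key=lambda v: (v.patient_id, v.sv_id))
    parent = list(range(len(svs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(svs)):
        for j in range(i + 1, len(svs)):
            if _svs_match(svs[i], svs[j], config):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(svs)):
        groups.setdefault(find(i), []).append(i)

    clusters, recurrent_map = [], {}
    for root in sorted(groups):
        members_idx = groups[root]
        members = [(svs[i].patient_id, svs[i].sv_id) for i in members_idx]
        cluster = RecurrenceCluster(
            members=members,
            representative=svs[members_idx[0]].interval,
            svtype=svs[members_idx[0]].svtype,
        )
        clusters.append(cluster)
        patients = {p for p, _ in members}
        for i in members_idx:
            if len(patients) >= config.recurrence_patient_min:
                recurrent_map[svs[i].sv_id] = cluster
            else:
                svs[i].shared_with = sorted(patients - {svs[i].patient_id})
    return clusters, recurrent_map


def recurrence_rule(
    sv: StructuralVariant, recurrent_map: dict[str, RecurrenceCluster]
) -> FilterDecision:
    cluster = recurrent_map.get(sv.sv_id)
    if cluster is not None:
        return FilterDecision(
            "recurrent_ge_min_patients", FilterOutcome.EXCLUDE,
            f"shared by {cluster.n_patients()} patients",
        )
    detail = f"shared with {','.join(sv.shared_with)}" if sv.shared_with else "unique"
    return FilterDecision("recurrent_ge_min_patients", FilterOutcome.PASS, detail)


def population_filter(
    sv: StructuralVariant,
    dgv: Sequence[PopulationSVRecord],
    gnomad: Sequence[PopulationSVRecord],
    config: PipelineConfig,
) -> FilterDecision:
    """Match an SV against population records; exclude only on solid evidence.

    A DGV gold-standard match excludes only when it is both common
    (frequency >= ``dgv_freq_max``) and reliably delineated (inner rank <=
    ``dgv_rank_reliable_max``); high-rank records are treated as unreliable
    support and never exclude on their own. A gnomAD CNV match excludes on
    frequency alone. Every match, excluding or not, lands in the detail.
    """
    matches = []
    excluding = []
    for rec in list(dgv) + list(gnomad):
        if rec.svtype is not sv.svtype:
            continue
        ro = reciprocal_overlap(sv.interval, rec.interval)
        if ro < config.popdb_ro_min:
            continue
        matches.append(f"{rec.record_id}(f={rec.frequency:.4f},ro={ro:.2f})")
        if rec.inner_rank is not None:  # DGV gold standard
            if (
                rec.frequency >= config.dgv_freq_max
                and rec.inner_rank <= config.dgv_rank_reliable_max
            ):
                excluding.append(rec.record_id)
        elif rec.frequency >= config.gnomad_freq_max:
            excluding.append(rec.record_id)
    detail = "matches: " + (";".join(matches) if matches else "none")
    if excluding:
        return FilterDecision(
            "population_common", FilterOutcome.EXCLUDE,
            f"excluded by {','.join(excluding)}; {detail}",
        )
    return FilterDecision("population_common", FilterOutcome.PASS, detail)


def annotate_sv(
    sv: StructuralVariant,
    transcripts: Sequence[TranscriptModel] | FeatureIndex,
    regulatory: Sequence[RegulatoryElement] | FeatureIndex,
    expression: Sequence[ExpressionFlag] | dict[str, bool],
) -> AnnotationBundle:
    """Overlap an SV with gene models, regulatory elements, expression flags.

    Exonic hits report affected exons as maximal consecutive ranges on the
    strand-aware numbering (e.g. "58-61, 64-66"), MANE transcripts first.
    ``intronic_only`` is true when the SV lies inside at least one transcript
    body yet touches no exon of any transcript.
    """
    tx_index = (
        transcripts
        if isinstance(transcripts, FeatureIndex)
        else FeatureIndex([(m.span(), m.transcript_id, m) for m in transcripts])
    )
    reg_index = (
        regulatory
        if isinstance(regulatory, FeatureIndex)
        else FeatureIndex([(e.interval, e.element_id, e) for e in regulatory])
    )
    cns = (
        expression
        if isinstance(expression, dict)
        else {f.gene: f.cns_expressed for f in expression}
    )

    exonic: list[tuple[str, str, bool]] = []
    genes: set[str] = set()
    in_body = False
    for _, _, model in tx_index.query(sv.interval):
        in_body = True
        genes.add(model.gene)
        hit_exons = [
            num for num, ex in model.numbered_exons() if sv.interval.overlaps(ex)
        ]
        if hit_exons:
            exonic.append((model.transcript_id, format_ranges(hit_exons), model.is_mane))
    exonic.sort(key=lambda h: (not h[2], h[0]))

    regulatory_hits = [eid for _, eid, _ in reg_index.query(sv.interval)]
    cns_genes = sorted(g for g in genes if cns.get(g, False))
    return AnnotationBundle(
        exonic_hits=[(tid, ranges) for tid, ranges, _ in exonic],
        regulatory_hits=regulatory_hits,
        cns_genes=cns_genes,
        intronic_only=in_body and not exonic,
        genes=sorted(genes),
    )


def decide_candidate(sv: StructuralVariant) -> FilterDecision:
    """Candidate iff at least one inclusion signal is present."""
    ann = sv.annotations
    if ann is None:
        raise ValueError(f"{sv.sv_id}: annotate_sv must run first")
    if ann.has_inclusion_signal():
        signals = []
        if ann.exonic_hits:
            signals.append("exonic")
        if ann.regulatory_hits:
            signals.append("regulatory")
        if ann.cns_genes:
            signals.append("cns_expressed")
        return FilterDecision(
            "inclusion_signal", FilterOutcome.INCLUDE_SIGNAL, "+".join(signals)
        )
    return FilterDecision(
        "intronic_no_regulatory", FilterOutcome.EXCLUDE,
        "intronic, no regulatory element, no CNS gene"
        if ann.intronic_only
        else "no feature overlap",
    )


# ---------------------------------------------------------------------------
# the cascade

def filter_by_size(
    svs: Sequence[StructuralVariant], config: PipelineConfig
) -> list[StructuralVariant]:
    kept = []
    for sv in svs:
        decision = size_rule(sv, config)
        sv.record(decision)
        if decision.outcome is not FilterOutcome.EXCLUDE:
            kept.append(sv)
    return kept


def run_prioritization(
    callsets: Sequence[PatientCallset],
    resources: ResourceBundle,
    config: PipelineConfig,
    rule_order: Sequence[str] = CANONICAL_RULE_ORDER,
) -> tuple[CandidateTable, FilterFunnel]:
    """Run the full cascade; deterministic given inputs and config.

    ``rule_order`` permutes the exclusion rules; because each rule is a pure
    predicate over the full ROI-restricted input the candidate set does not
    depend on it (the funnel counts do, since they follow the given order).
    """
    if not callsets:
        raise ValueError("no callsets given")
    if sorted(rule_order) != sorted(CANONICAL_RULE_ORDER):
        raise ValueError(f"rule_order must permute {CANONICAL_RULE_ORDER}")

    restricted = [restrict_to_roi(cs, resources.roi) for cs in callsets]
    all_svs = [v for cs in restricted for v in cs.variants]
    all_svs.sort(key=lambda v: (v.patient_id, v.interval.chrom, v.interval.start, v.sv_id))

    _, recurrent_map = cluster_recurrent(restricted, config)
    tx_index = resources.transcript_index()
    reg_index = resources.regulatory_index()
    cns = resources.cns_flags()

    verdicts: dict[str, dict[str, FilterDecision]] = {}
    for sv in all_svs:
        sv.annotations = annotate_sv(sv, tx_index, reg_index, cns)
        verdicts[sv.sv_id] = {
            "size": size_rule(sv, config),
            "recurrence": recurrence_rule(sv, recurrent_map),
            "population": population_filter(sv, resources.dgv, resources.gnomad, config),
            "annotation": decide_candidate(sv),
        }

    funnel_counts = {"roi": len(all_svs)}
    surviving = list(all_svs)
    rows = []
    for sv in all_svs:
        excluded = False
        for rule in rule_order:
            decision = verdicts[sv.sv_id][rule]
            sv.record(decision)
            if decision.outcome is FilterOutcome.EXCLUDE:
                excluded = True
                break
        if not excluded:
            rows.append(
                CandidateRow(
                    patient_id=sv.patient_id,
                    sv=sv,
                    shared_with=sv.shared_with,
                    annotation=sv.annotations,
                    population_evidence=verdicts[sv.sv_id]["population"].detail,
                )
            )
    for rule in rule_order:
        surviving = [
            sv for sv in surviving
            if verdicts[sv.sv_id][rule].outcome is not FilterOutcome.EXCLUDE
        ]
        funnel_counts[rule] = len(surviving)

    # the funnel reports the canonical stage order regardless of rule_order
    canon = {"roi": len(all_svs)}
    pool = list(all_svs)
    for rule in CANONICAL_RULE_ORDER:
        pool = [
            sv for sv in pool
            if verdicts[sv.sv_id][rule].outcome is not FilterOutcome.EXCLUDE
        ]
        canon[rule] = len(pool)
    funnel = FilterFunnel(
        detected_in_roi=canon["roi"],
        after_size_filter=canon["size"],
        after_recurrence=canon["recurrence"],
        after_population=canon["population"],
        after_annotation=canon["annotation"],
    )
    return CandidateTable(rows), funnel
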