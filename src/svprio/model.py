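"""Domain types shared by every pipeline stage.

Coordinate convention: intervals are half-open ``[start, end)`` on the axis
the SV callers use, so that ``length() == end - start`` reproduces the sizes
a VCF record implies (``END - POS``). BED inputs (0-based half-open) are
shifted on read. Insertions are represented as point intervals at the
insertion site (``start == end == POS``); an insertion overlaps a feature
when the point lies inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"


class PopSource(str, Enum):
    DGV_GOLD = "DGV_GOLD"
    GNOMAD_CNV = "GNOMAD_CNV"


#: population CNV call aliases mapped onto SV types for matching
POP_TYPE_ALIASES = {"LOSS": SVType.DEL, "GAIN": SVType.DUP}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval; ``length = end - start``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"interval end < start: {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Shared >= 1 bp, or a point interval lying strictly inside the other."""
        if self.chrom != other.chrom:
            return False
        if self.start == self.end:
            return other.start <= self.start < other.end or (
                other.start == other.end == self.start
            )
        if other.start == other.end:
            return self.start <= other.start < self.end
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class FilterOutcome(str, Enum):
    PASS = "pass"
    EXCLUDE = "exclude"
    INCLUDE_SIGNAL = "include_signal"


@dataclass
class FilterDecision:
    """One rule's verdict on one SV; provenance for the exclusion cascade."""

    rule_name: str
    outcome: FilterOutcome
    detail: str = ""


@dataclass
class AnnotationBundle:
    """Feature overlaps that drive the inclusion decision.

    ``exonic_hits`` maps transcripts to the maximal consecutive exon-number
    ranges the SV touches (MANE transcripts first); ``intronic_only`` is true
    when the SV lies inside at least one transcript body but touches no exon.
    """

    exonic_hits: list[tuple[str, str]] = field(default_factory=list)
    regulatory_hits: list[str] = field(default_factory=list)
    cns_genes: list[str] = field(default_factory=list)
    intronic_only: bool = False
    genes: list[str] = field(default_factory=list)

    def has_inclusion_signal(self) -> bool:
        return bool(self.exonic_hits or self.regulatory_hits or self.cns_genes)


@dataclass
class StructuralVariant:
    sv_id: str
    patient_id: str
    svtype: SVType
    interval: GenomicInterval
    svlen: int
    inserted_seq: Optional[str] = None
    annotations: Optional[AnnotationBundle] = None
    provenance: list[FilterDecision] = field(default_factory=list)
    roi_genes: list[str] = field(default_factory=list)
    shared_with: list[str] = field(default_factory=list)
    review_flag: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.inserted_seq is not None) != (self.svtype is SVType.INS):
            raise ValueError(
                f"{self.sv_id}: inserted_seq present iff svtype is INS"
            )
        if self.svtype is not SVType.INS and self.svlen != self.interval.length():
            raise ValueError(
                f"{self.sv_id}: svlen {self.svlen} != interval length "
                f"{self.interval.length()}"
            )

    def record(self, decision: FilterDecision) -> None:
        self.provenance.append(decision)

    @property
    def excluded(self) -> bool:
        return any(d.outcome is FilterOutcome.EXCLUDE for d in self.provenance)


@dataclass
class PatientCallset:
    patient_id: str
    variants: list[StructuralVariant]

    def __post_init__(self) -> None:
        ids = [v.sv_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sv_ids in callset {self.patient_id}")
        for v in self.variants:
            if v.patient_id != self.patient_id:
                raise ValueError(
                    f"variant {v.sv_id} carries patient {v.patient_id}, "
                    f"callset is {self.patient_id}"
                )


@dataclass
class PopulationSVRecord:
    source: PopSource
    record_id: str
    interval: GenomicInterval
    svtype: SVType
    frequency: float
    inner_rank: Optional[int] = None
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"{self.record_id}: frequency {self.frequency} not in [0,1]")
        if (self.inner_rank is not None) != (self.source is PopSource.DGV_GOLD):
            raise ValueError(f"{self.record_id}: inner_rank present iff DGV_GOLD")


REGULATORY_CATEGORIES = frozenset({"enhancer", "promoter", "promoter_enhancer", "tss"})


@dataclass
class RegulatoryElement:
    element_id: str
    interval: GenomicInterval
    category: str
    elite: bool
    target_genes: list[str]

    def __post_init__(self) -> None:
        if self.category not in REGULATORY_CATEGORIES:
            raise ValueError(f"bad regulatory category {self.category!r}")


@dataclass
class TranscriptModel:
    """Gene model with strand-aware exon numbering (exon 1 is 5'-most)."""

    gene: str
    transcript_id: str
    is_mane: bool
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        by_start = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_start, by_start[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    def numbered_exons(self) -> list[tuple[int, GenomicInterval]]:
        """(exon_number, interval) pairs, numbered 5'->3'."""
        by_start = sorted(self.exons, key=lambda e: e.start)
        if self.strand == "-":
            by_start = by_start[::-1]
        return [(i + 1, e) for i, e in enumerate(by_start)]

    def span(self) -> GenomicInterval:
        chrom = self.exons[0].chrom
        return GenomicInterval(
            chrom, min(e.start for e in self.exons), max(e.end for e in self.exons)
        )


@dataclass
class ExpressionFlag:
    gene: str
    cns_expressed: bool


@dataclass
class ROISet:
    """Regions of interest: evolutionarily young genes the analysis is restricted to."""

    entries: list[tuple[str, str, GenomicInterval]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ensembl_id in ROI set")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class InsertionOriginHit:
    sv_id: str
    target: GenomicInterval
    strand: str
    identity: float
    aligned_length: int
    score: int
    is_self_site: bool = False
    origin_genes: list[str] = field(default_factory=list)
    origin_elements: list[str] = field(default_factory=list)


@dataclass
class TwoWayReport:
    """Insertion annotated at both ends: landing site and origin locus."""

    sv_id: str
    site_features: AnnotationBundle
    origin_hits: list[InsertionOriginHit]


@dataclass
class RecurrenceCluster:
    members: list[tuple[str, str]]  # (patient_id, sv_id)
    representative: GenomicInterval
    svtype: SVType

    def n_patients(self) -> int:
        return len({p for p, _ in self.members})


@dataclass
class FilterFunnel:
    """Per-stage survivor counts; a non-increasing sequence."""

    detected_in_roi: int
    after_size_filter: int
    after_recurrence: int
    after_population: int
    after_annotation: int

    def as_dict(self) -> dict[str, int]:
        return {
            "detected_in_roi": self.detected_in_roi,
            "after_size_filter": self.after_size_filter,
            "after_recurrence": self.after_recurrence,
            "after_population": self.after_population,
            "after_annotation": self.after_annotation,
        }


@dataclass
class CandidateRow:
    patient_id: str
    sv: StructuralVariant
    shared_with: list[str]
    annotation: AnnotationBundle
    population_evidence: str


@dataclass
class CandidateTable:
    rows: list[CandidateRow]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ConvergenceNode:
    """A gene adjacent to candidate genes from >= 2 distinct SVs in one patient."""

    gene: str
    linked_candidates: list[str]
    distinct_sv_count: int
    is_candidate_itself: bool
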