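"""The exclusion/inclusion cascade: each rule's semantics and the cascade's
order-invariance on the synthetic world."""

import itertools

import numpy as np
import pytest

from svprio.config import PipelineConfig
from svprio.intervals import reciprocal_overlap
from svprio.io import read_sv_vcf
from svprio.model import (
    ExpressionFlag,
    FilterOutcome,
    GenomicInterval,
    PatientCallset,
    PopSource,
    PopulationSVRecord,
    RegulatoryElement,
    ROISet,
    StructuralVariant,
    SVType,
    TranscriptModel,
)
from svprio.prioritize import (
    ResourceBundle,
    annotate_sv,
    cluster_recurrent,
    decide_candidate,
    population_filter,
    restrict_to_roi,
    run_prioritization,
    size_rule,
)

CFG = PipelineConfig()


def _del(sv_id, chrom, start, end, patient="P1"):
    return StructuralVariant(
        sv_id, patient, SVType.DEL, GenomicInterval(chrom, start, end), end - start
    )


# ---------------------------------------------------------------------------
# size rule

@pytest.mark.parametrize(
    "svlen,excluded",
    [
        (5_000_000, False),   # exactly the cutoff: "larger than" is strict
        (5_000_001, True),
        (77_924, False),      # a printed candidate duplication size
        (3_219_212, False),   # printed inversion chrX:52,433,310-55,652,522
    ],
)
def test_size_rule_boundary(svlen, excluded):
    sv = _del("s", "chr1", 0, svlen)
    assert (size_rule(sv, CFG).outcome is FilterOutcome.EXCLUDE) == excluded


def test_size_of_printed_inversion():
    assert GenomicInterval("chrX", 52_433_310, 55_652_522).length() == 3_219_212


# ---------------------------------------------------------------------------
# ROI restriction

def _roi():
    return ROISet([
        ("E1", "GENEA", GenomicInterval("chr1", 1000, 5000)),
        ("E2", "GENEB", GenomicInterval("chr1", 4500, 9000)),
    ])


def test_restrict_to_roi_keeps_and_drops():
    cs = PatientCallset("P1", [
        _del("inside", "chr1", 2000, 2500),
        _del("nochrom", "chr9", 2000, 2500),
        _del("spanning", "chr1", 4400, 4600),
    ])
    kept = restrict_to_roi(cs, _roi())
    assert [v.sv_id for v in kept.variants] == ["inside", "spanning"]
    by_id = {v.sv_id: v for v in kept.variants}
    assert by_id["inside"].roi_genes == ["GENEA"]
    # overlapping two ROI genes: kept once, both genes recorded
    assert by_id["spanning"].roi_genes == ["GENEA", "GENEB"]
    dropped = [v for v in cs.variants if v.sv_id == "nochrom"][0]
    assert dropped.provenance[0].rule_name == "not_in_roi"


# ---------------------------------------------------------------------------
# recurrence clustering

def test_identical_deletion_in_four_patients_excluded_three_kept():
    def make(n):
        return [
            PatientCallset(f"P{i+1}", [_del(f"P{i+1}_d", "chr1", 100, 600, f"P{i+1}")])
            for i in range(n)
        ]

    _, recurrent4 = cluster_recurrent(make(4), CFG)
    assert set(recurrent4) == {f"P{i+1}_d" for i in range(4)}

    callsets3 = make(3)
    _, recurrent3 = cluster_recurrent(callsets3, CFG)
    assert recurrent3 == {}
    assert callsets3[0].variants[0].shared_with == ["P2", "P3"]


def test_low_overlap_chain_gives_singletons_matching_bruteforce():
    # staggered DELs with pairwise RO ~0.33: four singleton clusters
    svs = [
        _del(f"P{i+1}_d", "chr1", 1000 + 400 * i, 1600 + 400 * i, f"P{i+1}")
        for i in range(4)
    ]
    callsets = [PatientCallset(f"P{i+1}", [svs[i]]) for i in range(4)]
    clusters, recurrent = cluster_recurrent(callsets, CFG)
    assert recurrent == {}
    assert sorted(len(c.members) for c in clusters) == [1, 1, 1, 1]
    # brute-force oracle: transitive closure over the pairwise match relation
    n = len(svs)
    adj = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = i == j or (
                svs[i].svtype is svs[j].svtype
                and reciprocal_overlap(svs[i].interval, svs[j].interval)
                >= CFG.recurrence_ro_min
            )
    closure = adj.copy()
    for k in range(n):
        closure |= closure[:, k][:, None] & closure[k, :][None, :]
    assert int(closure.sum()) == n  # only self-pairs: all singletons


def test_insertion_matching_uses_window_and_length_tolerance():
    def ins(sv_id, patient, pos, length):
        return StructuralVariant(
            sv_id, patient, SVType.INS, GenomicInterval("chr1", pos, pos),
            length, inserted_seq="A" * length,
        )

    close = [
        PatientCallset("P1", [ins("a", "P1", 1000, 400)]),
        PatientCallset("P2", [ins("b", "P2", 1080, 430)]),
    ]
    clusters, _ = cluster_recurrent(close, CFG)
    assert max(len(c.members) for c in clusters) == 2
    far = [
        PatientCallset("P1", [ins("a", "P1", 1000, 400)]),
        PatientCallset("P2", [ins("b", "P2", 1300, 400)]),   # outside 100 bp
        PatientCallset("P3", [ins("c", "P3", 1010, 150)]),   # length off by >20%
    ]
    clusters, _ = cluster_recurrent(far, CFG)
    assert sorted(len(c.members) for c in clusters) == [1, 1, 1]


# ---------------------------------------------------------------------------
# population filter

def _dgv(rid, iv, freq, rank):
    return PopulationSVRecord(
        PopSource.DGV_GOLD, rid, iv, SVType.DEL, freq, inner_rank=rank
    )


def test_common_but_high_rank_dgv_match_is_retained():
    # frequencies up to 8.82% with inner ranks 13/7 do not exclude: the rank
    # marks the record as unreliably delineated
    sv = _del("s", "chr16", 28_698_464, 28_709_344)
    dgv = [
        _dgv("d1", sv.interval, 0.0882, 13),
        _dgv("d2", sv.interval, 0.0002, 7),
    ]
    decision = population_filter(sv, dgv, [], CFG)
    assert decision.outcome is FilterOutcome.PASS
    assert "d1" in decision.detail  # match still recorded in provenance


def test_no_population_match_passes():
    sv = _del("s", "chr1", 100, 600)
    assert population_filter(sv, [], [], CFG).outcome is FilterOutcome.PASS


def test_common_low_rank_dgv_match_excludes():
    sv = _del("s", "chr1", 100, 600)
    decision = population_filter(sv, [_dgv("d1", sv.interval, 0.05, 3)], [], CFG)
    assert decision.outcome is FilterOutcome.EXCLUDE


def test_gnomad_match_excludes_on_frequency_alone():
    sv = StructuralVariant(
        "s", "P1", SVType.DUP, GenomicInterval("chr1", 100, 600), 500
    )
    rec = PopulationSVRecord(
        PopSource.GNOMAD_CNV, "g1", sv.interval, SVType.DUP, 0.03
    )
    assert population_filter(sv, [], [rec], CFG).outcome is FilterOutcome.EXCLUDE
    # type-incompatible record (DEL vs DUP) never matches
    rec_del = PopulationSVRecord(
        PopSource.GNOMAD_CNV, "g2", sv.interval, SVType.DEL, 0.5
    )
    assert population_filter(sv, [], [rec_del], CFG).outcome is FilterOutcome.PASS


def test_low_reciprocal_overlap_match_ignored():
    sv = _del("s", "chr1", 0, 1000)
    rec = _dgv("d1", GenomicInterval("chr1", 900, 5000), 0.5, 1)
    assert population_filter(sv, [rec], [], CFG).outcome is FilterOutcome.PASS


# ---------------------------------------------------------------------------
# annotation + decision

def _six_exon_transcript():
    exons = [GenomicInterval("chr1", 1000 + 2000 * i, 1300 + 2000 * i) for i in range(6)]
    return TranscriptModel("GENEA", "TXA", True, "+", exons)


def test_deletion_covering_exons_2_to_4_reports_range():
    tx = _six_exon_transcript()
    sv = _del("s", "chr1", 2900, 7400)  # spans exons 2,3,4
    ann = annotate_sv(sv, [tx], [], [ExpressionFlag("GENEA", False)])
    assert ann.exonic_hits == [("TXA", "2-4")]
    assert not ann.intronic_only
    sv.annotations = ann
    assert decide_candidate(sv).outcome is FilterOutcome.INCLUDE_SIGNAL


def test_noncontiguous_exon_hits_reported_as_separate_ranges():
    tx = _six_exon_transcript()
    # exons 2-3 and 5-6 but not 4: two maximal runs
    from svprio.model import AnnotationBundle  # noqa: F401

    hit2_3 = GenomicInterval("chr1", 2900, 5400)
    hit5_6 = GenomicInterval("chr1", 8900, 11400)
    for sv_iv, expected in ((hit2_3, "2-3"), (hit5_6, "5-6")):
        sv = _del("s", "chr1", sv_iv.start, sv_iv.end)
        ann = annotate_sv(sv, [tx], [], [])
        assert ann.exonic_hits == [("TXA", expected)]


def test_intronic_sv_with_no_elements_is_excluded():
    tx = _six_exon_transcript()
    sv = _del("s", "chr1", 1400, 1900)  # intron 1
    ann = annotate_sv(sv, [tx], [], [])
    assert ann.intronic_only and not ann.has_inclusion_signal()
    sv.annotations = ann
    decision = decide_candidate(sv)
    assert decision.outcome is FilterOutcome.EXCLUDE
    assert decision.rule_name == "intronic_no_regulatory"


def test_intronic_sv_over_enhancer_is_candidate():
    tx = _six_exon_transcript()
    enh = RegulatoryElement(
        "GH1", GenomicInterval("chr1", 1500, 1700), "enhancer", True, ["GENEA"]
    )
    sv = _del("s", "chr1", 1400, 1900)
    ann = annotate_sv(sv, [tx], [enh], [])
    assert ann.intronic_only and ann.regulatory_hits == ["GH1"]
    sv.annotations = ann
    assert decide_candidate(sv).outcome is FilterOutcome.INCLUDE_SIGNAL


def test_intronic_sv_in_cns_gene_is_candidate():
    tx = _six_exon_transcript()
    sv = _del("s", "chr1", 1400, 1900)
    ann = annotate_sv(sv, [tx], [], [ExpressionFlag("GENEA", True)])
    assert ann.cns_genes == ["GENEA"]
    sv.annotations = ann
    assert decide_candidate(sv).outcome is FilterOutcome.INCLUDE_SIGNAL


def test_mane_transcripts_listed_first():
    tx_alt = TranscriptModel(
        "GENEA", "TX0alt", False, "+",
        [GenomicInterval("chr1", 1000, 1300), GenomicInterval("chr1", 3000, 3300)],
    )
    ann = annotate_sv(
        _del("s", "chr1", 1100, 3200), [tx_alt, _six_exon_transcript()], [], []
    )
    assert [t for t, _ in ann.exonic_hits] == ["TXA", "TX0alt"]


# ---------------------------------------------------------------------------
# whole cascade on the synthetic world

def _load_world(world_dir):
    from svprio.io import (
        read_expression, read_gene_models, read_population_db, read_regulatory,
        read_roi,
    )

    callsets = [read_sv_vcf(p) for p in sorted((world_dir / "patients").glob("*.vcf"))]
    resources = ResourceBundle(
        roi=read_roi(world_dir / "roi.tsv"),
        dgv=read_population_db(world_dir / "dgv.tsv", PopSource.DGV_GOLD),
        gnomad=read_population_db(world_dir / "gnomad.tsv", PopSource.GNOMAD_CNV),
        transcripts=read_gene_models(world_dir / "genes.gff3"),
        regulatory=read_regulatory(world_dir / "regulatory.tsv"),
        expression=read_expression(world_dir / "expression.tsv"),
    )
    return callsets, resources


def test_candidate_set_invariant_under_rule_permutation(world_dir, manifest):
    orders = [
        ("size", "recurrence", "population", "annotation"),
        ("annotation", "population", "recurrence", "size"),
        ("population", "size", "annotation", "recurrence"),
    ]
    seen = []
    for order in orders:
        callsets, resources = _load_world(world_dir)
        table, _ = run_prioritization(callsets, resources, CFG, rule_order=order)
        seen.append({r.sv.sv_id for r in table.rows})
    assert seen[0] == seen[1] == seen[2] == manifest.all_candidates()


def test_funnel_counts_non_increasing_and_conserved(world_dir):
    callsets, resources = _load_world(world_dir)
    table, funnel = run_prioritization(callsets, resources, CFG)
    counts = list(funnel.as_dict().values())
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == len(table)
    # exclusions + candidates account for every ROI-restricted SV
    n_roi = counts[0]
    excluded = n_roi - counts[-1]
    assert excluded + len(table) == n_roi


def test_each_decoy_class_blamed_only_by_its_own_rule(world_dir, manifest):
    """Moving the blamed rule last shows no other rule would exclude the decoy."""
    blames = {
        "size_gt_max": ("recurrence", "population", "annotation", "size"),
        "recurrent_ge_min_patients": ("size", "population", "annotation", "recurrence"),
        "population_common": ("size", "recurrence", "annotation", "population"),
        "intronic_no_regulatory": ("size", "recurrence", "population", "annotation"),
    }
    for rule_name, order in blames.items():
        callsets, resources = _load_world(world_dir)
        run_prioritization(callsets, resources, CFG, rule_order=order)
        decoys = [s for s, r in manifest.all_excluded().items() if r == rule_name]
        assert decoys
        all_svs = {v.sv_id: v for cs in callsets for v in cs.variants}
        for sv_id in decoys:
            prov = all_svs[sv_id].provenance
            assert prov[-1].rule_name == rule_name
            assert all(d.outcome is not FilterOutcome.EXCLUDE for d in prov[:-1])


def test_disabling_one_threshold_leaks_exactly_that_class(world_dir, manifest):
    leaks = {
        "size_gt_max": CFG.replace(max_sv_size=100_000_000),
        "recurrent_ge_min_patients": CFG.replace(recurrence_patient_min=40),
        "population_common": CFG.replace(dgv_freq_max=1.0, gnomad_freq_max=1.0),
    }
    for rule_name, cfg in leaks.items():
        callsets, resources = _load_world(world_dir)
        table, _ = run_prioritization(callsets, resources, cfg)
        observed = {r.sv.sv_id for r in table.rows}
        expected_leak = {s for s, r in manifest.all_excluded().items() if r == rule_name}
        assert observed == manifest.all_candidates() | expected_leak


def test_raising_dgv_freq_max_only_grows_candidates(world_dir):
    previous = None
    for freq_max in (0.0001, 0.01, 0.2, 1.0):
        callsets, resources = _load_world(world_dir)
        table, _ = run_prioritization(
            callsets, resources, CFG.replace(dgv_freq_max=freq_max)
        )
        current = {r.sv.sv_id for r in table.rows}
        if previous is not None:
            assert previous <= current
        previous = current


def test_empty_roi_and_zero_callsets_fatal(world_dir):
    callsets, resources = _load_world(world_dir)
    with pytest.raises(ValueError):
        run_prioritization([], resources, CFG)
    resources.roi = ROISet([])
    with pytest.raises(ValueError):
        run_prioritization(callsets, resources, CFG)
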