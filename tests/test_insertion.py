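"""Insertion-origin mapping: seed-and-extend hits vs a full local-alignment
oracle, identity calibration, strand symmetry."""

import numpy as np
import pytest
from Bio import Align

from svprio.config import PipelineConfig
from svprio.insertion import SeqSearcher, map_insertion_origin, revcomp
from svprio.model import GenomicInterval
from svprio.synth import _mutate

CFG = PipelineConfig()


def _random_ref(rng, lengths):
    return {
        f"chr{i+1}": "".join(rng.choice(list("ACGT"), n))
        for i, n in enumerate(lengths)
    }


def _aligner():
    # same scoring convention as the implementation: match +1, mismatch -1,
    # gap of length L costs 2 + L
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -3
    a.extend_gap_score = -1
    return a


def full_alignment_oracle(reference, query, min_identity, min_cover=0.8):
    """Exhaustive local-alignment hit search: align against each chromosome
    on both strands, mask each accepted or rejected best locus, repeat."""
    aligner = _aligner()
    hits = []
    for chrom, seq in reference.items():
        for q in (query, revcomp(query)):
            masked = seq
            for _ in range(10):
                alns = aligner.align(masked, q)
                if len(alns) == 0 or alns.score <= 0.3 * len(q):
                    break
                aln = alns[0]
                counts = aln.counts()
                identity = counts.identities / aln.length
                t_start = int(aln.coordinates[0][0])
                t_end = int(aln.coordinates[0][-1])
                q_cover = (int(aln.coordinates[1][-1]) - int(aln.coordinates[1][0]))
                if identity >= min_identity and q_cover >= min_cover * len(q):
                    hits.append(GenomicInterval(chrom, t_start, t_end))
                masked = masked[:t_start] + "N" * (t_end - t_start) + masked[t_end:]
    return hits


@pytest.fixture(scope="module")
def planted_world():
    rng = np.random.default_rng(11)
    ref = _random_ref(rng, [60_000, 40_000])
    donor = ref["chr2"][20_000:20_440]
    return ref, donor, GenomicInterval("chr2", 20_000, 20_440)


def test_exact_copy_found_at_identity_one(planted_world):
    ref, donor, locus = planted_world
    hits = map_insertion_origin(donor, ref, CFG)
    assert len(hits) == 1
    assert hits[0].identity == 1.0
    assert hits[0].target.overlaps(locus)
    assert hits[0].aligned_length == 440
    assert hits[0].strand == "+"


def test_ten_percent_divergence_rejected_two_percent_recovered(planted_world):
    ref, donor, locus = planted_world
    rng = np.random.default_rng(5)
    assert map_insertion_origin(_mutate(donor, 0.10, rng), ref, CFG) == []
    hits = map_insertion_origin(_mutate(donor, 0.02, rng), ref, CFG)
    assert len(hits) == 1
    assert hits[0].identity >= 0.95
    assert hits[0].target.overlaps(locus)


def test_random_sequence_has_no_origin(planted_world):
    ref, _, _ = planted_world
    rng = np.random.default_rng(7)
    random_query = "".join(rng.choice(list("ACGT"), 300))
    assert map_insertion_origin(random_query, ref, CFG) == []


def test_query_shorter_than_seed_errors(planted_world):
    ref, _, _ = planted_world
    with pytest.raises(ValueError, match="seed"):
        map_insertion_origin("ACGTACGT", ref, CFG)


def test_reverse_complement_found_with_identical_identity(planted_world):
    ref, donor, locus = planted_world
    rng = np.random.default_rng(9)
    q = _mutate(donor, 0.02, rng)
    fwd = map_insertion_origin(q, ref, CFG)
    rev = map_insertion_origin(revcomp(q), ref, CFG)
    assert len(fwd) == len(rev) == 1
    assert fwd[0].identity == rev[0].identity
    assert fwd[0].strand == "+" and rev[0].strand == "-"
    assert rev[0].target.overlaps(locus)  # coordinates on the forward strand


def test_two_diverged_copies_both_reported_score_ranked():
    rng = np.random.default_rng(13)
    base = {"chr1": "".join(rng.choice(list("ACGT"), 50_000))}
    donor = base["chr1"][10_000:10_400]
    second = _mutate(donor, 0.02, rng)
    seq = base["chr1"][:30_000] + second + base["chr1"][30_400:]
    ref = {"chr1": seq}
    hits = map_insertion_origin(donor, ref, CFG)
    assert len(hits) == 2
    assert hits[0].score >= hits[1].score
    assert hits[0].target.overlaps(GenomicInterval("chr1", 10_000, 10_400))
    assert hits[1].target.overlaps(GenomicInterval("chr1", 30_000, 30_400))
    assert hits[1].identity == pytest.approx(0.98, abs=0.02)


def test_identity_estimate_tracks_substitution_rate():
    """Over 50 simulated queries the identity estimate sits within +/-0.02
    of 1 - substitution rate."""
    rng = np.random.default_rng(21)
    ref = _random_ref(rng, [80_000])
    searcher = SeqSearcher(ref)
    rates = [0.0, 0.02, 0.04, 0.06]
    for trial in range(50):
        s = rates[trial % len(rates)]
        start = int(rng.integers(0, 79_000))
        segment = ref["chr1"][start:start + 400]
        query = _mutate(segment, s, rng)
        hits = searcher.search(query, min_identity=0.85)
        assert hits, f"trial {trial}: no hit at rate {s}"
        best = hits[0]
        assert abs(best.identity - (1.0 - s)) <= 0.02


def test_seed_and_extend_equals_full_alignment_oracle():
    """Hit sets agree with the exhaustive quadratic oracle on small refs."""
    rng = np.random.default_rng(31)
    ref = _random_ref(rng, [50_000, 30_000])
    # plant: an exact copy, a 2% copy, a reverse-complement copy, a 10% copy
    donor = ref["chr1"][5_000:5_400]
    chr2 = list(ref["chr2"])
    chr2[8_000:8_400] = list(_mutate(donor, 0.02, rng))
    chr2[20_000:20_400] = list(revcomp(_mutate(donor, 0.01, rng)))
    chr2[25_000:25_400] = list(_mutate(donor, 0.10, rng))
    ref["chr2"] = "".join(chr2)

    impl = map_insertion_origin(donor, ref, CFG)
    oracle = full_alignment_oracle(ref, donor, CFG.blat_min_identity)
    impl_keys = sorted((h.target.chrom, round(h.target.start, -1)) for h in impl)
    oracle_keys = sorted((h.chrom, round(h.start, -1)) for h in oracle)
    assert impl_keys == oracle_keys
    assert len(impl) == 3  # the 10% copy is below the identity cutoff


def test_self_site_hit_labelled():
    rng = np.random.default_rng(41)
    ref = _random_ref(rng, [30_000])
    insert_point = 12_000
    seq = ref["chr1"][insert_point:insert_point + 350]
    site = GenomicInterval("chr1", insert_point, insert_point)
    hits = map_insertion_origin(seq, ref, CFG, site=site)
    assert len(hits) == 1 and hits[0].is_self_site
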