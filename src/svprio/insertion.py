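"""Insertion-origin mapping: a BLAT-like seed-and-extend search.

An inserted segment can be a "two-way hit": it disrupts features at its
landing site and simultaneously imports coding or regulatory sequence from
its origin locus. This module locates that origin by exact k-mer seeding on
both strands, chaining seeds by diagonal, and extending each chain with an
affine-gap local alignment (Gotoh) over a window around the chained
diagonal. A locus is reported when identity (matches / alignment columns,
gaps counting against identity) reaches the 95% cutoff and at least 80% of
the query aligns.

Scoring: match +1, mismatch -1, gap open -2, gap extend -1 (a gap of length
L costs 2 + L). Scores are therefore in match-count units. Defaults: seed
size k = 11, two-hit chaining, window margin 32 bp around the chained
diagonal. Hit coordinates are always reported on the forward strand.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numba import njit

from .config import PipelineConfig
from .model import GenomicInterval, InsertionOriginHit, StructuralVariant, SVType, TwoWayReport

SEED_K = 11
BAND = 32
MIN_ALIGNED_FRACTION = 0.8
MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -1, -2, -1

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=False)
def _gotoh_local(q, w, match, mismatch, gap_first, gap_ext):  # pragma: no cover
    """Affine-gap local alignment with traceback.

    Returns (score, matches, columns, q_start, q_end, w_start, w_end);
    q_end/w_end are exclusive. ``gap_first`` is the cost of the first gap
    residue (open + extend), ``gap_ext`` of each further one.
    """
    n, m = len(q), len(w)
    NEG = -10_000_000
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), np.uint8)  # 1 opened from H
    ptr_f = np.zeros((n + 1, m + 1), np.uint8)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_first
            e_ext = E[i, j - 1] - gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_first
            f_ext = F[i - 1, j] - gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
            s = match if q[i - 1] == w[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h, p = diag, 1
            if E[i, j] > h:
                h, p = E[i, j], 2
            if F[i, j] > h:
                h, p = F[i, j], 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    matches = 0
    columns = 0
    i, j = bi, bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if q[i - 1] == w[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            opened = ptr_e[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            columns += 1
            opened = ptr_f[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, matches, columns, i, bi, j, bj


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


class SeqSearcher:
    """k-mer index over a reference; reusable across queries."""

    def __init__(self, reference: dict[str, str], k: int = SEED_K) -> None:
        self.k = k
        self.reference = {name: seq.upper() for name, seq in reference.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.reference.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((name, pos))

    def _seed_chains(self, query: str) -> list[tuple[str, int, int]]:
        """Chain seeds by diagonal; returns (chrom, diag_lo, diag_hi) per chain."""
        k, qlen = self.k, len(query)
        hits: list[tuple[str, int, int]] = []  # (chrom, diag, ref_pos)
        for i in range(qlen - k + 1):
            for chrom, pos in self.index.get(query[i:i + k], ()):
                hits.append((chrom, pos - i, pos))
        hits.sort()
        min_seeds = 2 if qlen >= 2 * k else 1
        chains: list[tuple[str, int, int]] = []
        cur: list[tuple[str, int, int]] = []
        for h in hits:
            if cur and (
                h[0] != cur[-1][0]
                or h[1] - cur[-1][1] > BAND
                or h[2] - cur[-1][2] > qlen + BAND
            ):
                if len(cur) >= min_seeds:
                    chains.append((cur[0][0], cur[0][1], cur[-1][1]))
                cur = []
            cur.append(h)
        if len(cur) >= min_seeds:
            chains.append((cur[0][0], cur[0][1], cur[-1][1]))
        return chains

    def search(
        self, query: str, min_identity: float,
        min_aligned_fraction: float = MIN_ALIGNED_FRACTION,
    ) -> list[InsertionOriginHit]:
        """All loci where the query realigns at >= min_identity, both strands."""
        if len(query) < self.k:
            raise ValueError(
                f"query length {len(query)} below seed size {self.k}: unusable"
            )
        qlen = len(query)
        raw: list[InsertionOriginHit] = []
        for strand, q in (("+", query.upper()), ("-", revcomp(query).upper())):
            qarr = _encode(q)
            for chrom, dlo, dhi in self._seed_chains(q):
                ref = self.reference[chrom]
                w_start = max(0, dlo - BAND)
                w_end = min(len(ref), dhi + qlen + BAND)
                warr = _encode(ref[w_start:w_end])
                score, matches, columns, qs, qe, ws, we = _gotoh_local(
                    qarr, warr, MATCH, MISMATCH, -(GAP_OPEN + GAP_EXT), -GAP_EXT
                )
                if columns == 0:
                    continue
                identity = matches / columns
                aligned = qe - qs
                if identity < min_identity or aligned < min_aligned_fraction * qlen:
                    continue
                raw.append(
                    InsertionOriginHit(
                        sv_id="",
                        target=GenomicInterval(chrom, w_start + ws, w_start + we),
                        strand=strand,
                        identity=identity,
                        aligned_length=aligned,
                        score=int(score),
                    )
                )
        return _dedupe_hits(raw)


def _dedupe_hits(hits: list[InsertionOriginHit]) -> list[InsertionOriginHit]:
    """Merge hits with overlapping targets, keeping the best score."""
    kept: list[InsertionOriginHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.target.chrom, h.target.start)):
        if any(h.target.overlaps(k.target) for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (-h.score, h.target.chrom, h.target.start))
    return kept


def map_insertion_origin(
    inserted_seq: str,
    reference: dict[str, str] | SeqSearcher,
    config: PipelineConfig,
    site: Optional[GenomicInterval] = None,
) -> list[InsertionOriginHit]:
    """Locate the origin of an inserted segment in the reference.

    Returns hits with identity >= ``config.blat_min_identity`` covering at
    least 80% of the query, ranked by score then target coordinate. A hit at
    the insertion site itself (when the flanking copy exists) is retained
    and labelled ``is_self_site``.
    """
    searcher = (
        reference if isinstance(reference, SeqSearcher) else SeqSearcher(reference)
    )
    hits = searcher.search(inserted_seq, config.blat_min_identity)
    if site is not None:
        margin = len(inserted_seq)
        for h in hits:
            if (
                h.target.chrom == site.chrom
                and h.target.start - margin <= site.start <= h.target.end + margin
            ):
                h.is_self_site = True
    return hits


def two_way_annotate(
    sv: StructuralVariant,
    resources,
    reference: dict[str, str] | SeqSearcher,
    config: PipelineConfig,
) -> TwoWayReport:
    """Two-step insertion analysis: annotate the landing site, then the origin.

    Step one treats the insertion point like any other SV (exon, regulatory,
    CNS annotation); step two maps the inserted sequence back to the
    reference and annotates each origin locus with the genes and regulatory
    elements it overlaps (whose target genes identify the imported
    regulatory potential). No origin hit is a valid, empty result.
    """
    from .prioritize import annotate_sv

    if sv.svtype is not SVType.INS or sv.inserted_seq is None:
        raise ValueError(f"{sv.sv_id}: two_way_annotate requires an INS with sequence")
    site_features = annotate_sv(
        sv, resources.transcript_index(), resources.regulatory_index(),
        resources.cns_flags(),
    )
    hits = map_insertion_origin(sv.inserted_seq, reference, config, site=sv.interval)
    tx_index = resources.transcript_index()
    reg_index = resources.regulatory_index()
    for h in hits:
        h.sv_id = sv.sv_id
        h.origin_genes = sorted({m.gene for _, _, m in tx_index.query(h.target)})
        h.origin_elements = [eid for _, eid, _ in reg_index.query(h.target)]
    return TwoWayReport(sv_id=sv.sv_id, site_features=site_features, origin_hits=hits)
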