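# Methods

## The cascade as a set of pure predicates

Every exclusion rule — size, cohort recurrence, population match,
annotation — is evaluated as a pure predicate over the full ROI-restricted
input, never over the survivors of earlier rules. Recurrence clustering in
particular runs on all same-type calls, so removing a cluster member by the
size filter cannot demote a cluster below the patient threshold. The
candidate set is therefore invariant under permutation of the rule order;
the order only decides which rule a doomed SV's provenance blames, and the
funnel counts always report the canonical order (size → recurrence →
population → annotation). This property is asserted by running three
shuffled orders in the test suite.

## Coordinates

Intervals are half-open `[start, end)` with `length = end − start`, chosen
so a VCF SV record reproduces its printed size as `END − POS` (verified
against three published coordinate/size pairs: 196 bp, 80 bp, 77,924 bp).
BED input is 0-based half-open and shifted on read; GFF3 is 1-based
inclusive and converted. Insertions are point intervals at the insertion
site (`start = end = POS`); a point overlaps a feature when it lies inside
it, and reciprocal overlap with a zero-length interval is defined as 0 —
which is why insertions are matched across patients by position window
(±100 bp) and length tolerance (20%) instead.

## Thresholds and their defaults

| parameter | default | why |
|---|---|---|
| `max_sv_size` | 5,000,000 bp | screen-negative patients exclude gross SVs; "larger than" is strict, 5 Mb exactly is kept |
| `recurrence_patient_min` | 4 | calls shared by ≥ 4 patients are treated as artifacts/common variation |
| `recurrence_ro_min`, `popdb_ro_min` | 0.5 | the community-standard reciprocal-overlap identity for SVs; the sources this pipeline emulates do not state a matching criterion, so the default is exposed in config |
| `dgv_freq_max` | 0.01 | a DGV match is "common" at ≥ 1% |
| `dgv_rank_reliable_max` | 6 | only reliably-delineated (low inner rank) DGV records may exclude; high-rank records are kept as context because observed practice retains SVs whose only support is common but high-rank (ranks 7–13) |
| `gnomad_freq_max` | 0.01 | gnomAD CNV matches exclude on frequency alone |
| `blat_min_identity` | 0.95 | insertion origins are reported at ≥ 95% identity |
| `hippie_min_conf` / `string_min_conf` | 0.63 / 0.700 | medium-/high-confidence PPI cutoffs; inclusive (an edge at exactly the threshold survives, since the filter removes edges *below* it) |

The inclusion criteria (exonic, regulatory, CNS-expressed) are combined
with OR, not AND: regulatory-only candidates exist in practice, so the
conjunction reading would be too strict. Manual genome-browser review of
borderline calls is replaced by the deterministic annotation decision; a
per-SV `review_flag` field exists for manual overrides.

## Insertion-origin search

Seed-and-extend: exact 11-mer seeds on both strands, grouped by diagonal
(two seeds required when the query holds at least two non-overlapping
k-mers), each chain extended by an affine-gap local alignment (Gotoh, numba
JIT) over a window spanning the chained diagonals ± 32 bp. Scoring: match
+1, mismatch −1, gap of length L costs 2 + L, so scores are in match-count
units. Identity is matches / alignment columns — gaps count against
identity; this is simpler than BLAT's exact formula and is documented
rather than configurable. Hits need identity ≥ the 95% cutoff **and**
aligned query coverage ≥ 0.8 (a guard against spurious short matches, a
choice of this implementation). Overlapping hits from different chains or
strands are merged keeping the best score; coordinates are always reported
on the forward strand; a hit at the insertion site itself is retained but
labelled. The test suite checks the hit set against an exhaustive
quadratic local-alignment oracle (biopython `PairwiseAligner` with the same
scoring, iteratively masking found loci) and calibrates the identity
estimate to within ±0.02 of 1 − substitution rate over 50 simulated
queries.

## Convergence definition

A convergence node is any subnetwork node adjacent to candidate genes
originating from ≥ 2 distinct SVs of one patient. A candidate gene's own
SV origins are counted once it has at least one adjacent candidate, so a
direct cross-SV candidate–candidate edge surfaces both endpoints as
zero-intermediary convergences; an isolated candidate never converges.
Neighbor–neighbor edges are kept (full induced subgraph over candidates ∪
first neighbors), matching how such networks are drawn; `star_only=True`
restricts to candidate-incident edges. Ranking is distinct-SV count, then
number of linked candidates, then lexicographic — fully deterministic.
Duplicate PPI edges keep the maximum confidence before thresholding;
HIPPIE-style and STRING-style inputs always yield two independent networks
and results are reported per network, never merged.

## The synthetic world

Defaults: 3 chromosomes × 500 kb of i.i.d. uniform sequence, 20 ROI genes
+ 20 non-ROI decoy genes (4–8 exons of 300 bp, 2 kb introns, random
strand), 6 patients, plus a virtual 12 Mb chromosome that carries the
oversize decoy by coordinate fiat (no sequence is emitted for it — only
insertion donors need sequence). Planted per patient: an exonic deletion
and duplication (each patient hits a different exon of the shared host
genes, pairwise reciprocal overlap 0), a regulatory-only intronic deletion
over a patient-private enhancer, an intronic deletion in a CNS-expressed
gene, and one insertion copied from a distal donor locus at divergence 0,
2% or 10% (cycled); plus a three-patient shared deletion and one deletion
whose only DGV support is common-but-high-rank (must survive). One
insertion has a second 2%-diverged reference copy (the two-locus case) and
one is planted reverse-complemented. Decoy classes — oversize, 4-patient
recurrent, population-common (DGV frequency 5% at rank 3, or gnomAD 3%;
records built at reciprocal overlap 0.9 so matching is unambiguous at the
0.5 threshold), intronic-silent, non-ROI — are each excluded by exactly
one rule, which the tests demonstrate by permuting rule orders and by
disabling one threshold at a time. The PPI world plants one bridge node
per patient between two of that patient's SV genes (confidences 0.85–0.90
in the HIPPIE-like list, 640–650/1000 in the STRING-like list so the
STRING network finds nothing), one direct cross-SV edge, sub-0.63 decoy
bridges, and random background edges that never touch more than one
candidate gene.

What passing on this world does *not* show: the generator has no
segmental-duplication repeat structure, no read-level noise, no breakpoint
imprecision and no multi-allelic complexity, so perfect precision/recall
here demonstrates the correctness of the filtering logic, not calling
accuracy on real repetitive loci. Sizes were chosen so the full suite and
the end-to-end acceptance run finish in well under a minute each on one
CPU.

## Determinism and numerical notes

All randomness flows from one `numpy` `default_rng(seed)`; writers emit
sorted rows, fixed float formats and no timestamps, so identical
seed/config reproduce byte-identical worlds and run outputs (hash-checked
in tests). The run manifest records the config hash and input checksums;
stage timings go to the log only, precisely to keep outputs byte-stable.
Tie-breaks everywhere are lexicographic or coordinate-sorted. Degenerate
inputs: empty VCF bodies give empty callsets; an insertion query shorter
than the seed size is an error; a patient with no candidate genes gets an
empty convergence table rather than a failure; zero-length intervals are
handled throughout (they overlap a feature only by containment).

## Known limitations

No breakend/translocation support, no liftover, no genotype semantics, no
mobile-element classification of insertions, no GO enrichment. The DGV- and
gnomAD-like tables use a minimal imposed TSV schema (the upstream export
formats vary); real exports need a one-off column mapping. Population
matching for insertions effectively never excludes (CNV databases carry
loss/gain records), mirroring practice of evaluating insertions separately.
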