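"""Synthetic miniature world with planted ground truth.

Generates everything the pipeline consumes — reference FASTA, gene models,
ROI list, regulatory track, expression flags, population SV databases,
per-patient SV callsets, and two PPI edge lists — small enough for a desk
run yet structured so every filtering rule has planted positives and
decoys:

* planted candidates: exonic deletions/duplications, regulatory-only
  intronic deletions (each over a patient-private intronic enhancer),
  CNS-expression-only intronic deletions, insertions copied from distal
  donor loci at controlled divergence (0, 2%, 10% substitutions), a
  three-patient shared deletion, and a deletion whose only population
  evidence is high-frequency but unreliably-delineated (high inner rank)
  DGV records — which must survive;
* decoy classes, each separably excluded by exactly one rule: oversize
  (> 5 Mb, by coordinate fiat on a virtual 12 Mb chromosome), recurrent
  (identical call in four patients), population-common (matched by a DGV
  record that is both common and low-rank, or by a common gnomAD record),
  intronic-silent (intron of a non-CNS gene, no regulatory element), and
  outside-ROI calls;
* a PPI world where each patient has a planted bridge node connecting two
  of their SVs' genes (the convergence pattern), one direct cross-SV
  candidate–candidate edge, sub-threshold decoy bridges that must be
  filtered out, and a STRING-like network whose bridges sit below the
  0.700 cutoff so it finds no convergence at all.

Base composition is i.i.d. uniform; no repeat structure is simulated. The
95%-identity mechanics are exercised by explicit donor copies (one
insertion additionally has a second, 2%-diverged reference copy so the
two-locus case occurs, and one inserted segment is reverse-complemented).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as svio
from .insertion import revcomp
from .model import (
    ExpressionFlag,
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

ALL_DECOY_CLASSES = (
    "oversize", "recurrent", "population", "intronic_silent", "non_roi",
)

EXON_LEN = 300
INTRON_LEN = 2000
GENE_SPACING = 5000


@dataclass(frozen=True)
class WorldParams:
    rng_seed: int = 17
    n_chromosomes: int = 3
    chrom_length: int = 500_000
    n_roi_genes: int = 20
    n_decoy_genes: int = 20
    n_patients: int = 6
    divergence_rates: tuple[float, ...] = (0.0, 0.02, 0.10)
    decoy_classes: tuple[str, ...] = ALL_DECOY_CLASSES
    n_background_ppi_genes: int = 40
    n_background_ppi_edges: int = 80
    virtual_chrom_length: int = 12_000_000

    def __post_init__(self) -> None:
        if self.n_roi_genes < 8 + 2 * self.n_patients:
            raise ValueError(
                f"n_roi_genes must be >= {8 + 2 * self.n_patients} for "
                f"{self.n_patients} patients (role genes cannot fit)"
            )
        if self.n_patients < 4 and "recurrent" in self.decoy_classes:
            raise ValueError("recurrent decoys need >= 4 patients")
        for d in self.divergence_rates:
            if not 0.0 <= d < 1.0:
                raise ValueError(f"divergence rate {d} not in [0,1)")
        needed = self.n_roi_genes + self.n_decoy_genes
        per_chrom = (needed + self.n_chromosomes - 1) // self.n_chromosomes
        span = per_chrom * (8 * EXON_LEN + 7 * INTRON_LEN + GENE_SPACING)
        if span > self.chrom_length - 60_000:
            raise ValueError(
                f"{needed} genes do not fit on {self.n_chromosomes} chromosomes "
                f"of {self.chrom_length} bp (need ~{span + 60_000} bp each)"
            )


@dataclass
class TruthManifest:
    """Per-patient expectations the generator guarantees by construction."""

    seed: int
    patients: dict[str, dict] = field(default_factory=dict)

    def all_candidates(self) -> set[str]:
        return {s for p in self.patients.values() for s in p["candidates"]}

    def all_excluded(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for p in self.patients.values():
            out.update(p["excluded"])
        return out

    def validate(self) -> None:
        cands = self.all_candidates()
        excl = set(self.all_excluded())
        if cands & excl:
            raise ValueError("candidate and excluded sets overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "patients": self.patients}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        data = json.loads(Path(path).read_text())
        return cls(seed=data["seed"], patients=data["patients"])


@dataclass
class _Gene:
    symbol: str
    ensembl_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]  # ascending start order

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def model(self) -> TranscriptModel:
        return TranscriptModel(
            gene=self.symbol, transcript_id=self.transcript_id, is_mane=True,
            strand=self.strand, exons=list(self.exons),
        )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute round(rate * len) distinct positions with a different base."""
    n = int(round(rate * len(seq)))
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    bases = "ACGT"
    for p in positions:
        alternatives = [b for b in bases if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


class _WorldBuilder:
    def __init__(self, params: WorldParams) -> None:
        self.p = params
        self.rng = np.random.default_rng(params.rng_seed)
        self.chroms = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
        self.seqs = {c: _random_seq(params.chrom_length, self.rng) for c in self.chroms}
        self.genes: list[_Gene] = []
        self.regulatory: list[RegulatoryElement] = []
        self.expression: dict[str, bool] = {}
        self.dgv: list[PopulationSVRecord] = []
        self.gnomad: list[PopulationSVRecord] = []
        self.callsets: dict[str, list[StructuralVariant]] = {
            f"P{i + 1}": [] for i in range(params.n_patients)
        }
        self.manifest = TruthManifest(seed=params.rng_seed)
        for pid in self.callsets:
            self.manifest.patients[pid] = {
                "candidates": [], "excluded": {}, "insertions": {},
                "convergence": {"HIPPIE_LIKE": [], "STRING_LIKE": []},
            }
        self._donor_cursor = {
            c: params.chrom_length - 40_000 for c in self.chroms
        }
        self._counters = {"dgv": 0, "gnomad": 0, "gh": 0}

    # -- identifiers --------------------------------------------------------

    def _dgv_id(self) -> str:
        self._counters["dgv"] += 1
        return f"dgvsyn_{self._counters['dgv']:04d}"

    def _gnomad_id(self) -> str:
        self._counters["gnomad"] += 1
        return f"gnomsyn_{self._counters['gnomad']:04d}"

    def _gh_id(self) -> str:
        self._counters["gh"] += 1
        return f"GHS{self._counters['gh']:04d}"

    # -- layout -------------------------------------------------------------

    def place_genes(self) -> None:
        p = self.p
        cursors = {c: 10_000 for c in self.chroms}
        n_total = p.n_roi_genes + p.n_decoy_genes
        role_indices = set(range(2)) | {8 + 2 * p.n_patients - 1}
        for g in range(n_total):
            is_roi = g < p.n_roi_genes
            chrom = self.chroms[g % len(self.chroms)]
            # role genes (exon-per-patient hosts) always get 8 exons
            n_exons = 8 if (is_roi and g in role_indices) else int(self.rng.integers(4, 9))
            strand = "+" if self.rng.integers(0, 2) == 0 else "-"
            start = cursors[chrom]
            exons = []
            pos = start
            for _ in range(n_exons):
                exons.append(GenomicInterval(chrom, pos, pos + EXON_LEN))
                pos += EXON_LEN + INTRON_LEN
            span_end = exons[-1].end
            cursors[chrom] = span_end + GENE_SPACING
            if is_roi:
                sym = f"ROIG{g + 1:02d}"
                eid = f"SENSG{g + 1:08d}"
            else:
                d = g - p.n_roi_genes
                sym = f"DCYG{d + 1:02d}"
                eid = f"SENSG{9000 + d:08d}"
            self.genes.append(
                _Gene(sym, eid, f"SENST{g + 1:08d}", chrom, strand, exons)
            )
        # virtual chromosome gene for the oversize decoy: exons spread over 6.5 Mb
        v_exons = [
            GenomicInterval("chrV", 500_000 + i * 400_000, 500_000 + i * 400_000 + EXON_LEN)
            for i in range(16)
        ]
        self.vgene = _Gene(
            "ROIGV1", f"SENSG{8888:08d}", f"SENST{8888:08d}", "chrV", "+", v_exons
        )
        self.genes.append(self.vgene)

    # role-gene accessors (indices into the ROI block)
    def roi_gene(self, idx: int) -> _Gene:
        return self.genes[idx]

    @property
    def g_exdel(self) -> _Gene:
        return self.roi_gene(0)

    @property
    def g_dup(self) -> _Gene:
        return self.roi_gene(1)

    def g_reg(self, i: int) -> _Gene:
        return self.roi_gene(2 + i)

    def g_cns(self, i: int) -> _Gene:
        return self.roi_gene(2 + self.p.n_patients + i)

    @property
    def g_shared3(self) -> _Gene:
        return self.roi_gene(2 + 2 * self.p.n_patients)

    @property
    def g_recur(self) -> _Gene:
        return self.roi_gene(3 + 2 * self.p.n_patients)

    @property
    def g_popdel(self) -> _Gene:
        return self.roi_gene(4 + 2 * self.p.n_patients)

    @property
    def g_popdup(self) -> _Gene:
        return self.roi_gene(5 + 2 * self.p.n_patients)

    @property
    def g_rankonly(self) -> _Gene:
        return self.roi_gene(6 + 2 * self.p.n_patients)

    @property
    def g_silent(self) -> _Gene:
        return self.roi_gene(7 + 2 * self.p.n_patients)

    def decoy_gene(self, i: int) -> _Gene:
        return self.genes[self.p.n_roi_genes + i]

    # -- annotations --------------------------------------------------------

    def place_annotations(self) -> None:
        p = self.p
        # patient-private intronic enhancers in the regulatory-pool genes
        self.reg_enhancers: list[RegulatoryElement] = []
        for i in range(p.n_patients):
            g = self.g_reg(i)
            e1 = g.exons[0]
            enh = RegulatoryElement(
                element_id=self._gh_id(),
                interval=GenomicInterval(g.chrom, e1.end + 600, e1.end + 800),
                category="enhancer",
                elite=bool(i % 2 == 0),
                target_genes=[g.symbol, f"BGN{i + 1:02d}"],
            )
            self.reg_enhancers.append(enh)
            self.regulatory.append(enh)
        # expression flags: CNS-pool genes are CNS-expressed, everything else not
        cns_syms = {self.g_cns(i).symbol for i in range(p.n_patients)}
        for g in self.genes:
            self.expression[g.symbol] = g.symbol in cns_syms

    # -- planted SVs --------------------------------------------------------

    def _add_sv(
        self, pid: str, sv_id: str, svtype: SVType, interval: GenomicInterval,
        expected: str, inserted_seq: str | None = None,
    ) -> StructuralVariant:
        svlen = len(inserted_seq) if inserted_seq is not None else interval.length()
        sv = StructuralVariant(sv_id, pid, svtype, interval, svlen, inserted_seq)
        self.callsets[pid].append(sv)
        entry = self.manifest.patients[pid]
        if expected == "candidate":
            entry["candidates"].append(sv_id)
        else:
            entry["excluded"][sv_id] = expected
        return sv

    @staticmethod
    def _exon_del(g: _Gene, exon_idx: int) -> GenomicInterval:
        ex = g.exons[exon_idx]
        return GenomicInterval(g.chrom, ex.start - 50, ex.end + 50)

    def plant_candidates(self) -> None:
        p = self.p
        for i in range(p.n_patients):
            pid = f"P{i + 1}"
            self._add_sv(
                pid, f"{pid}_exdel", SVType.DEL,
                self._exon_del(self.g_exdel, i % 8), "candidate",
            )
            self._add_sv(
                pid, f"{pid}_dup", SVType.DUP,
                self._exon_del(self.g_dup, i % 8), "candidate",
            )
            g = self.g_reg(i)
            enh = self.reg_enhancers[i].interval
            self._add_sv(
                pid, f"{pid}_regdel", SVType.DEL,
                GenomicInterval(g.chrom, enh.start - 100, enh.end + 100), "candidate",
            )
            g = self.g_cns(i)
            e2 = g.exons[1]
            self._add_sv(
                pid, f"{pid}_cnsdel", SVType.DEL,
                GenomicInterval(g.chrom, e2.end + 500, e2.end + 900), "candidate",
            )
        # shared-by-three deletion (kept, shared_with recorded)
        g = self.g_shared3
        iv = GenomicInterval(g.chrom, g.exons[1].start - 50, g.exons[3].end + 50)
        for i in range(min(3, p.n_patients)):
            self._add_sv(f"P{i + 1}", f"P{i + 1}_shared3", SVType.DEL, iv, "candidate")
        # deletion whose only DGV support is common but high-rank: retained
        if p.n_patients >= 2:
            g = self.g_rankonly
            iv = GenomicInterval(g.chrom, g.exons[1].start - 50, g.exons[2].end + 50)
            self._add_sv("P2", "P2_rankonly", SVType.DEL, iv, "candidate")
            for freq, rank in ((8.82, 13), (0.02, 7)):
                self.dgv.append(
                    PopulationSVRecord(
                        PopSource.DGV_GOLD, self._dgv_id(),
                        self._ro_expanded(iv, 0.9), SVType.DEL, freq / 100.0,
                        inner_rank=rank, n_samples=int(self.rng.integers(100, 5000)),
                    )
                )
            self.gnomad.append(
                PopulationSVRecord(
                    PopSource.GNOMAD_CNV, self._gnomad_id(),
                    self._ro_expanded(iv, 0.9), SVType.DEL, 0.001,
                )
            )

    def _ro_expanded(self, iv: GenomicInterval, target_ro: float) -> GenomicInterval:
        """An interval containing ``iv`` whose reciprocal overlap with it is target_ro."""
        extra = int(round(iv.length() * (1.0 / target_ro - 1.0)))
        return GenomicInterval(iv.chrom, iv.start, iv.end + extra)

    def plant_insertions(self) -> None:
        p = self.p
        for i in range(p.n_patients):
            pid = f"P{i + 1}"
            site_gene = self.g_cns(i)
            site_pos = site_gene.exons[1].start + 100
            donor_chrom = self.chroms[
                (self.chroms.index(site_gene.chrom) + 1) % len(self.chroms)
            ]
            length = 440 - 20 * i
            d_start = self._donor_cursor[donor_chrom]
            self._donor_cursor[donor_chrom] += length + 1500
            donor = GenomicInterval(donor_chrom, d_start, d_start + length)
            donor_seq = _to_str(self.seqs[donor_chrom][d_start:d_start + length])
            div = p.divergence_rates[i % len(p.divergence_rates)]
            inserted = _mutate(donor_seq, div, self.rng)
            if i == 1:  # reverse-complement planting exercises strand symmetry
                inserted = revcomp(inserted)
            origins = [donor]
            if i == 0:
                # second, 2%-diverged reference copy: the two-locus case
                copy_chrom = self.chroms[
                    (self.chroms.index(donor_chrom) + 1) % len(self.chroms)
                ]
                c_start = self._donor_cursor[copy_chrom]
                self._donor_cursor[copy_chrom] += length + 1500
                copy_seq = _mutate(donor_seq, 0.02, self.rng)
                enc = np.frombuffer(copy_seq.encode(), dtype=np.uint8)
                lut = np.full(256, -1, dtype=np.int8)
                for v, b in enumerate(b"ACGT"):
                    lut[b] = v
                self.seqs[copy_chrom][c_start:c_start + length] = lut[enc]
                origins.append(GenomicInterval(copy_chrom, c_start, c_start + length))
            recovered = div <= 0.05
            sv = self._add_sv(
                pid, f"{pid}_ins", SVType.INS,
                GenomicInterval(site_gene.chrom, site_pos, site_pos),
                "candidate", inserted_seq=inserted,
            )
            # donor promoter: the regulatory cargo an origin hit should report
            self.regulatory.append(
                RegulatoryElement(
                    element_id=self._gh_id(),
                    interval=GenomicInterval(donor.chrom, donor.start - 50, donor.start + 150),
                    category="promoter" if i % 2 == 0 else "promoter_enhancer",
                    elite=True,
                    target_genes=[
                        self.decoy_gene(2 * i).symbol,
                        self.decoy_gene(2 * i + 1).symbol,
                    ],
                )
            )
            self.manifest.patients[pid]["insertions"][sv.sv_id] = {
                "divergence": div,
                "recovered": recovered,
                "origins": [[o.chrom, o.start, o.end] for o in origins],
            }

    def plant_decoys(self) -> None:
        p = self.p
        classes = set(p.decoy_classes)
        if "oversize" in classes:
            iv = GenomicInterval("chrV", 600_000, 6_200_000)
            self._add_sv("P1", "P1_oversize", SVType.DEL, iv, "size_gt_max")
        if "recurrent" in classes:
            iv = self._exon_del(self.g_recur, 1)
            for i in range(4):
                self._add_sv(
                    f"P{i + 1}", f"P{i + 1}_recur", SVType.DEL, iv,
                    "recurrent_ge_min_patients",
                )
        if "population" in classes:
            iv = self._exon_del(self.g_popdel, 1)
            pop_iv = self._ro_expanded(iv, 0.9)
            self.dgv.append(
                PopulationSVRecord(
                    PopSource.DGV_GOLD, self._dgv_id(), pop_iv, SVType.DEL,
                    0.05, inner_rank=3, n_samples=2500,
                )
            )
            for i in (p.n_patients - 2, p.n_patients - 1):
                self._add_sv(
                    f"P{i + 1}", f"P{i + 1}_popdel", SVType.DEL, iv, "population_common"
                )
            ivd = GenomicInterval(
                self.g_popdup.chrom,
                self.g_popdup.exons[1].start - 50,
                self.g_popdup.exons[2].end + 50,
            )
            self.gnomad.append(
                PopulationSVRecord(
                    PopSource.GNOMAD_CNV, self._gnomad_id(),
                    self._ro_expanded(ivd, 0.9), SVType.DUP, 0.03,
                )
            )
            self._add_sv("P1", "P1_popdup", SVType.DUP, ivd, "population_common")
        if "intronic_silent" in classes:
            g = self.g_silent
            for i in range(min(p.n_patients, len(g.exons) - 1)):
                e = g.exons[i]
                iv = GenomicInterval(g.chrom, e.end + 400, e.end + 800)
                self._add_sv(
                    f"P{i + 1}", f"P{i + 1}_silent", SVType.DEL, iv,
                    "intronic_no_regulatory",
                )
        if "non_roi" in classes:
            for i in range(p.n_patients):
                g = self.decoy_gene(i)
                self._add_sv(
                    f"P{i + 1}", f"P{i + 1}_nonroi", SVType.DEL,
                    self._exon_del(g, 1), "not_in_roi",
                )

    def plant_population_background(self) -> None:
        """Records overlapping nothing planted; exercise readers/sorting only."""
        for j, chrom in enumerate(self.chroms):
            base = self.p.chrom_length - 8_000 + 500 * j
            iv = GenomicInterval(chrom, base, base + 1_200 + 100 * j)
            self.dgv.append(
                PopulationSVRecord(
                    PopSource.DGV_GOLD, self._dgv_id(), iv,
                    SVType.DEL if j % 2 == 0 else SVType.DUP,
                    float(self.rng.uniform(0.001, 0.2)),
                    inner_rank=int(self.rng.integers(2, 16)),
                    n_samples=int(self.rng.integers(50, 9000)),
                )
            )
            self.gnomad.append(
                PopulationSVRecord(
                    PopSource.GNOMAD_CNV, self._gnomad_id(),
                    GenomicInterval(chrom, base + 3_000, base + 4_000),
                    SVType.DUP, float(self.rng.uniform(0.001, 0.1)),
                )
            )

    # -- PPI ----------------------------------------------------------------

    def build_ppi(self) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, int]]]:
        p = self.p
        bg = [f"BGN{i + 1:02d}" for i in range(p.n_background_ppi_genes)]
        hippie: list[tuple[str, str, float]] = []
        string: list[tuple[str, str, int]] = []
        for i in range(p.n_patients):
            pid = f"P{i + 1}"
            bridge = f"BRDG{i + 1}"
            hippie.append((self.g_reg(i).symbol, bridge, 0.90))
            hippie.append((bridge, self.g_cns(i).symbol, 0.85))
            string.append((self.g_reg(i).symbol, bridge, 650))
            string.append((bridge, self.g_cns(i).symbol, 640))
            self.manifest.patients[pid]["convergence"]["HIPPIE_LIKE"] = sorted(
                [bridge, self.g_exdel.symbol, self.g_dup.symbol]
            )
        # direct cross-SV candidate-candidate edge (zero-intermediary convergence)
        hippie.append((self.g_exdel.symbol, self.g_dup.symbol, 0.80))
        # sub-threshold decoy bridge: must vanish at the 0.63 cutoff
        hippie.append((self.g_exdel.symbol, "LOWBR", 0.50))
        hippie.append(("LOWBR", self.g_dup.symbol, 0.55))
        # single-adjacency neighbors (never convergence)
        for i in range(p.n_patients):
            hippie.append((self.g_reg(i).symbol, bg[i], 0.75))
        string.append((self.g_exdel.symbol, bg[p.n_patients], 720))
        # background edges among background genes
        for _ in range(p.n_background_ppi_edges):
            a, b = self.rng.choice(len(bg), size=2, replace=False)
            hippie.append((bg[a], bg[b], float(round(self.rng.uniform(0.5, 0.99), 3))))
            c, d = self.rng.choice(len(bg), size=2, replace=False)
            string.append((bg[c], bg[d], int(self.rng.integers(400, 1000))))
        return hippie, string

    # -- output -------------------------------------------------------------

    def roi_set(self) -> ROISet:
        entries = []
        for g in self.genes:
            if g.symbol.startswith("ROIG"):
                entries.append((g.ensembl_id, g.symbol, g.span()))
        return ROISet(entries)

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        svio.write_fasta(
            {c: _to_str(self.seqs[c]) for c in self.chroms}, out_dir / "reference.fa"
        )
        svio.write_gene_models([g.model() for g in self.genes], out_dir / "genes.gff3")
        svio.write_roi(self.roi_set(), out_dir / "roi.tsv")
        svio.write_regulatory(
            sorted(self.regulatory, key=lambda e: e.element_id),
            out_dir / "regulatory.tsv",
        )
        svio.write_expression(
            [ExpressionFlag(g, cns) for g, cns in sorted(self.expression.items())],
            out_dir / "expression.tsv",
        )
        svio.write_population_db(self.dgv, out_dir / "dgv.tsv")
        svio.write_population_db(self.gnomad, out_dir / "gnomad.tsv")
        patients_dir = out_dir / "patients"
        patients_dir.mkdir(exist_ok=True)
        for pid, variants in self.callsets.items():
            svio.write_sv_vcf(PatientCallset(pid, variants), patients_dir / f"{pid}.vcf")
        hippie, string = self._ppi
        with open(out_dir / "ppi_hippie.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\tconfidence\n")
            for a, b, c in hippie:
                fh.write(f"{a}\t{b}\t{c}\n")
        with open(out_dir / "ppi_string.tsv", "w") as fh:
            fh.write("protein_a\tprotein_b\tcombined_score\n")
            for a, b, c in string:
                fh.write(f"{a}\t{b}\t{c}\n")
        self.manifest.to_json(out_dir / "truth.json")

    def build(self) -> None:
        self.place_genes()
        self.place_annotations()
        self.plant_candidates()
        self.plant_insertions()
        self.plant_decoys()
        self.plant_population_background()
        self._ppi = self.build_ppi()
        for entry in self.manifest.patients.values():
            entry["candidates"].sort()
        self.manifest.validate()


def generate_world(params: WorldParams, out_dir: str | Path) -> TruthManifest:
    """Generate the synthetic world under ``out_dir``; returns the manifest.

    Deterministic: identical params (including seed) produce byte-identical
    directories.
    """
    builder = _WorldBuilder(params)
    builder.build()
    builder.write(Path(out_dir))
    return builder.manifest


def synthetic_roi_list(n_entries: int = 218, seed: int = 0) -> ROISet:
    """A synthetic stand-in for a published region-of-interest gene list.

    Produces ``n_entries`` unique Ensembl-style IDs with plausible intervals;
    used where only the list's cardinality and schema matter.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_entries):
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(10_000, 200_000_000))
        length = int(rng.integers(5_000, 500_000))
        entries.append(
            (
                f"ENSG{i + 1:011d}",
                f"GENE{i + 1:04d}",
                GenomicInterval(chrom, start, start + length),
            )
        )
    return ROISet(entries)
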