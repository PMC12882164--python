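"""Compare pipeline outputs against a synthetic world's truth manifest.

Per stage (candidates, exclusion reasons, insertion origins, convergence
nodes) the verifier computes precision and recall and names every mismatch,
so a configuration change that loses planted truths is pinpointed rather
than just flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import report
from .model import GenomicInterval
from .synth import TruthManifest


@dataclass
class StageScore:
    n_expected: int
    n_observed: int
    n_matched: int
    false_positives: list[str] = field(default_factory=list)
    false_negatives: list[str] = field(default_factory=list)

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_observed if self.n_observed else 1.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_expected if self.n_expected else 1.0


@dataclass
class VerificationReport:
    stages: dict[str, StageScore]

    def all_perfect(self) -> bool:
        return all(s.precision == 1.0 and s.recall == 1.0 for s in self.stages.values())

    def summary(self) -> str:
        lines = []
        for name, s in self.stages.items():
            lines.append(
                f"{name}: precision={s.precision:.3f} recall={s.recall:.3f} "
                f"({s.n_matched}/{s.n_observed} observed, {s.n_expected} expected)"
            )
            for fp in s.false_positives:
                lines.append(f"  FP {fp}")
            for fn in s.false_negatives:
                lines.append(f"  FN {fn}")
        return "\n".join(lines)


def _score_sets(expected: set[str], observed: set[str]) -> StageScore:
    matched = expected & observed
    return StageScore(
        n_expected=len(expected),
        n_observed=len(observed),
        n_matched=len(matched),
        false_positives=sorted(observed - expected),
        false_negatives=sorted(expected - observed),
    )


def verify_against_manifest(
    run_dir: str | Path, manifest: TruthManifest
) -> VerificationReport:
    run_dir = Path(run_dir)
    for needed in ("candidates.tsv", "provenance.jsonl", "insertions.tsv"):
        if not (run_dir / needed).exists():
            raise FileNotFoundError(f"missing pipeline output {run_dir / needed}")

    stages: dict[str, StageScore] = {}

    # --- candidates -------------------------------------------------------
    cand_df = report.read_candidates(run_dir / "candidates.tsv")
    observed_cands = set(cand_df["sv_id"].astype(str))
    stages["candidates"] = _score_sets(manifest.all_candidates(), observed_cands)

    # --- exclusion reasons ------------------------------------------------
    expected_excl = manifest.all_excluded()
    observed_excl: dict[str, str] = {}
    for obj in report.read_provenance(run_dir / "provenance.jsonl"):
        for rule in obj["rules"]:
            if rule["outcome"] == "exclude":
                observed_excl[obj["sv_id"]] = rule["rule"]
                break
    expected_pairs = {f"{s}:{r}" for s, r in expected_excl.items()}
    observed_pairs = {f"{s}:{r}" for s, r in observed_excl.items()}
    stages["exclusion_reasons"] = _score_sets(expected_pairs, observed_pairs)

    # --- insertion origins ------------------------------------------------
    ins_df = report.read_insertion_reports(run_dir / "insertions.tsv")
    observed_hits: dict[str, list[GenomicInterval]] = {}
    for row in ins_df.itertuples(index=False):
        sv_id = str(row.sv_id)
        observed_hits.setdefault(sv_id, [])
        if str(row.hit_chrom):
            observed_hits[sv_id].append(
                GenomicInterval(str(row.hit_chrom), int(row.hit_start), int(row.hit_end))
            )
    expected_tags: set[str] = set()
    observed_tags: set[str] = set()
    for pid, entry in manifest.patients.items():
        for sv_id, ins in entry["insertions"].items():
            hits = observed_hits.get(sv_id, [])
            if ins["recovered"]:
                for chrom, start, end in ins["origins"]:
                    locus = GenomicInterval(chrom, start, end)
                    expected_tags.add(f"{sv_id}@{locus}")
                    if any(locus.overlaps(h) for h in hits):
                        observed_tags.add(f"{sv_id}@{locus}")
                for h in hits:
                    if not any(
                        GenomicInterval(c, s, e).overlaps(h)
                        for c, s, e in ins["origins"]
                    ):
                        observed_tags.add(f"{sv_id}@{h}")  # spurious locus
            else:
                for h in hits:
                    observed_tags.add(f"{sv_id}@{h}")  # any hit is spurious
    stages["insertion_origins"] = _score_sets(expected_tags, observed_tags)

    # --- convergence nodes ------------------------------------------------
    expected_conv: set[str] = set()
    observed_conv: set[str] = set()
    for pid, entry in manifest.patients.items():
        for source, genes in entry["convergence"].items():
            for g in genes:
                expected_conv.add(f"{pid}:{source}:{g}")
            conv_path = run_dir / "networks" / f"{pid}_{source}_convergence.tsv"
            if conv_path.exists():
                df = report.read_convergence(conv_path)
                for g in df["gene"].astype(str):
                    observed_conv.add(f"{pid}:{source}:{g}")
    stages["convergence_nodes"] = _score_sets(expected_conv, observed_conv)

    return VerificationReport(stages)
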