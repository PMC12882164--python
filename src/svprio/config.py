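"""Pipeline configuration: every numeric threshold the cascade applies.

Defaults encode the filtering rules as published for this analysis style:
SVs over 5 Mb are excluded (pre-screened by karyotype/CMA), SVs shared by
four or more patients are treated as technical or common-population
artifacts, population matches exclude only when the supporting database
record is both common (>= 1%) and reliably delineated (DGV inner rank <= 6),
inserted sequences must realign at >= 95% identity to call an origin, and
PPI edges below 0.63 (HIPPIE-style) / 0.700 (STRING-style) are dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    max_sv_size: int = 5_000_000
    recurrence_patient_min: int = 4
    recurrence_ro_min: float = 0.5
    ins_match_window: int = 100
    ins_match_len_tol: float = 0.2
    popdb_ro_min: float = 0.5
    dgv_freq_max: float = 0.01
    dgv_rank_reliable_max: int = 6
    gnomad_freq_max: float = 0.01
    blat_min_identity: float = 0.95
    hippie_min_conf: float = 0.63
    string_min_conf: float = 0.700
    rng_seed: int = 17

    def __post_init__(self) -> None:
        fractions = {
            "recurrence_ro_min": self.recurrence_ro_min,
            "ins_match_len_tol": self.ins_match_len_tol,
            "popdb_ro_min": self.popdb_ro_min,
            "dgv_freq_max": self.dgv_freq_max,
            "gnomad_freq_max": self.gnomad_freq_max,
            "blat_min_identity": self.blat_min_identity,
            "hippie_min_conf": self.hippie_min_conf,
            "string_min_conf": self.string_min_conf,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} not in [0,1]")
        for name in (
            "max_sv_size",
            "recurrence_patient_min",
            "ins_match_window",
            "dgv_rank_reliable_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hash(self) -> str:
        """Stable short hash of the configuration, stamped into outputs."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are fatal to prevent silent typos."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path}: expected a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
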