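"""Shared fixtures: one synthetic world (seed 17) and one pipeline run,
built once per session and reused by unit, property and acceptance tests."""

from __future__ import annotations

from pathlib import Path

import pytest

from svprio.config import PipelineConfig
from svprio.pipeline import RunSpec, run_all
from svprio.synth import TruthManifest, WorldParams, generate_world


@pytest.fixture(scope="session")
def world_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("world") / "w"
    generate_world(WorldParams(rng_seed=17), out)
    return out


@pytest.fixture(scope="session")
def manifest(world_dir) -> TruthManifest:
    return TruthManifest.from_json(world_dir / "truth.json")


@pytest.fixture(scope="session")
def run_dir(world_dir, tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("run") / "r"
    run_all(RunSpec.from_world(world_dir), out, PipelineConfig())
    return out


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()
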