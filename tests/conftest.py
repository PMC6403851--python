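"""Shared fixtures: pipeline configuration and the expensive synthetic
profile banks reused across morphometry, classification and statistics
tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from glutenpna import (AttributeProfile, PipelineConfig, default_spec,
                       generate_dose_series, generate_network_image,
                       process_micrograph)
from glutenpna.synthetic import AGENTS, REGIMES, SynthSpec

DOSES = [0.0, 1.0, 2.0, 3.0]
N_RECOVERY = 100      # images per regime for classifier recovery
N_SERIES_SEEDS = 20   # replicate seeds per agent series


def small_branched_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Quarter-field branched spec (256 px) with density-preserving
    parameters; cheap enough for per-seed loops."""
    spec = replace(
        default_spec("branched", seed=seed),
        size_px=256, n_seeds=240, starch_disc_count=3,
    )
    return replace(spec, **overrides) if overrides else spec


def mean_profile(profiles: list[AttributeProfile],
                 source_id: str = "mean") -> AttributeProfile:
    fields = ("lacunarity", "branching_rate", "endpoint_rate",
              "avg_protein_length_um", "protein_width_um", "protein_area_um2")
    means = {f: float(np.mean([getattr(p, f) for p in profiles])) for f in fields}
    return AttributeProfile(source_id=source_id, n_components=1, **means)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


def _profile(regime: str, seed: int, config: PipelineConfig) -> AttributeProfile:
    micro, _ = generate_network_image(default_spec(regime, seed=seed))
    return process_micrograph(micro, config)


@pytest.fixture(scope="session")
def reference_profile(config) -> AttributeProfile:
    """The standard (type II) reference: mean profile of 8 branched images."""
    return mean_profile(
        [_profile("branched", 10_000 + k, config) for k in range(8)], "standard"
    )


@pytest.fixture(scope="session")
def regime_profiles(config) -> dict[str, list[AttributeProfile]]:
    """100 measured profiles per morphological regime (seeds 0..99)."""
    return {
        regime: [_profile(regime, s, config) for s in range(N_RECOVERY)]
        for regime in REGIMES
    }


@pytest.fixture(scope="session")
def agent_profiles(config):
    """Measured dose-series profiles: agent -> seed -> [(conc, profile)]."""
    bank: dict[str, dict[int, list]] = {}
    for agent in AGENTS:
        bank[agent] = {}
        for seed in range(N_SERIES_SEEDS):
            series = generate_dose_series(agent, DOSES, seed=seed)
            bank[agent][seed] = [
                (conc, process_micrograph(micro, config))
                for conc, micro, _ in series
            ]
    return bank
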