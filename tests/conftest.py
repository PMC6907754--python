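"""Shared fixtures: toy hand-checkable networks, a small synthetic survey
scenario, and the loader for the deposited reference interaction-strength
dataset (used by the reference-value checks when the CSV is present)."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import pollinet as pn

REFERENCE_DIR = Path(__file__).parent / "data" / "reference"
S1_STRENGTHS = REFERENCE_DIR / "s1_interaction_strengths.csv"


def load_reference_network(measure: str) -> pn.WeightedBipartiteNetwork:
    """The deposited per-interaction strength table of the 19-plant scrubland
    network (long CSV: plant, pollinator, strength_encounter, strength_visit).

    The deposited supplementary CSV is not redistributable with this package;
    place it at ``tests/data/reference/s1_interaction_strengths.csv`` to
    enable the reference-value checks.
    """
    if not S1_STRENGTHS.exists():
        raise FileNotFoundError(
            f"reference interaction-strength dataset not present at "
            f"{S1_STRENGTHS}; deposit the published supplementary CSV there "
            f"(columns plant, pollinator, strength_encounter, strength_visit) "
            f"to run reference-value checks"
        )
    return pn.read_strength_matrix(S1_STRENGTHS, measure=measure)


@pytest.fixture
def toy_network() -> pn.WeightedBipartiteNetwork:
    """W = [[2, 2], [1, 0]] with rows (p1, p2), cols (z1, z2)."""
    return pn.WeightedBipartiteNetwork(
        ("p1", "p2"), ("z1", "z2"), np.array([[2.0, 2.0], [1.0, 0.0]])
    )


@pytest.fixture(scope="session")
def small_config() -> pn.ScenarioConfig:
    return pn.ScenarioConfig(
        n_plants=6,
        n_pollinators=12,
        n_weeks=8,
        follows_mean=8.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config) -> pn.SyntheticScenario:
    return pn.generate_scenario(small_config)


@pytest.fixture(scope="session")
def small_networks(small_scenario):
    """(filtered encounter network, visit network, estimates) for the small
    scenario."""
    return pn.build_networks(
        small_scenario.encounters,
        small_scenario.flower_surveys,
        small_scenario.visit_samples,
    )
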