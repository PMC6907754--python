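"""Synthetic plant-pollinator survey generator.

Emulates the statistical structure of a season-long scrubland visitation
survey so that every pipeline stage is testable without field data:

* a community of ~19 plants and ~122 pollinator morphotypes, the pollinators
  split into functional groups (bees, beetles, flies, butterflies, wasps,
  ants, true bugs, grasshoppers) with group-specific visit behavior;
* log-normal floral displays and a positive log-log relation between floral
  display and mean visits per encounter, with plant-level residual noise;
* heavy-tailed interaction preferences (Dirichlet rows over a shared
  heavy-tailed pollinator activity profile, giving a few dominant pollinators
  and many rare ones);
* weekly phenology: each plant blooms in a contiguous window with a
  triangular within-window intensity profile; weekly flower abundance and
  surveyed-flower counts follow display x phenology;
* overdispersed (negative binomial) encounter and follow counts.

One scenario seed governs all draws through ``numpy`` generator spawning
(community, encounters and visit follows each consume an independent child
stream), so any stage can be regenerated reproducibly in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EncounterEvent, FlowerSurveyRecord, PlantTraits, VisitSample

__all__ = [
    "ScenarioConfig",
    "Community",
    "SyntheticScenario",
    "generate_community",
    "generate_encounters",
    "generate_visit_samples",
    "generate_scenario",
]

# roster proportions of the eight pollinator functional groups (sums to 122)
_GROUPS = ("bees", "beetles", "flies", "butterflies", "wasps", "ants", "bugs", "grasshoppers")
_GROUP_COUNTS = (39, 27, 20, 15, 9, 8, 3, 1)
# log-scale multipliers on mean visits per encounter: bees work many flowers
# per plant, beetles and ants tend to sit on one or few
_GROUP_VISIT_EFFECTS = (0.25, -0.65, -0.10, 0.10, 0.0, -0.50, -0.30, -0.20)


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one synthetic survey scenario.

    Defaults describe a Mediterranean-scrubland-like community: 19 plants,
    122 pollinator morphotypes, a 14-week (March-June) season, log-normal
    floral displays (mu = 2.96, sigma = 1.81 on the log scale, i.e. median
    ~19 open flowers), and a display-visits log-log line with slope 0.28,
    intercept 0.17 and residual sd 0.52 — the regime estimated from a
    published 19-plant survey summary (see ``pollinet.datasets``). Encounter
    intensity is set so a default run records on the order of 4 x 10^3
    encounters, the scale of a full-season field campaign.
    """

    n_plants: int = 19
    n_pollinators: int = 122
    n_weeks: int = 14
    group_names: tuple[str, ...] = _GROUPS
    group_weights: tuple[float, ...] = _GROUP_COUNTS
    group_visit_effects: tuple[float, ...] = _GROUP_VISIT_EFFECTS
    display_log_mean: float = 2.96
    display_log_sd: float = 1.81
    visits_intercept: float = 0.17
    visits_slope: float = 0.28
    visits_resid_sd: float = 0.52
    preference_concentration: float = 0.02
    pollinator_activity_log_sd: float = 1.3
    mean_bloom_weeks: float = 6.0
    bloom_weeks_sd: float = 2.0
    plant_density_log_sd: float = 0.7
    tagged_individuals: float = 6.0
    encounter_intensity: float = 0.7
    encounter_dispersion: float | None = 1.0
    follows_mean: float = 15.0
    follows_dispersion: float | None = 0.5
    visit_count_dispersion: float | None = 2.0
    zero_follow_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 2 or self.n_pollinators < 2 or self.n_weeks < 2:
            raise ValueError("n_plants, n_pollinators and n_weeks must all be >= 2")
        if not (
            len(self.group_names)
            == len(self.group_weights)
            == len(self.group_visit_effects)
        ):
            raise ValueError("group name/weight/effect tuples must align")
        if self.display_log_sd <= 0 or not np.isfinite(self.display_log_sd):
            raise ValueError("display_log_sd must be positive and finite")
        if not np.isfinite(self.visits_slope) or self.visits_resid_sd < 0:
            raise ValueError("visits_slope must be finite and visits_resid_sd >= 0")
        if self.preference_concentration <= 0:
            raise ValueError("preference_concentration must be positive")
        if self.encounter_intensity <= 0:
            raise ValueError("encounter_intensity must be positive")


@dataclass(frozen=True)
class Community:
    """Sampled community: traits, roster, preferences and phenology."""

    traits: tuple[PlantTraits, ...]
    pollinators: pd.DataFrame  # columns: pollinator, group, visit_log_effect
    preference: np.ndarray  # plants x pollinators, rows sum to 1
    phenology: pd.DataFrame  # columns: plant, start_week, end_week
    density: dict[str, float]  # flowering individuals per m^2

    @property
    def plants(self) -> list[str]:
        return [t.plant for t in self.traits]

    @property
    def display(self) -> dict[str, float]:
        return {t.plant: t.floral_display for t in self.traits}


@dataclass(frozen=True)
class SyntheticScenario:
    """One fully generated survey dataset plus its ground truth."""

    config: ScenarioConfig
    community: Community
    encounters: list[EncounterEvent]
    flower_surveys: list[FlowerSurveyRecord]
    visit_samples: list[VisitSample]
    ground_truth: dict


def _count_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float | None
) -> np.ndarray:
    """Poisson (dispersion None), negative binomial, or deterministic
    (dispersion 0: rounded mean, the no-sampling-noise limit) counts."""
    mean = np.asarray(mean, float)
    if dispersion is None:
        return rng.poisson(mean)
    if dispersion == 0:
        return np.rint(mean).astype(int)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def _allocate_groups(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n pollinators across groups."""
    w = np.asarray(weights, float)
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_community(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> Community:
    """Draw traits, pollinator roster, preferences and phenology."""
    if rng is None:
        rng = np.random.default_rng(config.seed).spawn(3)[0]
    displays = np.exp(
        rng.normal(config.display_log_mean, config.display_log_sd, config.n_plants)
    )
    plants = [f"P{i + 1:02d}" for i in range(config.n_plants)]
    traits = tuple(PlantTraits(p, float(d)) for p, d in zip(plants, displays))

    counts = _allocate_groups(config.n_pollinators, config.group_weights)
    groups: list[str] = []
    effects: list[float] = []
    for name, eff, k in zip(config.group_names, config.group_visit_effects, counts):
        groups += [name] * k
        effects += [eff] * k
    pollinators = pd.DataFrame(
        {
            "pollinator": [f"Z{j + 1:03d}" for j in range(config.n_pollinators)],
            "group": groups,
            "visit_log_effect": effects,
        }
    )

    # shared heavy-tailed activity profile -> a few dominant pollinators;
    # small concentration -> heavy-tailed per-plant preference rows
    activity = np.exp(rng.normal(0.0, config.pollinator_activity_log_sd, config.n_pollinators))
    alpha = config.preference_concentration * activity / activity.mean()
    preference = np.vstack(
        [rng.dirichlet(alpha) for _ in range(config.n_plants)]
    )

    durations = np.clip(
        np.rint(rng.normal(config.mean_bloom_weeks, config.bloom_weeks_sd, config.n_plants)),
        1,
        config.n_weeks,
    ).astype(int)
    starts = np.array(
        [rng.integers(1, config.n_weeks - d + 2) for d in durations]
    )
    phenology = pd.DataFrame(
        {"plant": plants, "start_week": starts, "end_week": starts + durations - 1}
    )
    density = {
        p: float(np.exp(rng.normal(0.0, config.plant_density_log_sd)))
        for p in plants
    }
    return Community(traits, pollinators, preference, phenology, density)


def _bloom_profile(start: int, end: int) -> dict[int, float]:
    """Triangular within-window bloom intensity, peak 1 mid-window."""
    weeks = range(start, end + 1)
    mid = (start + end) / 2
    half = max((end - start) / 2, 0.5)
    return {w: max(1.0 - abs(w - mid) / (half + 0.5), 0.05) for w in weeks}


def generate_encounters(
    community: Community,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[EncounterEvent], list[FlowerSurveyRecord]]:
    """Weekly flower surveys and encounter events.

    Weekly flower abundance is density x display x bloom profile; surveyed
    flowers are a Poisson count around tagged-individuals x display x
    profile; encounter counts per (week, plant, pollinator) are overdispersed
    with mean intensity x abundance x preference. Encounters are only emitted
    in weeks where the plant's surveyed-flower count is positive (otherwise
    the weekly frequency would be undefined), mirroring a protocol in which
    observation bouts happen on the surveyed individuals.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed).spawn(3)[1]
    poll_labels = community.pollinators["pollinator"].tolist()
    encounters: list[EncounterEvent] = []
    surveys: list[FlowerSurveyRecord] = []
    for i, trait in enumerate(community.traits):
        row = community.phenology.iloc[i]
        start, end = int(row.start_week), int(row.end_week)
        if end < start:  # empty window: plant never blooms, never surveyed
            continue
        profile = _bloom_profile(start, end)
        for week, intensity in profile.items():
            abundance = community.density[trait.plant] * trait.floral_display * intensity
            surveyed = int(rng.poisson(config.tagged_individuals * trait.floral_display * intensity))
            surveys.append(
                FlowerSurveyRecord(week, trait.plant, surveyed, float(abundance))
            )
            if surveyed <= 0:
                continue
            mean = config.encounter_intensity * abundance * community.preference[i]
            counts = _count_draw(rng, mean, config.encounter_dispersion)
            for j in np.flatnonzero(counts):
                encounters.extend(
                    [EncounterEvent(week, trait.plant, poll_labels[j])] * int(counts[j])
                )
    return encounters, surveys


def generate_visit_samples(
    community: Community,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> list[VisitSample]:
    """4-minute follow samples of flowers visited per encounter.

    For each (plant, pollinator) pair the expected visits are
    mu = exp(intercept + slope * ln(display) + group effect + eps) with
    pair-level noise eps ~ N(0, resid_sd), clamped to >= 1. The number of
    follows per pair is an overdispersed count (many pairs get none,
    exercising the donor/expert imputation downstream);
    ``zero_follow_fraction`` instead forces exactly that share of pairs to
    zero follows. Visit counts are shifted negative binomial
    (1 + NB(mu - 1)), keeping support >= 1 and the mean exactly mu.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed).spawn(3)[2]
    n_p, n_z = config.n_plants, config.n_pollinators
    displays = np.array([t.floral_display for t in community.traits])
    effects = community.pollinators["visit_log_effect"].to_numpy()
    eps = rng.normal(0.0, config.visits_resid_sd, (n_p, n_z))
    mu = np.exp(
        config.visits_intercept
        + config.visits_slope * np.log(displays)[:, None]
        + effects[None, :]
        + eps
    )
    mu = np.maximum(mu, 1.0)

    n_follows = _count_draw(
        rng, np.full((n_p, n_z), float(config.follows_mean)), config.follows_dispersion
    )
    if config.zero_follow_fraction is not None:
        n_follows = np.maximum(n_follows, 1)
        flat = rng.permutation(n_p * n_z)[: round(config.zero_follow_fraction * n_p * n_z)]
        n_follows.ravel()[flat] = 0

    samples: list[VisitSample] = []
    poll_labels = community.pollinators["pollinator"].tolist()
    plants = community.plants
    for i in range(n_p):
        for j in range(n_z):
            k = int(n_follows[i, j])
            if k == 0:
                continue
            counts = 1 + _count_draw(
                rng, np.full(k, mu[i, j] - 1.0), config.visit_count_dispersion
            )
            samples.extend(
                VisitSample(plants[i], poll_labels[j], int(c)) for c in counts
            )
    return samples


def generate_scenario(config: ScenarioConfig | None = None) -> SyntheticScenario:
    """Generate a complete scenario from one seed.

    The scenario seed is split into three independent child streams
    (community, encounters, visit follows) so each stage is reproducible on
    its own.
    """
    config = config or ScenarioConfig()
    streams = np.random.default_rng(config.seed).spawn(3)
    community = generate_community(config, streams[0])
    encounters, surveys = generate_encounters(community, config, streams[1])
    visits = generate_visit_samples(community, config, streams[2])
    truth = {
        "visits_slope": config.visits_slope,
        "visits_intercept": config.visits_intercept,
        "visits_resid_sd": config.visits_resid_sd,
        "group_visit_effects": dict(
            zip(config.group_names, config.group_visit_effects)
        ),
        "floral_display": {t.plant: t.floral_display for t in community.traits},
    }
    return SyntheticScenario(config, community, encounters, surveys, visits, truth)
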