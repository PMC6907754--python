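"""Interaction-strength pipeline: weekly frequencies, abundance weighting,
visits-per-encounter estimation, and the visit-based network.

Encounter-based strength of plant i with pollinator j is the sum over survey
weeks of (encounters that week / open flowers surveyed on i that week)
multiplied by i's weekly flower abundance — i.e. a sampling-effort-corrected,
abundance-weighted encounter frequency. Visit-based strength multiplies each
cell by the interaction's mean number of flowers visited per encounter.

Mean visits-per-encounter follow a fixed imputation hierarchy: own 4-minute
follows (arithmetic mean pooled across years), else a donor value from a
functionally similar pollinator on the same plant, else an expert default,
else the interaction is excluded from all analyses. Donor and expert
assignments are judgment calls and therefore arrive as configuration, not
code.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core import (
    EncounterEvent,
    FlowerSurveyRecord,
    ValidationError,
    VisitEstimate,
    VisitSample,
    WeightedBipartiteNetwork,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WeeklyFrequency",
    "DonorMap",
    "weekly_encounter_frequency",
    "encounter_strength",
    "estimate_visits",
    "provenance_counts",
    "visit_strength",
    "build_networks",
]


@dataclass(frozen=True)
class WeeklyFrequency:
    """Encounters per surveyed flower for one (week, plant, pollinator)."""

    week: int
    plant: str
    pollinator: str
    frequency: float

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValidationError("frequency must be >= 0")


@dataclass(frozen=True)
class DonorMap:
    """Donor and expert-default configuration for visit imputation.

    `donors` maps an unobserved (plant, pollinator) to the donor pollinator
    whose observed mean on the same plant is borrowed; `expert_defaults` maps
    (plant, pollinator) directly to an expert mean-visits value.
    """

    donors: Mapping[tuple[str, str], str] = field(default_factory=dict)
    expert_defaults: Mapping[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DonorMap":
        """Load from a YAML file with sections::

            donors:
              - {plant: P, pollinator: Z, donor: Z2}
            expert_defaults:
              - {plant: P, pollinator: Z, mean_visits: 1.0}
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        donors = {
            (str(d["plant"]), str(d["pollinator"])): str(d["donor"])
            for d in raw.get("donors", []) or []
        }
        defaults = {
            (str(d["plant"]), str(d["pollinator"])): float(d["mean_visits"])
            for d in raw.get("expert_defaults", []) or []
        }
        return cls(donors, defaults)


def weekly_encounter_frequency(
    encounters: Sequence[EncounterEvent],
    flower_surveys: Sequence[FlowerSurveyRecord],
) -> list[WeeklyFrequency]:
    """Encounters per open surveyed flower, per (week, plant, pollinator).

    Every encounter's (week, plant) must have a flower survey with
    flowers_surveyed > 0; weeks in which a pair was not encountered produce
    no record.
    """
    surveyed = {(f.week, f.plant): f.flowers_surveyed for f in flower_surveys}
    counts = Counter((e.week, e.plant, e.pollinator) for e in encounters)
    bad = sorted(
        {
            (w, p)
            for (w, p, _z) in counts
            if surveyed.get((w, p), 0) <= 0
        }
    )
    if bad:
        raise ValidationError(
            "encounters without a positive flower survey for (week, plant): "
            + ", ".join(map(str, bad))
        )
    return [
        WeeklyFrequency(w, p, z, n / surveyed[(w, p)])
        for (w, p, z), n in sorted(counts.items())
    ]


def encounter_strength(
    weekly_frequencies: Sequence[WeeklyFrequency],
    flower_surveys: Sequence[FlowerSurveyRecord],
) -> WeightedBipartiteNetwork:
    """Abundance-weighted encounter strength network.

    a_ij = sum over weeks of frequency(week, i, j) x flower_abundance(week, i).
    """
    abundance = {(f.week, f.plant): f.flower_abundance for f in flower_surveys}
    missing = sorted(
        {
            (wf.week, wf.plant)
            for wf in weekly_frequencies
            if (wf.week, wf.plant) not in abundance
        }
    )
    if missing:
        raise ValidationError(
            "no flower abundance for contributing (week, plant): "
            + ", ".join(map(str, missing))
        )
    cells: dict[tuple[str, str], float] = defaultdict(float)
    for wf in weekly_frequencies:
        cells[(wf.plant, wf.pollinator)] += wf.frequency * abundance[(wf.week, wf.plant)]
    return WeightedBipartiteNetwork.from_cells(cells, measure="encounter")


def estimate_visits(
    visit_samples: Sequence[VisitSample],
    observed_interactions: Iterable[tuple[str, str]],
    donor_map: DonorMap | None = None,
) -> list[VisitEstimate]:
    """Mean visits-per-encounter for every interaction in the network.

    Resolution order per (plant, pollinator): own follows (arithmetic mean),
    donor pollinator's observed mean on the same plant, expert default,
    otherwise excluded. A donor that itself lacks an observed estimate on
    that plant is a configuration error.
    """
    donor_map = donor_map or DonorMap()
    pooled: dict[tuple[str, str], list[int]] = defaultdict(list)
    for s in visit_samples:
        pooled[(s.plant, s.pollinator)].append(s.n_visits)

    estimates: list[VisitEstimate] = []
    for pair in sorted(set(observed_interactions)):
        plant, pollinator = pair
        if pooled.get(pair):
            obs = pooled[pair]
            estimates.append(
                VisitEstimate(plant, pollinator, float(np.mean(obs)), len(obs), "observed")
            )
            continue
        donor = donor_map.donors.get(pair)
        if donor is not None:
            donor_obs = pooled.get((plant, donor))
            if not donor_obs:
                raise ValidationError(
                    f"donor {donor!r} for ({plant}, {pollinator}) has no "
                    f"observed visit samples on plant {plant!r}"
                )
            estimates.append(
                VisitEstimate(plant, pollinator, float(np.mean(donor_obs)), 0, "donor")
            )
            continue
        if pair in donor_map.expert_defaults:
            estimates.append(
                VisitEstimate(
                    plant, pollinator, donor_map.expert_defaults[pair], 0, "expert"
                )
            )
            continue
        estimates.append(VisitEstimate(plant, pollinator, None, 0, "excluded"))

    counts = provenance_counts(estimates)
    logger.info(
        "visit estimates: %(observed)d observed, %(donor)d donor, "
        "%(expert)d expert, %(excluded)d excluded; %(reliable)d with >= 5 follows",
        {**counts, "reliable": sum(1 for e in estimates if e.n_obs >= 5)},
    )
    return estimates


def provenance_counts(estimates: Sequence[VisitEstimate]) -> dict[str, int]:
    """Counts per provenance class, plus the >=5-follow reliability diagnostic.

    The >=5 count is reported as a diagnostic only; it is never used to
    filter interactions.
    """
    counts = {k: 0 for k in ("observed", "donor", "expert", "excluded")}
    for e in estimates:
        counts[e.provenance] += 1
    counts["n_obs_ge_5"] = sum(1 for e in estimates if e.n_obs >= 5)
    return counts


def visit_strength(
    encounter_network: WeightedBipartiteNetwork,
    visit_estimates: Sequence[VisitEstimate],
) -> tuple[WeightedBipartiteNetwork, WeightedBipartiteNetwork]:
    """Visit-based network plus the matching filtered encounter network.

    Each encounter cell is multiplied by its interaction's mean
    visits-per-encounter. Interactions resolved as excluded are removed from
    BOTH returned networks, so downstream comparisons operate on identical
    link sets. Returns ``(visit_network, filtered_encounter_network)``.
    """
    by_pair = {(e.plant, e.pollinator): e for e in visit_estimates}
    enc_cells = encounter_network.cells()
    missing = sorted(pair for pair in enc_cells if pair not in by_pair)
    if missing:
        raise ValidationError(
            "encounter cells without a visit estimate: " + ", ".join(map(str, missing))
        )
    excluded = {pair for pair in enc_cells if by_pair[pair].excluded}
    visit_cells = {
        pair: v * by_pair[pair].mean_visits
        for pair, v in enc_cells.items()
        if pair not in excluded
    }
    if excluded:
        logger.info("excluded %d interaction(s) lacking visit estimates", len(excluded))
    visit_net = WeightedBipartiteNetwork.from_cells(visit_cells, measure="visit")
    enc_filtered = (
        encounter_network.drop_links(excluded) if excluded else encounter_network
    )
    return visit_net, enc_filtered


def build_networks(
    encounters: Sequence[EncounterEvent],
    flower_surveys: Sequence[FlowerSurveyRecord],
    visit_samples: Sequence[VisitSample],
    donor_map: DonorMap | None = None,
) -> tuple[WeightedBipartiteNetwork, WeightedBipartiteNetwork, list[VisitEstimate]]:
    """Full pipeline: events -> (filtered encounter network, visit network,
    visit estimates)."""
    freqs = weekly_encounter_frequency(encounters, flower_surveys)
    enc = encounter_strength(freqs, flower_surveys)
    estimates = estimate_visits(visit_samples, enc.links(), donor_map)
    visit, enc_filtered = visit_strength(enc, estimates)
    return enc_filtered, visit, estimates
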