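"""Species-level descriptors: dependences, species strength, push-pull
asymmetry, and d' specialization.

All three descriptors derive from the dependence matrix. The dependence of
plant i on pollinator j is d_ij = a_ij / A_i (the fraction of i's total
interaction strength contributed by j), and symmetrically d_ji = a_ij / A_j.

* species strength S_i: sum over partners of their dependence on the focal
  species — a quantitative measure of the species' importance for its
  partners.
* push-pull PP_i: mean, over the k_i partners, of (partner's dependence on i)
  minus (i's dependence on the partner); positive values mark "pushers" that
  affect their partners more strongly than the reverse, negative values
  "pullers".
* d': standardized Kullback-Leibler divergence between a species' partner-use
  distribution and partner availability (partners' marginal totals), 0 =
  minimum and 1 = maximum specialization.

Strengths here are real-valued (abundance-weighted), so d' is standardized in
its continuous form: the divergence is scaled by its upper bound ln(m / A_i)
with the continuous lower bound d_min = 0 (the integer-shuffling minimum of
the original index is undefined for real weights).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import WeightedBipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "dependence_matrices",
    "species_strength",
    "push_pull",
    "d_prime",
    "species_descriptors",
]

LEVELS = ("plant", "pollinator")


def _oriented(network: WeightedBipartiteNetwork, level: str):
    """Matrix with the focal level on rows, plus focal/partner labels."""
    if level == "plant":
        return network.values, list(network.plants), list(network.pollinators)
    if level == "pollinator":
        return network.values.T, list(network.pollinators), list(network.plants)
    raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


def dependence_matrices(
    network: WeightedBipartiteNetwork,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(plant-on-pollinator, pollinator-on-plant) dependence matrices.

    Both are indexed plants x pollinators; the first has rows summing to 1,
    the second columns summing to 1.
    """
    w = network.values
    d_plants = w / w.sum(axis=1, keepdims=True)
    d_polls = w / w.sum(axis=0, keepdims=True)
    idx = pd.Index(network.plants, name="plant")
    cols = pd.Index(network.pollinators, name="pollinator")
    return (
        pd.DataFrame(d_plants, index=idx, columns=cols),
        pd.DataFrame(d_polls, index=idx, columns=cols),
    )


def species_strength(network: WeightedBipartiteNetwork, level: str) -> pd.Series:
    """S_i = sum over partners j of a_ij / A_j (partners' dependence on i).

    Strengths over one level sum exactly to the number of species in the
    opposite level (each opposite-level species' dependences sum to 1).
    """
    w, focal, _ = _oriented(network, level)
    partner_totals = w.sum(axis=0)  # opposite-level marginals
    s = (w / partner_totals).sum(axis=1)
    return pd.Series(s, index=pd.Index(focal, name=level), name="strength")


def push_pull(
    network: WeightedBipartiteNetwork, level: str, aggregate: str = "mean"
) -> pd.Series:
    """Push-pull asymmetry index per species of `level`.

    PP_i = (1/k_i) * sum over partners j of (d_ji - d_ij), where d_ji is the
    partner's dependence on i and d_ij is i's dependence on the partner.
    Averaging over the k_i partners bounds the index in [-1, 1];
    ``aggregate="sum"`` gives the unnormalized summed form for sensitivity
    checks.
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    w, focal, _ = _oriented(network, level)
    d_focal = w / w.sum(axis=1, keepdims=True)  # i's dependence on partners
    d_partner = w / w.sum(axis=0, keepdims=True)  # partners' dependence on i
    diff = np.where(w > 0, d_partner - d_focal, 0.0).sum(axis=1)
    if aggregate == "mean":
        diff = diff / np.count_nonzero(w, axis=1)
    return pd.Series(diff, index=pd.Index(focal, name=level), name="push_pull")


def d_prime(network: WeightedBipartiteNetwork, level: str) -> pd.Series:
    """Standardized specialization d' in [0, 1] per species of `level`.

    With partner-use p'_ij = a_ij / A_i and availability q_j = A_j / m:
    raw divergence d_i = sum_j p'_ij ln(p'_ij / q_j) (zero-use terms
    contribute 0), upper bound d_max = ln(m / A_i) (all strength on the
    rarest achievable allocation), continuous lower bound d_min = 0
    (allocation proportional to availability), d' = d_i / d_max clamped to
    [0, 1]. Invariant to rescaling the whole matrix.
    """
    w, focal, _ = _oriented(network, level)
    m = w.sum()
    a_focal = w.sum(axis=1)
    q = w.sum(axis=0) / m
    p = w / a_focal[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    d_raw = terms.sum(axis=1)
    d_max = np.log(m / a_focal)
    out = np.zeros_like(d_raw)
    degenerate = d_max <= 0  # species holding the entire opposite level
    if degenerate.any():
        logger.info(
            "d': %d species with degenerate bounds (d_max = d_min); d' set to 0",
            int(degenerate.sum()),
        )
    np.divide(d_raw, d_max, out=out, where=~degenerate)
    return pd.Series(
        np.clip(out, 0.0, 1.0), index=pd.Index(focal, name=level), name="d_prime"
    )


def species_descriptors(
    network: WeightedBipartiteNetwork, push_pull_aggregate: str = "mean"
) -> pd.DataFrame:
    """Tidy per-species table: species, level, degree, strength, push_pull,
    d_prime (one row per species of both levels)."""
    frames = []
    for level in LEVELS:
        w, focal, _ = _oriented(network, level)
        frames.append(
            pd.DataFrame(
                {
                    "species": focal,
                    "level": level,
                    "degree": np.count_nonzero(w, axis=1),
                    "strength": species_strength(network, level).to_numpy(),
                    "push_pull": push_pull(
                        network, level, aggregate=push_pull_aggregate
                    ).to_numpy(),
                    "d_prime": d_prime(network, level).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
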