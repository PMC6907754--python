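"""Network-level descriptors: weighted nestedness (wNODF), H2'
specialization, interaction evenness, and generality per trophic level.

All four are computed on the normalized interaction-strength distribution
p_ij = a_ij / m and are therefore invariant to rescaling the whole matrix by
a positive constant.

Two descriptors have published dialects that differ between software
implementations; both are exposed behind keyword flags:

* wNODF pair eligibility — ``pair_rule="fill"`` (default) gates a row or
  column pair on strictly decreasing *binary fill* (number of nonzero cells),
  which is what the widely used R implementation (vegan's ``nestednodf``, the
  engine behind bipartite's wNODF) does; ``pair_rule="margin"`` gates on
  strictly decreasing marginal totals instead. Ties score 0 under either
  rule, so sort order never matters.
* interaction evenness denominator — ``denominator="all"`` (default) divides
  the Shannon entropy of p by ln(R*C) over all potential links;
  ``"realized"`` divides by ln(number of realized links).

H2' is standardized with continuous-marginal bounds, consistent with
real-valued strengths: the maximum-entropy allocation given the margins is
the independence outer product A_i * A_j / m, and the minimum-entropy
allocation is approximated by greedy concentration (repeatedly place
min(remaining row, remaining column) in the cell of the currently largest
remaining margins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError, WeightedBipartiteNetwork

__all__ = [
    "NetworkDescriptorSet",
    "weighted_nodf",
    "h2_prime",
    "interaction_evenness",
    "generality",
    "network_descriptors",
]


def _entropy(weights: np.ndarray) -> float:
    """Shannon entropy (nats) of weights normalized to a distribution."""
    p = weights[weights > 0] / weights.sum()
    return float(-(p * np.log(p)).sum())


def _nodf_line_scores(mat: np.ndarray, key: np.ndarray) -> float:
    """Sum of pair scores over lines (rows of `mat`), eligibility key strict.

    For an unordered line pair let u be the line with the strictly larger
    key; the pair scores |{c : a_vc > 0 and a_uc > a_vc}| / |{c : a_vc > 0}|,
    or 0 when the keys tie.
    """
    nz = mat > 0
    fill = nz.sum(axis=1)
    # ordered-pair tensor; only one orientation of each unordered pair is
    # eligible because eligibility is a strict inequality on the key
    greater = (mat[:, None, :] > mat[None, :, :]) & nz[None, :, :]
    counts = greater.sum(axis=2)
    eligible = key[:, None] > key[None, :]
    with np.errstate(invalid="ignore"):
        scores = np.where(eligible, counts / fill[None, :], 0.0)
    return float(scores.sum())


def weighted_nodf(
    network: WeightedBipartiteNetwork, pair_rule: str = "fill"
) -> float:
    """Weighted NODF nestedness in [0, 100].

    Mean over all row pairs and all column pairs of the decreasing-fill pair
    score (see module docstring for the two `pair_rule` dialects). Requires
    at least two lines on at least one axis.
    """
    if pair_rule not in ("fill", "margin"):
        raise ValueError("pair_rule must be 'fill' or 'margin'")
    w = network.values
    nr, nc = w.shape
    if nr < 2 and nc < 2:
        raise ValidationError("wNODF undefined for a single-cell network")
    total = 0.0
    for mat in (w, w.T):
        if mat.shape[0] < 2:
            continue
        key = (mat > 0).sum(axis=1) if pair_rule == "fill" else mat.sum(axis=1)
        total += _nodf_line_scores(mat, key)
    n_pairs = nr * (nr - 1) // 2 + nc * (nc - 1) // 2
    return 100.0 * total / n_pairs


def _greedy_min_entropy_allocation(row_tot: np.ndarray, col_tot: np.ndarray) -> np.ndarray:
    """Low-entropy allocation with the given margins by greedy concentration."""
    r = row_tot.astype(float).copy()
    c = col_tot.astype(float).copy()
    alloc = np.zeros((r.size, c.size))
    # each step exhausts a row or a column: at most R + C - 1 iterations
    tol = 1e-12 * max(r.sum(), 1.0)
    while r.sum() > tol and c.sum() > tol:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        amount = min(r[i], c[j])
        alloc[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return alloc


def h2_prime(network: WeightedBipartiteNetwork) -> float:
    """Network-level standardized specialization H2' in [0, 1].

    H2 is the Shannon entropy of p_ij = a_ij / m; H2max the entropy of the
    independence allocation A_i A_j / m (maximum entropy given the margins);
    H2min the entropy of the greedy concentration allocation.
    H2' = (H2max - H2) / (H2max - H2min), clamped to [0, 1]:
    0 = maximum generalization, 1 = maximum specialization.
    """
    w = network.values
    h2 = _entropy(w)
    h2max = _entropy(np.outer(network.plant_totals, network.pollinator_totals))
    h2min = _entropy(
        _greedy_min_entropy_allocation(network.plant_totals, network.pollinator_totals)
    )
    if h2max - h2min < 1e-12:
        raise ValidationError("degenerate marginals: H2max equals H2min")
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


def h2_bounds(network: WeightedBipartiteNetwork) -> tuple[float, float, float]:
    """(H2, H2min, H2max) in nats, before standardization."""
    w = network.values
    return (
        _entropy(w),
        _entropy(
            _greedy_min_entropy_allocation(
                network.plant_totals, network.pollinator_totals
            )
        ),
        _entropy(np.outer(network.plant_totals, network.pollinator_totals)),
    )


def interaction_evenness(
    network: WeightedBipartiteNetwork, denominator: str = "all"
) -> float:
    """Uniformity of interaction strengths in [0, 1].

    Shannon entropy of p_ij over realized links divided by ln(R*C) over all
    potential links (``denominator="all"``) or by ln(#links)
    (``denominator="realized"``).
    """
    if denominator not in ("all", "realized"):
        raise ValueError("denominator must be 'all' or 'realized'")
    nr, nc = network.values.shape
    if nr * nc == 1:
        raise ValidationError("interaction evenness undefined for a 1x1 network")
    h = _entropy(network.values)
    denom = np.log(nr * nc) if denominator == "all" else np.log(network.n_links)
    if denom <= 0:
        return 0.0  # single realized link under the "realized" dialect
    return float(h / denom)


def generality(network: WeightedBipartiteNetwork, level: str) -> float:
    """Weighted mean effective number of partners for one trophic level.

    Each species' effective partner number is exp(Shannon entropy) of its
    interaction distribution; species are weighted by their share A_i / m of
    total strength. "Plant generality" is the weighted mean number of
    pollinator partners per plant (a.k.a. vulnerability when plants are the
    resource level); lies in [1, size of the opposite level].
    """
    if level == "plant":
        w = network.values
    elif level == "pollinator":
        w = network.values.T
    else:
        raise ValueError(f"level must be 'plant' or 'pollinator', got {level!r}")
    totals = w.sum(axis=1)
    eff = np.array([np.exp(_entropy(row)) for row in w])
    return float((totals / totals.sum() * eff).sum())


@dataclass(frozen=True)
class NetworkDescriptorSet:
    """The five network descriptors for one strength measure."""

    wnodf: float
    h2_prime: float
    interaction_evenness: float
    plant_generality: float
    pollinator_generality: float
    measure: str

    def to_dict(self) -> dict[str, float]:
        return {
            "wnodf": self.wnodf,
            "h2_prime": self.h2_prime,
            "interaction_evenness": self.interaction_evenness,
            "plant_generality": self.plant_generality,
            "pollinator_generality": self.pollinator_generality,
        }

    NAMES = (
        "wnodf",
        "h2_prime",
        "interaction_evenness",
        "plant_generality",
        "pollinator_generality",
    )


def network_descriptors(
    network: WeightedBipartiteNetwork,
    pair_rule: str = "fill",
    evenness_denominator: str = "all",
) -> NetworkDescriptorSet:
    """All five descriptors of one network."""
    return NetworkDescriptorSet(
        wnodf=weighted_nodf(network, pair_rule=pair_rule),
        h2_prime=h2_prime(network),
        interaction_evenness=interaction_evenness(network, evenness_denominator),
        plant_generality=generality(network, "plant"),
        pollinator_generality=generality(network, "pollinator"),
        measure=network.measure,
    )
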