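"""Statistical comparison of encounter- and visit-based networks.

Three stages mirror the study design the pipeline supports:

1. A species-level regression of mean visits-per-encounter on floral display
   (both log-transformed): do plants with larger displays receive more
   flower visits per pollinator encounter?
2. Descriptor-versus-descriptor regressions (visit-based value on
   encounter-based value, per descriptor and trophic level, with the
   normalizing transforms stated below) and slope-vs-1 tests: a slope
   indistinguishable from 1 with high R^2 means the descriptor is robust to
   the strength measure. Companion regressions relate each plant's ratio of
   change (visit / encounter) to its floral display.
3. A bootstrap comparison: subsample the pool of encounter events, rebuild
   both networks through the full weekly-weighting pipeline, and compare the
   five network descriptors between measures with paired t-tests at several
   subsampling intensities.

Transforms follow the analysis conventions for these quantities: species
strengths are log-transformed on both axes, plant d' is arcsin(sqrt)
transformed on both axes, ratios of change of strength are log- and of d'
sqrt-transformed, and floral display is always log-transformed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    EncounterEvent,
    FlowerSurveyRecord,
    PlantTraits,
    ValidationError,
    VisitEstimate,
    WeightedBipartiteNetwork,
)
from .netmetrics import NetworkDescriptorSet, network_descriptors
from .strength import encounter_strength, visit_strength, weekly_encounter_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "BootstrapComparison",
    "fit_regression",
    "descriptor_change_analysis",
    "bootstrap_compare",
]

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda v: v,
    "log": np.log,
    "sqrt": np.sqrt,
    "arcsin_sqrt": lambda v: np.arcsin(np.sqrt(v)),
}


@dataclass(frozen=True)
class RegressionResult:
    """Simple-OLS summary, including a two-sided test of slope = 1."""

    slope: float
    slope_se: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r2: float
    r2_adj: float
    p_slope_vs_1: float
    n: int


def _apply_transform(values: np.ndarray, transform: str, label: str) -> np.ndarray:
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    v = np.asarray(values, dtype=float)
    if transform == "log" and np.any(v <= 0):
        bad = np.flatnonzero(v <= 0)
        raise ValidationError(
            f"log transform of nonpositive {label} value(s) at position(s) "
            f"{bad.tolist()}"
        )
    if transform in ("sqrt", "arcsin_sqrt") and np.any(v < 0):
        raise ValidationError(f"{transform} transform of negative {label} values")
    if transform == "arcsin_sqrt" and np.any(v > 1):
        raise ValidationError(f"arcsin_sqrt requires {label} values in [0, 1]")
    return _TRANSFORMS[transform](v)


def fit_regression(
    x: Sequence[float],
    y: Sequence[float],
    transform_x: str = "identity",
    transform_y: str = "identity",
) -> RegressionResult:
    """OLS of transform_y(y) on transform_x(x) with a slope-vs-1 test.

    Requires n >= 3 finite pairs after transformation. When the fit is exact
    (zero residual variance) the slope-vs-1 p-value degenerates to 1.0 for
    slope exactly 1 and 0.0 otherwise.
    """
    xt = _apply_transform(np.asarray(x, float), transform_x, "predictor")
    yt = _apply_transform(np.asarray(y, float), transform_y, "response")
    keep = np.isfinite(xt) & np.isfinite(yt)
    xt, yt = xt[keep], yt[keep]
    n = xt.size
    if n < 3:
        raise ValidationError(f"need >= 3 finite pairs after transformation, got {n}")
    fit = sm.OLS(yt, sm.add_constant(xt)).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    # an exact fit has zero slope SE up to float noise; the t-test degenerates
    exact = se <= 1e-10 * max(abs(slope), 1.0) or not np.isfinite(se)
    if exact:
        p_vs_1 = 1.0 if np.isclose(slope, 1.0) else 0.0
    else:
        t1 = (slope - 1.0) / se
        p_vs_1 = float(2 * stats.t.sf(abs(t1), n - 2))
    return RegressionResult(
        slope=slope,
        slope_se=se,
        intercept=float(fit.params[0]),
        f_stat=float(fit.fvalue),
        df=(1, n - 2),
        p_value=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        p_slope_vs_1=p_vs_1,
        n=n,
    )


# descriptor -> (transform applied to both axes in the visit-vs-encounter
# regression, transform of the change ratio in the ratio-vs-display
# regression); plant d' gets the arcsin(sqrt)/sqrt pair, strengths log/log
_DESCRIPTOR_TRANSFORMS: dict[tuple[str, str], tuple[str, str]] = {
    ("strength", "plant"): ("log", "log"),
    ("strength", "pollinator"): ("log", "log"),
    ("push_pull", "plant"): ("identity", "identity"),
    ("push_pull", "pollinator"): ("identity", "identity"),
    ("d_prime", "plant"): ("arcsin_sqrt", "sqrt"),
    ("d_prime", "pollinator"): ("identity", "sqrt"),
}


def descriptor_change_analysis(
    encounter_descriptors: pd.DataFrame,
    visit_descriptors: pd.DataFrame,
    traits: Sequence[PlantTraits] | Mapping[str, float],
) -> pd.DataFrame:
    """Descriptor robustness regressions between the two strength measures.

    Inputs are the tidy per-species tables from
    :func:`pollinet.species.species_descriptors` for the encounter- and
    visit-based networks (matched species sets), plus plant floral displays.

    Returns one row per fitted regression with columns ``analysis``
    ("measure_comparison" or "ratio_vs_display"), ``descriptor``, ``level``,
    the transforms used, and the :class:`RegressionResult` fields.
    Species whose encounter-based value is zero cannot form a change ratio
    and are dropped from ratio regressions with a logged warning.
    """
    if isinstance(traits, Mapping):
        display = dict(traits)
    else:
        display = {t.plant: t.floral_display for t in traits}

    merged = encounter_descriptors.merge(
        visit_descriptors,
        on=["species", "level"],
        suffixes=("_enc", "_vis"),
        how="inner",
    )
    rows: list[dict] = []
    for (descriptor, level), (tf_pair, tf_ratio) in _DESCRIPTOR_TRANSFORMS.items():
        sub = merged[merged["level"] == level]
        if len(sub) < 3:
            continue
        res = fit_regression(
            sub[f"{descriptor}_enc"],
            sub[f"{descriptor}_vis"],
            transform_x=tf_pair,
            transform_y=tf_pair,
        )
        rows.append(
            {
                "analysis": "measure_comparison",
                "descriptor": descriptor,
                "level": level,
                "transform_x": tf_pair,
                "transform_y": tf_pair,
                **res.__dict__,
            }
        )
        if level != "plant":
            continue
        # ratio-of-change vs floral display, plants only
        sub = sub[sub["species"].isin(display)]
        enc_vals = sub[f"{descriptor}_enc"].to_numpy(float)
        zero = enc_vals == 0
        if zero.any():
            logger.warning(
                "ratio of change of %s: dropping plant(s) with zero "
                "encounter-based value: %s",
                descriptor,
                sub.loc[zero, "species"].tolist(),
            )
            sub = sub[~zero]
        if len(sub) < 3:
            continue
        ratio = sub[f"{descriptor}_vis"].to_numpy(float) / sub[
            f"{descriptor}_enc"
        ].to_numpy(float)
        disp = sub["species"].map(display).to_numpy(float)
        try:
            res = fit_regression(disp, ratio, transform_x="log", transform_y=tf_ratio)
        except ValidationError as exc:
            logger.warning(
                "ratio regression for %s skipped: %s", descriptor, exc
            )
            continue
        rows.append(
            {
                "analysis": "ratio_vs_display",
                "descriptor": descriptor,
                "level": level,
                "transform_x": "log",
                "transform_y": tf_ratio,
                **res.__dict__,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapComparison:
    """Paired encounter/visit summary for one descriptor at one intensity."""

    descriptor: str
    fraction: float
    encounter_mean: float
    encounter_sd: float
    visit_mean: float
    visit_sd: float
    paired_t: float
    p_value: float
    n_reps: int


def _mean_sd(vals: np.ndarray) -> tuple[float, float]:
    # constant series stay exact (np.mean can drift by an ulp on n identical
    # values, which would break the fraction-1.0 degeneracy contract)
    if np.all(vals == vals[0]):
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))


def _paired_t(enc: np.ndarray, vis: np.ndarray) -> tuple[float, float]:
    diff = enc - vis
    if np.allclose(diff.std(ddof=1), 0.0):
        # degenerate pairs (e.g. fraction 1.0): identical differences
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, float(diff[0])), 0.0
    t, p = stats.ttest_rel(enc, vis)
    return float(t), float(p)


def bootstrap_compare(
    encounters: Sequence[EncounterEvent],
    flower_surveys: Sequence[FlowerSurveyRecord],
    visit_estimates: Sequence[VisitEstimate],
    fractions: Iterable[float] = (0.25, 0.5, 0.75),
    n_reps: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    replace: bool = False,
    reweight_weekly: bool = True,
    pair_rule: str = "fill",
    evenness_denominator: str = "all",
    max_redraws: int = 1000,
) -> list[BootstrapComparison]:
    """Subsample encounter events and compare descriptors between measures.

    Per replicate, floor(fraction * N) events are drawn from the pool of
    observed encounters (without replacement by default — a subsample, not a
    resample; ``replace=True`` switches to bootstrap resampling). Sampled
    events keep their week labels, the encounter network is rebuilt through
    the full weekly-weighting pipeline against the complete flower-survey
    table (``reweight_weekly=False`` builds it from raw counts instead), the
    visit multipliers are applied, and the five network descriptors are
    computed on both networks. Across replicates, means, SDs and two-sided
    paired t-tests are reported per descriptor and fraction.

    Replicates in which either trophic level collapses below 2 species are
    redrawn (counted and logged). Identical seed and inputs give
    bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    events = list(encounters)
    n_events = len(events)
    if n_events == 0:
        raise ValidationError("no encounter events to subsample")

    out: list[BootstrapComparison] = []
    for fraction in fractions:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        k = int(np.floor(fraction * n_events))
        enc_vals = {name: np.empty(n_reps) for name in NetworkDescriptorSet.NAMES}
        vis_vals = {name: np.empty(n_reps) for name in NetworkDescriptorSet.NAMES}
        redraws = 0
        for rep in range(n_reps):
            while True:
                idx = rng.choice(n_events, size=k, replace=replace)
                sample = [events[i] for i in idx]
                try:
                    d_enc, d_vis = _replicate_descriptors(
                        sample,
                        flower_surveys,
                        visit_estimates,
                        reweight_weekly,
                        pair_rule,
                        evenness_denominator,
                    )
                except _CollapsedReplicate:
                    redraws += 1
                    if redraws > max_redraws:
                        raise ValidationError(
                            f"exceeded {max_redraws} redraws at fraction {fraction}; "
                            "community too small for this subsampling intensity"
                        )
                    continue
                break
            for name in NetworkDescriptorSet.NAMES:
                enc_vals[name][rep] = getattr(d_enc, name)
                vis_vals[name][rep] = getattr(d_vis, name)
        if redraws:
            logger.info("fraction %.2f: %d collapsed replicate(s) redrawn", fraction, redraws)
        for name in NetworkDescriptorSet.NAMES:
            t, p = _paired_t(enc_vals[name], vis_vals[name])
            e_mean, e_sd = _mean_sd(enc_vals[name])
            v_mean, v_sd = _mean_sd(vis_vals[name])
            out.append(
                BootstrapComparison(
                    descriptor=name,
                    fraction=float(fraction),
                    encounter_mean=e_mean,
                    encounter_sd=e_sd,
                    visit_mean=v_mean,
                    visit_sd=v_sd,
                    paired_t=t,
                    p_value=p,
                    n_reps=n_reps,
                )
            )
    return out


class _CollapsedReplicate(Exception):
    pass


def _replicate_descriptors(
    sample: Sequence[EncounterEvent],
    flower_surveys: Sequence[FlowerSurveyRecord],
    visit_estimates: Sequence[VisitEstimate],
    reweight_weekly: bool,
    pair_rule: str,
    evenness_denominator: str,
) -> tuple[NetworkDescriptorSet, NetworkDescriptorSet]:
    excluded = {(e.plant, e.pollinator) for e in visit_estimates if e.excluded}
    sample = [s for s in sample if (s.plant, s.pollinator) not in excluded]
    if not sample:
        raise _CollapsedReplicate
    if reweight_weekly:
        freqs = weekly_encounter_frequency(sample, flower_surveys)
        enc = encounter_strength(freqs, flower_surveys)
    else:
        from collections import Counter

        counts = Counter((s.plant, s.pollinator) for s in sample)
        enc = WeightedBipartiteNetwork.from_cells(
            {k: float(v) for k, v in counts.items()}, measure="encounter"
        )
    if len(enc.plants) < 2 or len(enc.pollinators) < 2:
        raise _CollapsedReplicate
    vis, enc = visit_strength(enc, visit_estimates)
    if min(len(n.plants) for n in (enc, vis)) < 2 or min(
        len(n.pollinators) for n in (enc, vis)
    ) < 2:
        raise _CollapsedReplicate
    return (
        network_descriptors(enc, pair_rule, evenness_denominator),
        network_descriptors(vis, pair_rule, evenness_denominator),
    )
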