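"""Regression machinery, descriptor-change analysis, and the bootstrap
comparison engine."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import pollinet as pn
from pollinet.core import ValidationError
from pollinet.netmetrics import NetworkDescriptorSet
from oracles import ols_oracle


class TestFitRegression:
    def test_matches_closed_form_on_three_points(self):
        x, y = [1.0, 2.0, 4.0], [2.0, 3.0, 7.0]
        res = pn.fit_regression(x, y)
        slope, intercept, se, f, r2 = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.slope_se == pytest.approx(se)
        assert res.f_stat == pytest.approx(f)
        assert res.r2 == pytest.approx(r2)
        assert res.df == (1, 1)

    def test_exact_identity_line(self):
        res = pn.fit_regression([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_slope_vs_1 == 1.0

    def test_exact_non_unit_slope(self):
        res = pn.fit_regression([1, 2, 3], [2, 4, 6])
        assert res.slope == pytest.approx(2.0)
        assert res.p_slope_vs_1 == 0.0

    def test_recovers_known_slope_within_3_se(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, 40)
        y = 2.0 * x + rng.normal(0, 0.01, 40)
        res = pn.fit_regression(x, y)
        assert abs(res.slope - 2.0) < 3 * res.slope_se

    def test_log_of_nonpositive_is_an_error(self):
        with pytest.raises(ValidationError, match="log"):
            pn.fit_regression([1, 2, 0], [1, 2, 3], transform_x="log")

    def test_arcsin_sqrt_range_check(self):
        with pytest.raises(ValidationError, match="arcsin_sqrt"):
            pn.fit_regression([0.1, 0.5, 1.4], [1, 2, 3], transform_x="arcsin_sqrt")

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError, match=">= 3"):
            pn.fit_regression([1, 2], [1, 2])

    def test_slope_vs_one_test_consistency(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 30)
        y = x + rng.normal(0, 0.05, 30)
        res = pn.fit_regression(x, y)
        t = (res.slope - 1) / res.slope_se
        from scipy import stats

        assert res.p_slope_vs_1 == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2))


class TestDescriptorChangeAnalysis:
    def test_identical_networks_give_unit_slopes_and_unit_ratios(self, small_networks):
        enc, _, _ = small_networks
        desc = pn.species_descriptors(enc)
        traits = {p: 10.0 * (i + 1) for i, p in enumerate(enc.plants)}
        table = pn.descriptor_change_analysis(desc, desc.copy(), traits)
        comp = table[table["analysis"] == "measure_comparison"]
        assert len(comp) == 6  # 3 descriptors x 2 levels
        assert np.allclose(comp["slope"], 1.0)
        assert np.allclose(comp["r2"], 1.0)
        ratio = table[table["analysis"] == "ratio_vs_display"]
        # visit/encounter ratios are identically 1 -> flat regressions
        assert np.allclose(ratio["slope"], 0.0, atol=1e-12)

    def test_full_pipeline_produces_all_regressions(self, small_networks, small_scenario):
        enc, vis, _ = small_networks
        table = pn.descriptor_change_analysis(
            pn.species_descriptors(enc),
            pn.species_descriptors(vis),
            list(small_scenario.community.traits),
        )
        assert set(table["analysis"]) == {"measure_comparison", "ratio_vs_display"}
        comp = table[table["analysis"] == "measure_comparison"]
        assert set(zip(comp["descriptor"], comp["level"])) == {
            ("strength", "plant"), ("strength", "pollinator"),
            ("push_pull", "plant"), ("push_pull", "pollinator"),
            ("d_prime", "plant"), ("d_prime", "pollinator"),
        }
        # stated transforms: strength log-log, plant d' arcsin(sqrt)
        by = {(r.descriptor, r.level): r for r in comp.itertuples()}
        assert by[("strength", "plant")].transform_x == "log"
        assert by[("d_prime", "plant")].transform_x == "arcsin_sqrt"
        assert by[("d_prime", "pollinator")].transform_x == "identity"


def _tiny_event_world():
    """A small deterministic event world for bootstrap behavior tests."""
    rng = np.random.default_rng(0)
    plants = [f"p{i}" for i in range(4)]
    polls = [f"z{j}" for j in range(6)]
    encounters, surveys = [], []
    for week in (1, 2, 3):
        for i, p in enumerate(plants):
            surveys.append(pn.FlowerSurveyRecord(week, p, 20 + 5 * i, 4.0 + i))
            for j, z in enumerate(polls):
                n = rng.poisson(2.0 if (i + j) % 2 else 0.7)
                encounters.extend([pn.EncounterEvent(week, p, z)] * n)
    pairs = {(e.plant, e.pollinator) for e in encounters}
    estimates = [
        pn.VisitEstimate(p, z, 1.0 + idx % 5, 6, "observed")
        for idx, (p, z) in enumerate(sorted(pairs))
    ]
    return encounters, surveys, estimates


class TestBootstrapCompare:
    def test_fraction_one_degenerates_to_original_descriptors(self):
        encounters, surveys, estimates = _tiny_event_world()
        freqs = pn.weekly_encounter_frequency(encounters, surveys)
        enc = pn.encounter_strength(freqs, surveys)
        vis, enc_f = pn.visit_strength(enc, estimates)
        orig_enc = pn.network_descriptors(enc_f)
        orig_vis = pn.network_descriptors(vis)
        out = pn.bootstrap_compare(
            encounters, surveys, estimates, fractions=[1.0], n_reps=5, seed=1
        )
        for b in out:
            assert b.encounter_mean == getattr(orig_enc, b.descriptor)
            assert b.visit_mean == getattr(orig_vis, b.descriptor)
            assert b.encounter_sd == 0.0 and b.visit_sd == 0.0

    def test_identical_seed_gives_bit_identical_output(self):
        encounters, surveys, estimates = _tiny_event_world()
        kw = dict(fractions=[0.5], n_reps=12, seed=7)
        a = pn.bootstrap_compare(encounters, surveys, estimates, **kw)
        b = pn.bootstrap_compare(encounters, surveys, estimates, **kw)
        assert [dataclasses.asdict(x) for x in a] == [dataclasses.asdict(y) for y in b]

    def test_independent_seeds_agree_within_3_sd(self):
        encounters, surveys, estimates = _tiny_event_world()
        a = pn.bootstrap_compare(encounters, surveys, estimates, [0.5], 40, seed=1)
        b = pn.bootstrap_compare(encounters, surveys, estimates, [0.5], 40, seed=2)
        for x, y in zip(a, b):
            assert x.encounter_sd > 0
            spread = 3 * max(x.encounter_sd, y.encounter_sd)
            assert abs(x.encounter_mean - y.encounter_mean) <= spread

    def test_means_approach_original_with_subsample_size(self):
        encounters, surveys, estimates = _tiny_event_world()
        freqs = pn.weekly_encounter_frequency(encounters, surveys)
        enc = pn.encounter_strength(freqs, surveys)
        vis, enc_f = pn.visit_strength(enc, estimates)
        orig = pn.network_descriptors(enc_f)
        out = pn.bootstrap_compare(
            encounters, surveys, estimates, fractions=[0.25, 0.75], n_reps=60, seed=3
        )
        by = {(b.descriptor, b.fraction): b for b in out}
        # size-sensitive descriptors drift toward the full-network value
        for name in ("wnodf", "plant_generality", "pollinator_generality"):
            d25 = abs(by[(name, 0.25)].encounter_mean - getattr(orig, name))
            d75 = abs(by[(name, 0.75)].encounter_mean - getattr(orig, name))
            assert d75 <= d25 + 1e-9

    def test_excluded_interactions_never_enter_replicates(self):
        encounters, surveys, estimates = _tiny_event_world()
        # mark the most frequent pair as excluded
        from collections import Counter

        top = Counter((e.plant, e.pollinator) for e in encounters).most_common(1)[0][0]
        estimates = [
            pn.VisitEstimate(e.plant, e.pollinator, None, 0, "excluded")
            if (e.plant, e.pollinator) == top
            else e
            for e in estimates
        ]
        out = pn.bootstrap_compare(
            encounters, surveys, estimates, fractions=[1.0], n_reps=2, seed=0
        )
        freqs = pn.weekly_encounter_frequency(encounters, surveys)
        enc = pn.encounter_strength(freqs, surveys)
        vis, enc_f = pn.visit_strength(enc, estimates)
        expected = pn.network_descriptors(enc_f)
        by = {b.descriptor: b for b in out}
        for name in NetworkDescriptorSet.NAMES:
            assert by[name].encounter_mean == getattr(expected, name)

    def test_invalid_fraction_rejected(self):
        encounters, surveys, estimates = _tiny_event_world()
        with pytest.raises(ValueError):
            pn.bootstrap_compare(encounters, surveys, estimates, fractions=[0.0])
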