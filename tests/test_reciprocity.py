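"""Inaccuracy statistic: oracles, identities, combinations, bootstrap."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reciprostat.config import PopulationConfig
from reciprostat.reciprocity import (OrganSummary, bootstrap_inaccuracy,
                                     enumerate_combinations,
                                     inaccuracy_component,
                                     inaccuracy_for_combination,
                                     population_inaccuracy, summarize_organs,
                                     ReciprocityAnalysis)
from reciprostat.synth import generate_dataset
from tests.conftest import CELLS


def _summary(area, morph, organ, mean, var, n=5):
    return OrganSummary(area=area, morph=morph, organ=organ,
                        mean=mean, variance=var, n=n)


def heights_table(per_group):
    """Tidy table with explicit stigma/anther heights per (area, morph)."""
    rows = []
    for (area, morph), organs in per_group.items():
        for organ_trait, values in organs.items():
            for j, v in enumerate(values):
                rows.append({"area": area, "morph": morph,
                             "individual_id": f"{area}-{morph}-i{j}",
                             "unit_id": f"{area}-{morph}-u{j}",
                             "trait": organ_trait, "value": float(v)})
    return pd.DataFrame(rows)


def full_heights_table(overrides=None):
    base = {"stigma_height": [10.0, 10.5, 9.5], "anther_height": [10.2, 9.8, 10.0]}
    per_group = {cell: dict(base) for cell in CELLS}
    per_group.update(overrides or {})
    return heights_table(per_group)


class TestSummarizeOrgans:
    def test_constant_sample(self):
        tab = full_heights_table()
        tab.loc[(tab["morph"] == "L") & (tab["area"] == "no_fire")
                & (tab["trait"] == "stigma_height"), "value"] = 10.0
        s = summarize_organs(tab)
        assert s[("no_fire", "L", "stigma")].mean == 10.0
        assert s[("no_fire", "L", "stigma")].variance == 0.0

    def test_hand_arithmetic_three_values(self):
        tab = full_heights_table(
            {("no_fire", "L"): {"stigma_height": [16.2, 16.6, 16.4],
                                "anther_height": [10.0, 10.1, 9.9]}})
        s = summarize_organs(tab)
        got = s[("no_fire", "L", "stigma")]
        assert got.mean == pytest.approx(16.4)
        # ((−0.2)² + 0.2² + 0²) / 2
        assert got.variance == pytest.approx(0.04)
        assert got.level == "high"

    def test_missing_organ_errors_with_group_name(self):
        tab = full_heights_table()
        tab = tab[~((tab["area"] == "fire") & (tab["morph"] == "S")
                    & (tab["trait"] == "anther_height"))]
        with pytest.raises(ValueError, match=r"\(fire, S\)"):
            summarize_organs(tab)

    def test_single_flower_group_rejected(self):
        tab = full_heights_table()
        keep = ~((tab["area"] == "fire") & (tab["morph"] == "L")
                 & (tab["trait"] == "stigma_height") & (tab["unit_id"] != "fire-L-u0"))
        with pytest.raises(ValueError, match="at least 2"):
            summarize_organs(tab[keep])


class TestInaccuracyComponent:
    def test_perfect_reciprocity_is_zero(self):
        a = _summary("no_fire", "S", "anther", 10.0, 0.0)
        s = _summary("no_fire", "L", "stigma", 10.0, 0.0)
        assert inaccuracy_component(a, s) == (0.0, 0.0, 0.0)

    def test_formula_decomposition(self):
        a = _summary("no_fire", "S", "anther", 12.0, 0.5)
        s = _summary("no_fire", "L", "stigma", 10.0, 0.3)
        bias, imprec, inacc = inaccuracy_component(a, s)
        assert bias == pytest.approx(4.0)
        assert imprec == pytest.approx(0.8)
        assert inacc == pytest.approx(4.8)

    def test_five_value_toy_samples_match_direct_arithmetic(self):
        """Exact agreement with literal sums computed term by term."""
        anther_vals = [10.1, 10.3, 9.9, 10.0, 10.2]
        stigma_vals = [10.4, 10.0, 10.2, 10.6, 9.8]
        # oracle: direct arithmetic, independent of the implementation
        am = sum(anther_vals) / 5
        sm = sum(stigma_vals) / 5
        av = sum((v - am) ** 2 for v in anther_vals) / 4
        sv = sum((v - sm) ** 2 for v in stigma_vals) / 4
        exp_bias = (am - sm) ** 2
        exp_imprec = av + sv

        tab = full_heights_table(
            {("no_fire", "S"): {"stigma_height": [9.0] * 5,
                                "anther_height": anther_vals},
             ("no_fire", "L"): {"stigma_height": stigma_vals,
                                "anther_height": [9.0] * 5}})
        s = summarize_organs(tab)
        bias, imprec, inacc = inaccuracy_component(
            s[("no_fire", "S", "anther")], s[("no_fire", "L", "stigma")])
        assert bias == pytest.approx(exp_bias, abs=1e-12)
        assert imprec == pytest.approx(exp_imprec, abs=1e-12)
        assert inacc == pytest.approx(exp_bias + exp_imprec, abs=1e-12)

    def test_illegitimate_pairing_rejected(self):
        high_anther = _summary("no_fire", "S", "anther", 16.0, 0.1)
        low_stigma = _summary("no_fire", "S", "stigma", 10.0, 0.1)
        with pytest.raises(ValueError, match="illegitimate"):
            inaccuracy_component(high_anther, low_stigma)

    def test_symmetric_in_organs(self):
        a = _summary("fire", "L", "anther", 10.7, 0.2)
        s = _summary("fire", "S", "stigma", 10.1, 0.4)
        b1 = inaccuracy_component(a, s)
        # swapping the roles of means/variances leaves the formula unchanged
        a2 = _summary("fire", "L", "anther", 10.1, 0.4)
        s2 = _summary("fire", "S", "stigma", 10.7, 0.2)
        assert inaccuracy_component(a2, s2) == pytest.approx(b1)


class TestCombinations:
    def test_four_combinations_each_group_once_per_level(self):
        combos = enumerate_combinations()
        assert len(combos) == 4
        high_usage, low_usage = [], []
        for c in combos:
            s = c.slots()
            high_usage += [s["high_anther"], s["high_stigma"]]
            low_usage += [s["low_anther"], s["low_stigma"]]
        for cell in CELLS:
            assert high_usage.count(cell) == 2  # once as combo member per side
            assert low_usage.count(cell) == 2

    def test_cross_area_slot_assignment(self):
        """no-fire L x fire S: high anther from fire S, high stigma from
        no-fire L, low anther from no-fire L, low stigma from fire S."""
        combo = {c.label: c for c in enumerate_combinations()}["no_fire_L x fire_S"]
        assert combo.high_anther == ("fire", "S")
        assert combo.high_stigma == ("no_fire", "L")
        assert combo.low_anther == ("no_fire", "L")
        assert combo.low_stigma == ("fire", "S")

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="four"):
            enumerate_combinations([("no_fire", "L"), ("no_fire", "S"),
                                    ("fire", "L")])

    def test_morph_roles_respect_levels(self):
        for c in enumerate_combinations():
            assert c.high_anther[1] == "S" and c.high_stigma[1] == "L"
            assert c.low_anther[1] == "L" and c.low_stigma[1] == "S"


class TestInaccuracyForCombination:
    def test_all_equal_means_zero_variance(self):
        summaries = {(a, m, o): _summary(a, m, o, 10.0, 0.0)
                     for a, m in CELLS for o in ("stigma", "anther")}
        for combo in enumerate_combinations():
            r = inaccuracy_for_combination(summaries, combo)
            assert r.total_inaccuracy == 0.0

    def test_symmetric_areas_give_identical_combinations(self):
        """If fire changes nothing, all four pairings yield the same values."""
        vals = {("stigma", "L"): (16.4, 0.9), ("stigma", "S"): (10.4, 0.7),
                ("anther", "L"): (10.8, 0.6), ("anther", "S"): (16.5, 1.0)}
        summaries = {(a, m, o): _summary(a, m, o, *vals[(o, m)])
                     for a, m in CELLS for o in ("stigma", "anther")}
        results = [inaccuracy_for_combination(summaries, c)
                   for c in enumerate_combinations()]
        first = results[0]
        for r in results[1:]:
            assert r.total_inaccuracy == pytest.approx(first.total_inaccuracy)
            assert r.inaccuracy_high == pytest.approx(first.inaccuracy_high)
            assert r.inaccuracy_low == pytest.approx(first.inaccuracy_low)

    def test_population_value_from_config_formulas(self):
        """Plugging configured means/variances into the formulas directly."""
        cfg = PopulationConfig()
        combo = enumerate_combinations()[0]
        r = population_inaccuracy(cfg, combo)
        sd = cfg.flower_trait_sds
        var_tot = {t: sd[t] ** 2 + cfg.individual_sd ** 2
                   for t in ("stigma_height", "anther_height")}
        exp_bias_high = (16.51 - 16.46) ** 2
        exp_imprec = var_tot["anther_height"] + var_tot["stigma_height"]
        assert r.maladaptive_bias_high == pytest.approx(exp_bias_high)
        assert r.imprecision_high == pytest.approx(exp_imprec)
        assert r.total_inaccuracy == pytest.approx(
            exp_bias_high + (10.83 - 10.42) ** 2 + 2 * exp_imprec)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(st.lists(st.tuples(st.floats(5.0, 25.0), st.floats(0.0, 4.0)),
                min_size=4, max_size=4))
def test_decomposition_identities_hold_for_random_summaries(quad):
    """bias + imprecision == inaccuracy; high + low == total; all >= 0."""
    (ham, hav), (hsm, hsv), (lam, lav), (lsm, lsv) = quad
    summaries = {
        ("no_fire", "S", "anther"): _summary("no_fire", "S", "anther", ham, hav),
        ("no_fire", "L", "stigma"): _summary("no_fire", "L", "stigma", hsm, hsv),
        ("no_fire", "L", "anther"): _summary("no_fire", "L", "anther", lam, lav),
        ("no_fire", "S", "stigma"): _summary("no_fire", "S", "stigma", lsm, lsv),
    }
    combo = enumerate_combinations()[0]
    r = inaccuracy_for_combination(summaries, combo)
    assert r.inaccuracy_high == r.maladaptive_bias_high + r.imprecision_high
    assert r.inaccuracy_low == r.maladaptive_bias_low + r.imprecision_low
    assert r.total_inaccuracy == r.inaccuracy_high + r.inaccuracy_low
    for v in r.as_dict().values():
        if isinstance(v, float):
            assert v >= 0.0
    assert r.maladaptive_bias_high <= r.inaccuracy_high
    assert r.imprecision_high <= r.inaccuracy_high


class TestBootstrap:
    def test_degenerate_data_degenerate_ci(self):
        tab = full_heights_table(
            {cell: {"stigma_height": [10.0] * 4, "anther_height": [10.0] * 4}
             for cell in CELLS})
        ci = bootstrap_inaccuracy(tab, enumerate_combinations()[0], B=200, seed=0)
        assert (ci["ci_lower"] == ci["estimate"]).all()
        assert (ci["ci_upper"] == ci["estimate"]).all()

    def test_deterministic_given_seed(self, default_table):
        combo = enumerate_combinations()[1]
        a = bootstrap_inaccuracy(default_table, combo, B=150, seed=11)
        b = bootstrap_inaccuracy(default_table, combo, B=150, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_small_B_rejected(self, default_table):
        with pytest.raises(ValueError, match="B"):
            bootstrap_inaccuracy(default_table, enumerate_combinations()[0], B=50)

    def test_cluster_bootstrap_widens_or_matches(self, default_table):
        combo = enumerate_combinations()[0]
        flower = bootstrap_inaccuracy(default_table, combo, B=300, seed=1)
        cluster = bootstrap_inaccuracy(default_table, combo, B=300, seed=1,
                                       cluster_by_individual=True)
        assert set(cluster["component"]) == set(flower["component"])

    def test_coverage_of_population_value(self):
        """Percentile CIs cover the generating-config truth at close to the
        nominal rate (mild undercoverage is expected for variance-dominated
        statistics at n=200 flowers/group)."""
        combo = enumerate_combinations()[0]
        cfg0 = PopulationConfig(n_flower_individuals=25, flowers_per_individual=8)
        pop = population_inaccuracy(cfg0, combo).total_inaccuracy
        covered = 0
        reps = 60
        for r in range(reps):
            cfg = dataclasses.replace(cfg0, seed=1000 + r)
            tab = generate_dataset(cfg)
            ci = bootstrap_inaccuracy(tab, combo, B=600, seed=r)
            row = ci[ci["component"] == "total_inaccuracy"].iloc[0]
            covered += int(row["ci_lower"] <= pop <= row["ci_upper"])
        assert covered / reps >= 0.85


class TestReciprocityEstimator:
    def test_fit_produces_tables_and_params_roundtrip(self, default_table):
        est = ReciprocityAnalysis(bootstrap_B=150, seed=2, standardize=True)
        assert est.get_params()["bootstrap_B"] == 150
        est.fit(default_table)
        assert len(est.results_) == 4
        assert len(est.table_) == 8  # raw + standardized rows
        assert set(est.ci_) == {c.label for c in enumerate_combinations()}
        out = est.transform()
        assert "total_inaccuracy" in out.columns

    def test_unfitted_transform_errors(self, default_table):
        with pytest.raises(RuntimeError):
            ReciprocityAnalysis().transform(default_table)
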