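"""Univariate tests, mixed-model backward selection, type-I calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrmeat.panel import MetaboliteModel, default_panel
from nmrmeat.screening import (
    friedman,
    kruskal_wallis_posthoc,
    mixed_model_screen,
    normality_gate,
    spearman,
)
from nmrmeat.simdesign import generate_design, simulate_concentrations


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self, rng):
        x = np.array([1, 2, 2, 3, 4, 4, 4, 5, 6, 7.0])
        y = rng.normal(size=10)
        r, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged(self):
        r, p = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)


class TestFriedman:
    def test_identical_columns_zero_statistic(self):
        t = np.tile([[1.0], [2.0], [3.0]], (1, 4))
        stat, p = friedman(t)
        assert stat == 0.0
        assert p == 1.0

    def test_hand_computed_three_by_three(self):
        # per-row ranks: [1,2,3], [1,2,3], [2,1,3]; rank sums R = [4,5,9]
        # chi2 = 12/(n k (k+1)) sum R^2 - 3 n (k+1) = (12/36)*122 - 36
        t = np.array([[1.0, 2, 3], [10, 20, 30], [5, 4, 6]])
        stat, p = friedman(t)
        assert stat == pytest.approx(12 / 36 * 122 - 36, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(stat, 2), abs=1e-12)

    def test_monotone_effect_power(self, rng):
        base = rng.normal(size=(30, 1))
        t = base + np.array([[0.0, 1.0, 2.0]]) + 0.3 * rng.normal(size=(30, 3))
        _, p = friedman(t)
        assert p < 1e-3

    def test_missing_cells_rejected(self):
        t = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            friedman(t)


class TestKruskalWallis:
    def test_identical_groups_nonsignificant(self):
        vals = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        h, p, table = kruskal_wallis_posthoc(vals, labels)
        assert p > 0.9
        assert not table.significant.any()

    def test_one_shifted_group_drives_pairs(self, rng):
        groups = {g: rng.normal(size=12) for g in "abcde"}
        groups["e"] = groups["e"] + 30.0
        vals = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 12)
        h, p, table = kruskal_wallis_posthoc(vals, labels)
        assert p < 1e-4
        sig = table[table.significant]
        assert len(sig) > 0
        assert sig.apply(lambda r: "e" in (r.group_a, r.group_b), axis=1).all()

    def test_bonferroni_definition_and_monotonicity(self, rng):
        vals = rng.normal(size=40)
        labels = np.repeat(list("abcd"), 10)
        _, _, table = kruskal_wallis_posthoc(vals, labels)
        n_pairs = len(table)
        assert np.allclose(
            table.p_bonferroni, np.minimum(table.p_raw * n_pairs, 1.0), atol=1e-12
        )
        assert (table.p_bonferroni >= table.p_raw - 1e-12).all()


class TestNormalityGate:
    def test_normal_samples_pass_mostly(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=100)
            hits += normality_gate(x) == "normal"
        assert hits >= 90

    def test_exponential_samples_fail(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=100)
            hits += normality_gate(x) == "non-normal"
        assert hits >= 99

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            normality_gate(np.ones(10))
        with pytest.raises(ValueError):
            normality_gate(np.array([1.0, 2.0]))


def _null_panel(n, sd=1.0, animal_re=0.3, run_re=0.1):
    return [
        MetaboliteModel(
            name=f"null{i}",
            mean_day0=10.0,
            mean_day28=10.0,
            within_sd_day0=sd,
            within_sd_day28=sd,
            animal_re_sd=animal_re * sd,
            run_re_sd=run_re * sd,
        )
        for i in range(n)
    ]


class TestMixedModelScreen:
    def test_pure_cattle_effect_recovered(self):
        design = generate_design(seed=0)
        panel = [
            MetaboliteModel(
                name="m",
                mean_day0=5.0,
                mean_day28=5.0,
                within_sd_day0=0.3,
                within_sd_day28=0.3,
                cattle_offset=2.0,
            )
        ]
        conc = simulate_concentrations(design, panel, seed=1)
        res = mixed_model_screen(conc, "m", "model1")
        assert res.error is None
        assert "cattle" in res.retained_terms
        assert not any("day" == t or "aging" == t for t in res.retained_terms)
        assert res.factor_p["cattle"] < 1e-6

    def test_strong_trend_flagged_and_spearman_high(self):
        design = generate_design(seed=0)
        panel = [
            MetaboliteModel(
                name="m",
                mean_day0=1.0,
                mean_day28=5.0,
                within_sd_day0=0.3,
                within_sd_day28=0.3,
            )
        ]
        conc = simulate_concentrations(design, panel, seed=2)
        res = mixed_model_screen(conc, "m", "model1")
        assert res.affected_by("day", 0.05, n_tests=30)
        assert res.spearman_r > 0.9
        assert res.friedman_p < 1e-6
        assert res.kruskal_p < 1e-6

    def test_single_animal_reported_not_fatal(self):
        design = generate_design(1, 1, [0, 28], 1, seed=0)
        panel = _null_panel(1)
        conc = simulate_concentrations(design, panel, seed=0)
        res = mixed_model_screen(conc, "null0", "model1")
        assert res.error is not None

    def test_backward_selection_stability(self, conc_table):
        # refitting from the final retained model changes nothing
        from nmrmeat.screening import _backward_select

        res = mixed_model_screen(conc_table, "glutamate", "model1")
        df = conc_table[
            ["animal_id", "cattle_type", "aging_day", "aging_type", "aging_run"]
        ].copy()
        v = conc_table["glutamate"].to_numpy(float)
        df["conc"] = (v - v.mean()) / v.std()
        df["aging_day"] = df["aging_day"].astype(float)
        df["is_cow"] = (df.cattle_type == "cow").astype(float)
        df["is_dry"] = (df.aging_type == "dry").astype(float)
        df["day_x_cow"] = df.aging_day * df.is_cow
        df["day_x_dry"] = df.aging_day * df.is_dry
        terms2, _, _, _ = _backward_select(df, tuple(res.retained_terms), True, 0.05)
        assert terms2 == res.retained_terms


class TestNullBehaviour:
    def test_null_model1_drops_everything_mostly(self):
        design = generate_design(seed=20)
        panel = _null_panel(40)
        conc = simulate_concentrations(design, panel, seed=21)
        n_terms = []
        for i in range(40):
            res = mixed_model_screen(conc, f"null{i}", "model1")
            n_terms.append(len(res.retained_terms))
        # most null metabolites end with an empty fixed structure
        assert np.mean(np.array(n_terms) == 0) > 0.6
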