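import numpy as np
import pandas as pd
import pytest

from pollinet.glmm import fit_logistic_glmm
from pollinet.invasion import (
    assemble_model_table,
    dependence_regression,
    exotic_link_indicator,
    exotic_prevalence_trends,
    fit_exotic_link_model,
    kruskal_wallis,
    preference_regression,
    relative_probability,
    simulate_link_table,
)
from pollinet.null_models import build_ensemble

from conftest import make_network, random_connected_binary


def kw_closed_form(groups):
    """Tie-free Kruskal-Wallis H: 12/(n(n+1)) * sum n_g (rbar_g - rbar)^2."""
    all_vals = np.concatenate(groups)
    order = np.argsort(all_vals)
    ranks = np.empty(len(all_vals))
    ranks[order] = np.arange(1, len(all_vals) + 1)
    n = len(all_vals)
    rbar = (n + 1) / 2
    h = 0.0
    start = 0
    for g in groups:
        rg = ranks[start : start + len(g)]
        h += len(g) * (rg.mean() - rbar) ** 2
        start += len(g)
    return 12.0 / (n * (n + 1)) * h


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([1, 2, 3, 1, 2, 3], [True] * 3 + [False] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], [True] * 3 + [False] * 3)
        assert res.statistic == pytest.approx(kw_closed_form([[1, 2, 3], [4, 5, 6]]))
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_monotone_transform_invariance(self):
        vals = np.array([0.3, 1.9, 2.2, 0.1, 5.0, 4.4])
        flags = [True, True, True, False, False, False]
        a = kruskal_wallis(vals, flags)
        b = kruskal_wallis(np.exp(vals), flags)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], [True, True, True])

    def test_matches_permutation_oracle(self):
        # small-sample permutation p-value vs the chi-square approximation
        rng = np.random.default_rng(0)
        vals = np.array([3.1, 0.2, 4.7, 1.1, 2.8, 0.9, 3.3, 2.0])
        flags = np.array([True, True, True, True, False, False, False, False])
        observed = kruskal_wallis(vals, flags).statistic
        exceed = 0
        n_perm = 20_000
        for _ in range(n_perm):
            stat = kruskal_wallis(vals, rng.permutation(flags)).statistic
            exceed += stat >= observed - 1e-12
        perm_p = exceed / n_perm
        chi2_p = kruskal_wallis(vals, flags).pvalue
        assert abs(perm_p - chi2_p) < 0.05  # chi2 approx within MC error at n=8


class TestPrevalenceTrends:
    def test_perfect_inverse_ordering(self):
        frame = pd.DataFrame(
            {
                "S": [10, 20, 30, 40],
                "P": [5, 10, 15, 20],
                "A": [5, 10, 15, 20],
                "n_exotic": [4, 3, 2, 1],
            }
        )
        out = exotic_prevalence_trends(frame).set_index("pair")
        assert out.loc["exotic_proportion_vs_S", "rho"] == pytest.approx(-1.0)
        assert out.loc["exotic_proportion_vs_S", "pvalue"] < 0.1

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(8)
        n = 200
        frame = pd.DataFrame(
            {
                "S": rng.integers(20, 100, n),
                "P": rng.integers(5, 40, n),
                "A": rng.integers(10, 60, n),
                "n_exotic": rng.integers(1, 5, n),
            }
        )
        out = exotic_prevalence_trends(frame).set_index("pair")
        # independent draws: endemic vs count association is weak
        assert abs(out.loc["endemic_richness_vs_n_exotic", "rho"]) < 0.2

    def test_too_few_networks(self):
        frame = pd.DataFrame({"S": [1, 2], "P": [1, 2], "A": [1, 2], "n_exotic": [1, 1]})
        with pytest.raises(ValueError):
            exotic_prevalence_trends(frame)


def synth_dependence_records(rng, n=400, exotic_factor=1.0):
    rows = []
    for i in range(n):
        exotic = i % 2 == 0
        base = rng.beta(2, 5)
        d = min(base * (exotic_factor if exotic else 1.0), 0.999)
        rows.append(
            {
                "d_plant": d,
                "d_pollinator": min(rng.beta(2, 5), 0.999),
                "plant_exotic": exotic,
                "gamma": float(np.exp(rng.normal(0, 0.5))),
            }
        )
    return pd.DataFrame(rows)


class TestDependenceRegression:
    def test_null_effect_small_z(self):
        rng = np.random.default_rng(1)
        frame = synth_dependence_records(rng, n=800)
        coefficient, z, _ = dependence_regression(frame, "plant")
        assert abs(z) < 3

    def test_planted_halving_negative(self):
        rng = np.random.default_rng(2)
        frame = synth_dependence_records(rng, n=800, exotic_factor=0.5)
        coefficient, z, p = dependence_regression(frame, "plant")
        assert coefficient < 0
        assert p < 0.01

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        frame = synth_dependence_records(rng, n=100)
        frame["plant_exotic"] = True
        with pytest.raises(ValueError):
            dependence_regression(frame, "plant")

    def test_degenerate_all_ones(self):
        frame = pd.DataFrame(
            {
                "d_plant": [1.0] * 10,
                "d_pollinator": [1.0] * 10,
                "plant_exotic": [True, False] * 5,
            }
        )
        with pytest.raises(ValueError):
            dependence_regression(frame, "plant")


class TestPreferenceRegression:
    def test_null_effect(self):
        rng = np.random.default_rng(4)
        frame = synth_dependence_records(rng, n=800)
        slope, t, _ = preference_regression(frame)
        assert abs(t) < 3

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(5)
        frame = synth_dependence_records(rng, n=1000)
        frame.loc[frame.plant_exotic, "gamma"] *= np.exp(0.5)
        slope, t, p = preference_regression(frame)
        se = 0.5 / abs(t) * (abs(slope) / 0.5)  # slope/t = SE
        assert abs(slope - 0.5) < 2 * abs(slope / t)
        assert p < 0.01

    def test_zero_variance_flagged(self):
        frame = pd.DataFrame(
            {"gamma": [1.0] * 10, "plant_exotic": [True, False] * 5}
        )
        slope, t, p = preference_regression(frame)
        assert slope == 0.0 and np.isnan(t)


class TestExoticLinkIndicator:
    def test_basic_flags(self):
        net = make_network(
            [[1, 1, 0, 0], [0, 0, 1, 1]], exotic=[True, False]
        )
        np.testing.assert_array_equal(
            exotic_link_indicator(net), [True, True, False, False]
        )

    def test_all_exotic(self):
        net = make_network([[1, 0], [0, 1]], exotic=[True, True])
        assert exotic_link_indicator(net).all()

    def test_no_exotics_rejected(self, triangle3):
        with pytest.raises(ValueError, match="no exotic plants"):
            exotic_link_indicator(triangle3)


class TestAssembleModelTable:
    def test_row_count_and_structure(self):
        rng = np.random.default_rng(10)
        net = make_network(
            random_connected_binary(rng, 6, 5),
            exotic=[True, False, False, True, False, False],
            network_id="m1",
        )
        ens = build_ensemble(net, "swap", 10, rng_seed=2)
        table = assemble_model_table(net, ens, contribution_reps=10, rng_seed=3)
        assert len(table) == 5 * (1 + 10)
        # k constant within pollinator across swap replicates
        for pol, sub in table.groupby("pollinator"):
            assert sub["k"].nunique() == 1
        emp = table[table.is_random == 0]
        assert len(emp) == 5
        assert set(emp.replicate) == {-1}


class TestGlmmOracle:
    def test_matches_lme4_frozen_fit(self):
        # Regenerate a fixed simulated dataset and compare to the frozen
        # estimates of an independent reference fitter (R lme4::glmer,
        # nAGQ=15) computed once on exactly this data.
        rng = np.random.default_rng(42)
        n_groups, n_per = 40, 30
        b = rng.normal(0, 0.8, n_groups)
        X_rows, y_rows, g_rows = [], [], []
        for i in range(n_groups):
            x1 = rng.random(n_per)
            x2 = rng.random(n_per)
            eta = -1.0 + 1.5 * x1 - 2.0 * x2 + b[i]
            y = (rng.random(n_per) < 1 / (1 + np.exp(-eta))).astype(int)
            X_rows.append(np.column_stack([np.ones(n_per), x1, x2]))
            y_rows.append(y)
            g_rows.append(np.full(n_per, i))
        X = np.vstack(X_rows)
        y = np.concatenate(y_rows)
        groups = np.concatenate(g_rows)
        res = fit_logistic_glmm(X, y, groups)

        expected_coef = [-0.638677, 1.083846, -2.228094]
        expected_se = [0.2106686, 0.2487432, 0.2588437]
        np.testing.assert_allclose(res.coef, expected_coef, atol=2e-4)
        np.testing.assert_allclose(res.se, expected_se, atol=2e-3)
        assert res.sigma == pytest.approx(0.6253564, abs=2e-3)
        assert res.loglik == pytest.approx(-631.8788, abs=1e-2)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_glmm(np.ones((4, 1)), [0, 1, 2, 1], [0, 0, 1, 1])


class TestExoticLinkModel:
    def test_recovery_with_planted_coefficients(self):
        coeffs = (-1.0, 1.5, -1.2, 2.0)
        table = simulate_link_table(
            120, 40, coeffs, contrasts=(0.6, -0.5, 0.8, -1.0),
            sigma_network=0.5, n_random_reps=1, seed=9,
        )
        result = fit_exotic_link_model(table)
        assert result.converged
        for name, truth in zip(("alpha", "beta", "gamma", "delta"), coeffs):
            assert abs(result.estimates[name] - truth) < 3 * result.se[name], name
        for name, truth in zip(
            ("alpha_star", "beta_star", "gamma_star", "delta_star"),
            (0.6, -0.5, 0.8, -1.0),
        ):
            assert abs(result.estimates[name] - truth) < 3 * result.se[name], name

    def test_null_slopes_near_zero(self):
        rng = np.random.default_rng(14)
        table = simulate_link_table(
            60, 30, (-1.0, 0.0, 0.0, 0.0), sigma_network=0.3, seed=15
        )
        result = fit_exotic_link_model(table)
        for name in ("beta", "gamma", "delta"):
            assert abs(result.estimates[name]) < 3 * result.se[name]

    def test_intercept_identity(self):
        table = simulate_link_table(30, 30, (-1.5, 1.0, -1.0, 2.0), seed=20)
        result = fit_exotic_link_model(table)
        p00 = result.predict_probability(0.0, 0.0)
        expected = 1 / (1 + np.exp(-result.estimates["alpha"]))
        assert p00 == pytest.approx(expected)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            fit_exotic_link_model(pd.DataFrame({"y": [0, 1]}))

    def test_coefficient_table_reconstruction(self):
        table = simulate_link_table(
            40, 25, (-1.0, 1.0, -1.0, 1.5), contrasts=(0.3, 0.2, -0.2, 0.1), seed=21
        )
        result = fit_exotic_link_model(table)
        summary = result.coefficient_table()
        random_rows = summary[summary.network_type == "Random"]
        est = result.estimates
        expect = [
            est["alpha"] + est["alpha_star"],
            est["beta"] + est["beta_star"],
            est["gamma"] + est["gamma_star"],
            est["delta"] + est["delta_star"],
        ]
        np.testing.assert_allclose(random_rows["estimate"].to_numpy(), expect)


class TestRelativeProbability:
    def test_unity_when_no_contrast(self):
        table = simulate_link_table(40, 25, (-1.0, 1.0, -1.0, 1.5), seed=22)
        result = fit_exotic_link_model(table)
        forced = {**result.estimates}
        for star in ("alpha_star", "beta_star", "gamma_star", "delta_star"):
            forced[star] = 0.0
        object.__setattr__(result, "estimates", forced)
        grid = np.linspace(0, 1, 5)
        for k in grid:
            for c in grid:
                assert relative_probability(result, k, c) == pytest.approx(1.0)

    def test_two_intercept_ratio(self):
        # direct evaluation of two given intercepts at (k, c) = (0, 0)
        table = simulate_link_table(40, 25, (-1.0, 1.0, -1.0, 1.5), seed=23)
        result = fit_exotic_link_model(table)
        forced = {name: 0.0 for name in result.estimates}
        forced["alpha"] = -3.69
        forced["alpha_star"] = -4.44 - (-3.69)
        object.__setattr__(result, "estimates", forced)
        expected = (1 / (1 + np.exp(3.69))) / (1 / (1 + np.exp(4.44)))
        assert relative_probability(result, 0.0, 0.0) == pytest.approx(expected)

    def test_positive_on_unit_square(self):
        table = simulate_link_table(
            40, 25, (-1.0, 1.0, -1.0, 1.5), contrasts=(0.5, -0.3, 0.2, 0.4), seed=24
        )
        result = fit_exotic_link_model(table)
        ks, cs = np.meshgrid(np.linspace(0, 1, 9), np.linspace(0, 1, 9))
        ratios = relative_probability(result, ks.ravel(), cs.ravel())
        assert np.all(ratios > 0)
        assert np.all(np.isfinite(ratios))
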