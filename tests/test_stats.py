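"""Fisher-z handling, signed-rank tests, classification, MLR, distances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import parcelfit as pf
from parcelfit.exceptions import InvalidArgumentError


class TestFisherZ:
    def test_closed_forms(self):
        assert pf.fisher_z(0.0) == 0.0
        assert pf.fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert pf.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_round_trip(self):
        for r in np.arange(-0.9, 0.91, 0.1):
            assert pf.fisher_z_inv(pf.fisher_z(r)) == pytest.approx(
                r, abs=1e-12)

    def test_extreme_values_clipped(self):
        assert np.isfinite(pf.fisher_z(1.0))
        assert np.isfinite(pf.fisher_z(-1.0))

    def test_fisher_mean_closed_form(self):
        # atanh(0.8) = ln(9)/2, atanh(0.6) = ln(4)/2, so the z-average is
        # ln(6)/2 and the back-transform is (6 - 1)/(6 + 1) = 5/7
        expected = np.tanh((np.arctanh(0.8) + np.arctanh(0.6)) / 2)
        assert pf.fisher_mean([0.8, 0.6]) == pytest.approx(expected)
        assert pf.fisher_mean([0.8, 0.6]) == pytest.approx(5.0 / 7.0,
                                                          abs=1e-12)

    def test_fisher_mean_of_identical_values(self):
        assert pf.fisher_mean([0.4, 0.4, 0.4]) == pytest.approx(0.4)


class TestFitPatternCorrelations:
    def _table(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        return pd.DataFrame({
            "A1": base + 0.3 * rng.normal(size=n),
            "A2": base + 0.3 * rng.normal(size=n),
            "B1": rng.normal(size=n),
        })

    def test_self_correlation_unit_and_significant(self):
        table = self._table()
        report = pf.fit_pattern_correlations(table)
        assert np.allclose(np.diag(report.r), 1.0)
        assert report.r.loc["A1", "A1"] == 1.0

    def test_symmetry_and_pvalues(self):
        report = pf.fit_pattern_correlations(self._table())
        assert report.r.equals(report.r.T)
        r, p = sps.pearsonr(self._table()["A1"], self._table()["A2"])
        assert report.r.loc["A1", "A2"] == pytest.approx(r)
        assert report.p.loc["A1", "A2"] == pytest.approx(p)

    def test_intra_exceeds_inter_for_shared_signal(self):
        report = pf.fit_pattern_correlations(
            self._table(), atlas_labels={"A1": "A", "A2": "A", "B1": "B"})
        assert report.intra_atlas_mean > report.inter_atlas_mean

    def test_common_permutation_invariance(self):
        table = self._table()
        perm = np.random.default_rng(1).permutation(len(table))
        report1 = pf.fit_pattern_correlations(table)
        report2 = pf.fit_pattern_correlations(table.iloc[perm]
                                              .reset_index(drop=True))
        pd.testing.assert_frame_equal(report1.r, report2.r)


class TestSignedRank:
    def test_identical_vectors(self):
        x = np.arange(6, dtype=float)
        with pytest.warns(UserWarning):
            p, effect = pf.signed_rank_test(x, x)
        assert p == 1.0 and effect == 0.0

    def test_exact_p_matches_exhaustive_enumeration(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])
        p, _ = pf.signed_rank_test(d)
        # oracle: enumerate all 2^6 sign assignments of the |d| midranks
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            1 for signs in itertools.product([0, 1], repeat=6)
            if sum(r for s, r in zip(signs, ranks) if s) >= w_obs - 1e-9)
        assert p == pytest.approx(count / 2 ** 6)

    def test_all_positive_differences_give_unit_effect(self):
        p, effect = pf.signed_rank_test(np.array([0.5, 1.0, 2.0, 3.0, 0.1]))
        assert effect == 1.0
        assert p == pytest.approx(1 / 2 ** 5)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, 24)
        p_exact, _ = pf.signed_rank_test(d, exact_max_n=25)
        p_normal, _ = pf.signed_rank_test(d, exact_max_n=0)
        assert p_normal == pytest.approx(p_exact, abs=0.01)

    def test_one_sided_complementarity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p_xy, _ = pf.signed_rank_test(x, y)
        p_yx, _ = pf.signed_rank_test(y, x)
        # p> + p< = 1 + P(W = w_obs), so the smaller one barely exceeds 1/2
        assert min(p_xy, p_yx) <= 0.55


class TestPairwiseWilcoxon:
    def _fits(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=20)
        return pd.DataFrame({"P1": base + 1.0,
                             "P2": base + 0.3 * rng.normal(size=20),
                             "P3": base})

    def test_identical_columns_corrected_to_one(self):
        fits = self._fits()
        fits["P2"] = fits["P1"]
        with pytest.warns(UserWarning):
            report = pf.pairwise_wilcoxon(fits[["P1", "P2"]])
        assert report.p_corrected.loc["P1", "P2"] == 1.0
        assert report.p_corrected.loc["P2", "P1"] == 1.0

    def test_dominant_column_detected(self):
        report = pf.pairwise_wilcoxon(self._fits())
        assert report.p_corrected.loc["P1", "P3"] < 0.05
        assert report.p_corrected.loc["P3", "P1"] == 1.0
        assert report.effect.loc["P1", "P3"] == 1.0

    def test_bonferroni_scales_raw_p(self):
        report = pf.pairwise_wilcoxon(self._fits())
        m = 6  # ordered pairs of 3 columns
        raw = report.p.loc["P1", "P3"]
        assert report.p_corrected.loc["P1", "P3"] == pytest.approx(
            min(1.0, raw * m))

    def test_holm_not_more_conservative_than_bonferroni(self):
        fits = self._fits()
        bon = pf.pairwise_wilcoxon(fits, correction="bonferroni")
        holm = pf.pairwise_wilcoxon(fits, correction="holm")
        assert np.all(holm.p_corrected.to_numpy()[~np.eye(3, dtype=bool)]
                      <= bon.p_corrected.to_numpy()[~np.eye(3, dtype=bool)]
                      + 1e-12)


class TestVariableFitRegression:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k, parc in enumerate(["P1", "P2", "P3"]):
            v = rng.normal(size=40)
            rows.append(pd.DataFrame({
                "parcellation": parc,
                "linear": v,
                "intra_var": rng.normal(size=40),
                "fit": v,
            }))
        return pd.concat(rows, ignore_index=True)

    def test_exact_linear_relation(self):
        report = pf.variable_fit_regression(self._table(), ["linear"])
        assert np.allclose(report.per_parcellation_r.loc["linear"], 1.0)
        assert report.summary.loc["linear", "joint_r"] == pytest.approx(1.0)
        assert report.summary.loc["linear", "group_median_r"] == pytest.approx(
            1.0)

    def test_constructed_intra_variable(self):
        rng = np.random.default_rng(1)
        rows = []
        for k, parc in enumerate(["P1", "P2", "P3", "P4"]):
            v = rng.normal(size=60)
            # within each parcellation the variable tracks fit tightly, but
            # large opposing parcellation-level offsets destroy the joint r
            rows.append(pd.DataFrame({
                "parcellation": parc,
                "x": v + 30.0 * (-1) ** k,
                "fit": v + 0.3 * rng.normal(size=60),
            }))
        table = pd.concat(rows, ignore_index=True)
        report = pf.variable_fit_regression(table, ["x"])
        assert report.classification("x") == "intra"

    def test_constructed_inter_variable(self):
        rng = np.random.default_rng(2)
        rows = []
        for k, parc in enumerate(["P1", "P2", "P3", "P4"]):
            # fit is driven by the parcellation-level offset only
            rows.append(pd.DataFrame({
                "parcellation": parc,
                "x": rng.normal(size=60) + 3.0 * k,
                "fit": 0.5 * k + 0.1 * rng.normal(size=60),
            }))
        table = pd.concat(rows, ignore_index=True)
        report = pf.variable_fit_regression(table, ["x"])
        assert report.classification("x") == "inter"

    def test_group_median_bruteforce(self):
        table = self._table(seed=3)
        report = pf.variable_fit_regression(table, ["intra_var"])
        med = table.groupby("parcellation")[["intra_var", "fit"]].median()
        expected, _ = sps.pearsonr(med["intra_var"], med["fit"])
        assert report.summary.loc["intra_var",
                                  "group_median_r"] == pytest.approx(expected)

    def test_sign_flip_preserves_classification(self):
        table = self._table(seed=4)
        r1 = pf.variable_fit_regression(table, ["linear"])
        flipped = table.assign(linear=-table["linear"])
        r2 = pf.variable_fit_regression(flipped, ["linear"])
        assert (r1.classification("linear") == r2.classification("linear"))

    def test_too_few_parcellations(self):
        table = self._table()
        with pytest.raises(InvalidArgumentError):
            pf.variable_fit_regression(
                table[table["parcellation"] != "P3"], ["linear"])


class TestMLR:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = 2 * x["a"] - x["b"] + 0.5 * x["c"] + 3
        result = pf.mlr_fit(x, y)
        assert result.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(100, 5)),
                         columns=[f"v{i}" for i in range(5)])
        y = rng.normal(size=100)
        result = pf.mlr_fit(x, y)
        xz = (x - x.mean()) / x.std(ddof=0)
        design = np.column_stack([np.ones(100), xz])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(result.coefficients.to_numpy(), beta,
                                   atol=1e-10)

    def test_intercept_equals_mean_of_y(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = rng.normal(size=60)
        result = pf.mlr_fit(x, y)
        assert result.coefficients["intercept"] == pytest.approx(
            y.mean(), abs=1e-10)

    def test_nested_model_r2_non_decreasing(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(80, 4)),
                         columns=["a", "b", "c", "d"])
        y = x["a"] + rng.normal(size=80)
        r2 = [pf.mlr_fit(x[cols], y).r_squared
              for cols in (["a"], ["a", "b"], ["a", "b", "c"],
                           ["a", "b", "c", "d"])]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame({"a": rng.normal(size=40)})
        x["b"] = 2 * x["a"]
        x["c"] = rng.normal(size=40)
        with pytest.raises(InvalidArgumentError) as err:
            pf.mlr_fit(x, rng.normal(size=40))
        assert "a" in str(err.value) and "b" in str(err.value)

    def test_too_few_rows(self):
        x = pd.DataFrame(np.random.default_rng(5).normal(size=(4, 4)))
        with pytest.raises(InvalidArgumentError):
            pf.mlr_fit(x, np.zeros(4))


class TestOptimalParameterDistances:
    def test_identical_optima(self):
        optima = {"P1": [[4.0, 0.3], [6.0, 0.2]],
                  "P2": [[4.0, 0.3], [6.0, 0.2]]}
        d = pf.optimal_parameter_distances(optima)
        assert d.loc["P1", "P2"] == 0.0

    def test_single_tau_step(self):
        optima = {"P1": [[4.0, 0.3]], "P2": [[6.0, 0.3]]}
        d = pf.optimal_parameter_distances(optima)
        assert d.loc["P1", "P2"] == pytest.approx(2.0 / 94.0)

    def test_two_subject_hand_example(self):
        optima = {"P1": [[0.0, 0.0], [94.0, 0.945]],
                  "P2": [[94.0, 0.0], [94.0, 0.0]]}
        d = pf.optimal_parameter_distances(optima)
        expected = (np.hypot(1.0, 0.0) + np.hypot(0.0, 1.0)) / 2
        assert d.loc["P1", "P2"] == pytest.approx(expected)

    def test_missing_optima_excluded_with_warning(self):
        optima = {"P1": [[4.0, 0.3], [np.nan, 0.2]],
                  "P2": [[4.0, 0.3], [6.0, 0.2]]}
        with pytest.warns(UserWarning):
            d = pf.optimal_parameter_distances(optima)
        assert d.loc["P1", "P2"] == 0.0
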