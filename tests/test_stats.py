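"""Accuracy measures, heteroscedastic GLS, permutation tests, Gamma GLM."""

import itertools

import numpy as np
import pytest

import scaffoldcount as sc
from scaffoldcount.errors import AnalysisError
from scaffoldcount.stats import (
    MethodSample,
    comparisons_to_frame,
    gamma_glm_log,
    residual_diagnostics,
)


class TestTheoreticalValue:
    @pytest.mark.parametrize(
        "vals,expected", [([10, 10, 10], 10.0), ([12, 14, 16, 18], 15.0)]
    )
    def test_known_means(self, vals, expected):
        s = MethodSample("ref", "d", np.array(vals, float))
        assert sc.theoretical_value(s) == pytest.approx(expected)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1e5, 37)
        s = MethodSample("ref", "d", x)
        acc = 0.0
        for v in x:
            acc += v
        assert sc.theoretical_value(s) == pytest.approx(acc / 37)


class TestAccuracyMeasures:
    def test_reference_mean_bias_is_zero(self):
        s = MethodSample("ref", "d", np.array([4.0, 6.0, 8.0]))
        tv = sc.theoretical_value(s)
        table = sc.accuracy_measures([s], tv)
        bias = table[table.measure == "bias"].value
        assert bias.mean() == pytest.approx(0.0)

    def test_hand_computed_deviations(self):
        s = MethodSample("m", "d", np.array([4.0, 6.0]))
        table = sc.accuracy_measures([s], tv=3.0)
        by = lambda m: sorted(table[table.measure == m].value)
        assert by("dev_mean") == pytest.approx([1.0, 1.0])
        assert by("sq_dev_mean") == pytest.approx([1.0, 1.0])
        assert by("dev_tv") == pytest.approx([1.0, 3.0])
        assert by("sq_dev_tv") == pytest.approx([1.0, 9.0])

    def test_squared_measures_are_squares_of_absolute(self):
        rng = np.random.default_rng(1)
        s = MethodSample("m", "d", rng.uniform(0, 1e5, 25))
        table = sc.accuracy_measures([s], tv=40_000.0)
        for absname, sqname in (("dev_mean", "sq_dev_mean"),
                                ("dev_tv", "sq_dev_tv")):
            a = table[table.measure == absname].value.to_numpy()
            q = table[table.measure == sqname].value.to_numpy()
            np.testing.assert_allclose(q, a**2)


class TestGLS:
    def test_identical_groups_have_zero_effect(self):
        fit = sc.gls_heteroscedastic([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert fit.contrast("a", "b").beta == pytest.approx(0.0)

    def test_no_residual_variance_gives_zero_width_ci(self):
        fit = sc.gls_heteroscedastic([0, 0, 0, 0, 2, 2, 2, 2],
                                     list("aaaabbbb"))
        con = fit.contrast("b", "a")
        assert con.beta == pytest.approx(2.0)
        assert con.ci_lower == con.ci_upper == pytest.approx(2.0)

    def test_beta_equals_raw_mean_difference(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 1, 8)
        y = rng.normal(20, 5, 13)
        fit = sc.gls_heteroscedastic(np.r_[x, y], ["x"] * 8 + ["y"] * 13)
        assert fit.contrast("y", "x").beta == pytest.approx(
            y.mean() - x.mean(), abs=1e-12
        )

    def test_matches_nlme_gls_varident_reml(self):
        # frozen oracle: R nlme::gls(value ~ grp, weights=varIdent(~1|grp),
        # method="REML") on this dataset gives beta = 11.2, SE = 2.645750
        # (the analytic value is sqrt(7) = 2.6457513; nlme stops at ~1e-6)
        vals = [10, 12, 11, 14, 9, 20, 25, 15, 30, 22]
        fit = sc.gls_heteroscedastic(vals, ["a"] * 5 + ["b"] * 5)
        con = fit.contrast("b", "a")
        assert con.beta == pytest.approx(11.2, abs=1e-9)
        assert con.se == pytest.approx(2.6457513, abs=1e-5)

    def test_singleton_group_rejected(self):
        with pytest.raises(AnalysisError):
            sc.gls_heteroscedastic([1, 2, 3], ["a", "a", "b"])


def _exact_permutation_p(x, y):
    """Exhaustive-enumeration oracle for the two-sided Welch permutation p."""
    pooled = np.r_[x, y]
    n, nx = len(pooled), len(x)

    def welch(a, b):
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        if se == 0:
            return 0.0 if a.mean() == b.mean() else np.inf
        return (a.mean() - b.mean()) / se

    t_obs = abs(welch(np.asarray(x, float), np.asarray(y, float)))
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        t = abs(welch(pooled[sel], pooled[~sel]))
        hits += t >= t_obs - 1e-12
        total += 1
    return hits / total


class TestPermutationTTest:
    def test_identical_vectors_give_p_one(self):
        res = sc.permutation_t_test([1, 2, 3], [1, 2, 3], n_perm=999, seed=0)
        assert res.p == 1.0

    def test_degenerate_constant_data(self):
        res = sc.permutation_t_test([5, 5], [5, 5, 5], n_perm=99, seed=0)
        assert res.p == 1.0

    def test_monte_carlo_agrees_with_exact_enumeration(self):
        # n = 4 vs 4: all C(8,4) = 70 label assignments enumerable
        x = [12.1, 9.8, 11.4, 10.7]
        y = [14.2, 13.1, 15.0, 12.8]
        exact = _exact_permutation_p(x, y)
        res = sc.permutation_t_test(x, y, n_perm=5000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 5000)
        assert abs(res.p - exact) <= 3 * se + 2 / 5001

    def test_shift_invariance_is_exact_for_fixed_seed(self):
        x = [3.0, 1.0, 4.0, 1.5]
        y = [5.0, 9.0, 2.0, 6.0, 5.0]
        p1 = sc.permutation_t_test(x, y, n_perm=2000, seed=7).p
        p2 = sc.permutation_t_test(
            [v + 123.0 for v in x], [v + 123.0 for v in y], n_perm=2000, seed=7
        ).p
        assert p1 == p2

    def test_relabel_invariance_within_monte_carlo_error(self):
        x = [12.1, 9.8, 11.4, 10.7]
        y = [14.2, 13.1, 15.0, 12.8]
        exact = _exact_permutation_p(x, y)
        for a, b in ((x, y), (y, x)):
            p = sc.permutation_t_test(a, b, n_perm=5000, seed=11).p
            se = np.sqrt(exact * (1 - exact) / 5000)
            assert abs(p - exact) <= 3 * se + 2 / 5001

    def test_empty_sample_rejected(self):
        with pytest.raises(AnalysisError):
            sc.permutation_t_test([], [1, 2], n_perm=10)


class TestGammaGLM:
    def test_effect_equals_log_mean_ratio(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 10.0, 20)
        y = rng.gamma(2.0, 20.0, 15)
        res = gamma_glm_log(np.r_[x, y], ["a"] * 20 + ["b"] * 15,
                            n_perm=200, seed=0)
        assert res.beta_log == pytest.approx(np.log(y.mean() / x.mean()),
                                             abs=1e-6)

    def test_identical_groups(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = gamma_glm_log(v, list("aaabbb"), n_perm=500, seed=0)
        assert res.beta_log == pytest.approx(0.0, abs=1e-10)
        assert res.p == 1.0

    def test_zero_values_shifted_by_recorded_offset(self):
        res = gamma_glm_log([0.0, 2.0, 4.0, 3.0], list("aabb"),
                            n_perm=100, seed=0)
        assert res.zero_offset == pytest.approx(2.0 * 1e-3)

    def test_all_zero_rejected(self):
        with pytest.raises(AnalysisError):
            gamma_glm_log([0.0, 0.0, 0.0, 0.0], list("aabb"))

    def test_three_groups_rejected(self):
        with pytest.raises(AnalysisError):
            gamma_glm_log([1, 2, 3], list("abc"))


class TestResidualDiagnostics:
    def test_normal_sample_rarely_rejected(self):
        rng = np.random.default_rng(0)
        rejected = sum(
            residual_diagnostics(rng.normal(size=100)).shapiro_p < 0.01
            for _ in range(40)
        )
        assert rejected <= 2

    def test_exponential_sample_usually_rejected(self):
        rng = np.random.default_rng(1)
        rejected = sum(
            residual_diagnostics(rng.exponential(size=100)).shapiro_p < 0.01
            for _ in range(20)
        )
        assert rejected >= 18

    def test_degenerate_inputs(self):
        with pytest.raises(AnalysisError):
            residual_diagnostics([1.0, 1.0])
        with pytest.raises(AnalysisError):
            residual_diagnostics([2.0, 2.0, 2.0, 2.0])


class TestCompareMethods:
    def _samples(self, rng, bias=0.0):
        ref = MethodSample("burker", 125, rng.normal(125_000, 15_000, 10).clip(0))
        cand = MethodSample(
            "candidate", 125, rng.normal(125_000 + bias, 15_000, 12).clip(0)
        )
        return [ref, cand]

    def test_identical_candidate_gives_null_results(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        samples = [
            MethodSample("ref", "d", vals),
            MethodSample("cand", "d", vals.copy()),
        ]
        results = sc.compare_methods(samples, "ref", n_perm=500, seed=0)
        df = comparisons_to_frame(results)
        contrasts = df[df.contrast == "cand vs. ref"]
        assert np.allclose(contrasts.beta, 0.0, atol=1e-10)
        assert (contrasts.p == 1.0).all()

    def test_reference_bias_row_is_zero_with_symmetric_ci(self):
        rng = np.random.default_rng(7)
        results = sc.compare_methods(self._samples(rng), "burker",
                                     n_perm=200, seed=0)
        df = comparisons_to_frame(results)
        row = df[(df.measure == "bias") & df.contrast.str.startswith("Ref")]
        assert row.beta.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert row.ci_lower.iloc[0] == pytest.approx(-row.ci_upper.iloc[0],
                                                     abs=1e-6)

    def test_planted_bias_is_recovered_within_ci(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(30):
            results = sc.compare_methods(
                self._samples(rng, bias=-30_000), "burker", n_perm=200,
                seed=int(rng.integers(2**31)),
            )
            df = comparisons_to_frame(results)
            row = df[(df.measure == "bias")
                     & (df.contrast == "candidate vs. burker")]
            hits += bool(row.ci_lower.iloc[0] <= -30_000 <= row.ci_upper.iloc[0])
        assert hits >= 26  # ~95% nominal coverage

    def test_in_thousands_rescales_linear_measures_only(self):
        rng = np.random.default_rng(9)
        samples = self._samples(rng)
        raw = comparisons_to_frame(
            sc.compare_methods(samples, "burker", n_perm=100, seed=0)
        )
        thousands = comparisons_to_frame(
            sc.compare_methods(samples, "burker", n_perm=100, seed=0,
                               in_thousands=True)
        )
        lin = raw.measure.isin(["bias", "dev_mean", "dev_tv"])
        np.testing.assert_allclose(
            thousands[lin].beta, raw[lin].beta / 1000.0
        )
        np.testing.assert_allclose(
            thousands[~lin].beta, raw[~lin].beta
        )

    def test_unknown_reference_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(AnalysisError):
            sc.compare_methods(self._samples(rng), "nope", n_perm=10)


def test_plot_writes_a_file(tmp_path):
    rng = np.random.default_rng(0)
    samples = [
        MethodSample("a", "d", rng.normal(100, 10, 8).clip(0)),
        MethodSample("b", "d", rng.normal(120, 10, 8).clip(0)),
    ]
    out = tmp_path / "strip.png"
    sc.stats.plot_method_estimates(samples, out, tv=100.0)
    assert out.stat().st_size > 0
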