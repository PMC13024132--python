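import numpy as np
import pytest
from scipy import stats as sps

import qeegkit as qk
from qeegkit.errors import DesignError, EstimatorError, FitError
from qeegkit.stats import dunn_test


class TestCriticalR:
    def test_printed_threshold_n22(self):
        assert qk.critical_r(22, 0.05) == pytest.approx(0.4224, abs=1e-3)

    def test_one_sided_variant_smaller(self):
        assert qk.critical_r(22, 0.05, tail="one-sided") == pytest.approx(
            0.360, abs=1e-3)

    def test_monotone_decreasing_in_n(self):
        vals = [qk.critical_r(n) for n in (5, 10, 50, 500, 50000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01

    @pytest.mark.parametrize("n, alpha", [(10, 0.05), (22, 0.05),
                                          (40, 0.01), (100, 0.10)])
    def test_round_trip_t_statistic(self, n, alpha):
        r = qk.critical_r(n, alpha)
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        assert t == pytest.approx(sps.t.ppf(1 - alpha / 2, n - 2), abs=1e-6)

    def test_agrees_with_grid_search(self):
        # brute-force inversion of the t formula on an r grid
        rng = np.random.default_rng(0)
        grid = np.arange(1e-5, 1.0, 1e-5)
        for _ in range(10):
            n = int(rng.integers(5, 200))
            alpha = float(rng.uniform(0.001, 0.2))
            tcrit = sps.t.ppf(1 - alpha / 2, n - 2)
            tvals = grid * np.sqrt(n - 2) / np.sqrt(1 - grid ** 2)
            brute = grid[np.searchsorted(tvals, tcrit)]
            assert qk.critical_r(n, alpha) == pytest.approx(brute, abs=2e-5)

    def test_insufficient_df(self):
        with pytest.raises(EstimatorError):
            qk.critical_r(3)


class TestFitPolynomial:
    def test_exact_cubic_r_one(self):
        x = np.linspace(40, 70, 20)
        y = 1.0 - 0.2 * x + 0.01 * x ** 2 - 5e-5 * x ** 3
        fit = qk.fit_polynomial(x, y, 3)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.significant

    def test_constant_y_reported_missing(self):
        fit = qk.fit_polynomial(np.arange(10.0), np.full(10, 2.0), 2)
        assert np.isnan(fit.r) and not fit.significant

    def test_degree_one_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 30)
        y = 3.0 + 0.5 * x + rng.standard_normal(30)
        fit = qk.fit_polynomial(x, y, 1)
        slope, intercept, r, *_ = sps.linregress(x, y)
        assert fit.coefficients[0] == pytest.approx(intercept, abs=1e-10)
        assert fit.coefficients[1] == pytest.approx(slope, abs=1e-10)
        assert fit.r == pytest.approx(abs(r), abs=1e-10)

    def test_r_invariant_to_affine_y(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 25)
        y = np.sin(x) + 0.1 * rng.standard_normal(25)
        r1 = qk.fit_polynomial(x, y, 2).r
        r2 = qk.fit_polynomial(x, 4.0 - 2.5 * y, 2).r
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_rank_deficiency(self):
        with pytest.raises(FitError):
            qk.fit_polynomial(np.ones(10), np.arange(10.0), 2)

    def test_cubic_parameter_recovery(self):
        # seeded replicates: mean estimated coefficients within 2 SE of
        # the generating cubic link
        true = np.array([2.0, -0.08, 0.002, 1.2e-5])
        rng = np.random.default_rng(3)
        estimates = []
        for _ in range(100):
            x = rng.uniform(30, 70, 22)
            y = np.polynomial.polynomial.polyval(x, true) \
                + 0.05 * rng.standard_normal(22)
            estimates.append(qk.fit_polynomial(x, y, 3).coefficients)
        est = np.array(estimates)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - true) < 2 * se + 1e-12)


class TestSelectDegree:
    def test_linear_data_selects_one(self):
        x = np.linspace(0, 10, 30)
        assert qk.select_degree(x, 2.0 + 0.7 * x) == 1

    def test_strong_cubic_selects_three(self):
        rng = np.random.default_rng(4)
        x = np.linspace(-3, 3, 40)
        y = x ** 3 - 3.0 * x + 0.2 * rng.standard_normal(40)
        # direct validation: r(3) must carry >75% of the best r while
        # lower degrees do not
        rs = {d: qk.fit_polynomial(x, y, d).r for d in (1, 2, 3, 4)}
        assert rs[3] > 0.75 * max(rs.values()) > rs[2]
        assert qk.select_degree(x, y) == 3

    def test_flat_r_profile_selects_minimum(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 40)
        y = 5.0 + 2.0 * x + 0.01 * rng.standard_normal(40)
        assert qk.select_degree(x, y) == 1


class TestGroupCompare:
    def test_identical_paired_samples_not_significant(self):
        a = np.random.default_rng(6).standard_normal(22)
        rep = qk.group_compare(a, a.copy(), design="paired")
        assert not rep.significant

    def test_large_shift_power(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = rng.standard_normal(22)
            b = rng.standard_normal(22) + 3.0
            if qk.group_compare(a, b, design="independent").significant:
                hits += 1
        assert hits >= 99

    def test_heavy_tails_route_to_rank_test(self):
        rng = np.random.default_rng(8)
        a = rng.standard_cauchy(40)
        b = rng.standard_cauchy(40)
        rep = qk.group_compare(a, b, design="independent")
        assert rep.test == "Mann-Whitney" and not rep.normal

    def test_gaussian_equal_var_routes_to_t(self):
        rng = np.random.default_rng(9)
        rep = qk.group_compare(rng.standard_normal(30),
                               rng.standard_normal(30),
                               design="independent")
        assert rep.test == "Student t"

    def test_paired_unequal_lengths(self):
        with pytest.raises(DesignError):
            qk.group_compare(np.arange(10.0), np.arange(8.0),
                             design="paired")

    def test_kruskal_with_dunn_posthoc(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + 4.0
        c = rng.standard_normal(15)
        rep = qk.group_compare(a, b, c, design="k-group")
        assert rep.test == "Kruskal-Wallis" and rep.significant
        shifted = [d for d in rep.posthoc if 1 in d["groups"]]
        same = [d for d in rep.posthoc if d["groups"] == (0, 2)]
        assert all(d["p_adj"] < 0.05 for d in shifted)
        assert same[0]["p_adj"] > 0.05

    def test_dunn_against_pairwise_ranksum_direction(self):
        # z signs must follow the rank ordering of the group means
        samples = [np.array([1.0, 2.0, 3.0, 2.5]),
                   np.array([10.0, 11.0, 12.0, 11.5])]
        res = dunn_test(samples)
        assert res[0]["z"] < 0
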