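"""LHS design, PRCC against a matrix-inversion oracle, monotonicity."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from kiwipol import (
    LHSDesign,
    ParameterRanges,
    Scenario,
    integrate,
    lhs_sample,
    monotonicity_check,
    prcc,
    run_batch,
    scenario_from_sample,
    table2_ranges,
    truncated_prcc,
)


class TestRanges:
    def test_raw_parameterization_covers_all_sixteen_parameters(self):
        names = table2_ranges("raw").names
        assert len(names) == 16
        assert {"alpha", "beta", "B_m", "B_f", "rho", "p3"} <= set(names)

    def test_derived_parameterization_swaps_bud_covariates(self):
        names = table2_ranges("derived").names
        assert "B_m" not in names and "B_f" not in names
        assert {"total_buds", "pct_female"} <= set(names)

    def test_truncation_validates_windows(self):
        r = table2_ranges("derived")
        with pytest.raises(ValueError):
            r.truncated({"pct_female": (0.0, 0.5)})   # below range
        with pytest.raises(KeyError):
            r.truncated({"nope": (0, 1)})
        t = r.truncated({"pct_female": (0.05, 0.76)})
        assert dict(zip(t.names, t.bounds[:, 1]))["pct_female"] == 0.76

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            ParameterRanges((("x", 1.0, 1.0),))


class TestLHS:
    def test_exactly_one_draw_per_stratum(self):
        design = lhs_sample(table2_ranges("raw"), 10, seed=1)
        strata = design.strata()
        for j in range(strata.shape[1]):
            assert sorted(strata[:, j]) == list(range(10))

    def test_seed_determinism(self):
        r = table2_ranges("raw")
        a = lhs_sample(r, 50, seed=7)
        b = lhs_sample(r, 50, seed=7)
        c = lhs_sample(r, 50, seed=8)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_marginals_near_uniform(self):
        from scipy.stats import kstest

        design = lhs_sample(table2_ranges("raw"), 1000, seed=3)
        bounds = design.ranges.bounds
        ok = 0
        for j in range(design.samples.shape[1]):
            u = (design.samples[:, j] - bounds[j, 0]) / (
                bounds[j, 1] - bounds[j, 0])
            if kstest(u, "uniform").statistic < 1.36 / np.sqrt(1000):
                ok += 1
        assert ok >= 15

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            lhs_sample(table2_ranges("raw"), 1, seed=0)
        # PRCC itself needs enough residual degrees of freedom
        design = lhs_sample(table2_ranges("raw"), 10, seed=0)
        with pytest.raises(ValueError):
            prcc(design.samples, np.arange(10.0), design.names)


def prcc_by_matrix_inversion(X, y):
    """Textbook oracle: partial correlations from the inverse of the
    full Spearman correlation matrix of [X | y]."""
    full = np.column_stack([X, y])
    corr = spearmanr(full).statistic
    prec = np.linalg.inv(corr)
    k = X.shape[1]
    return np.array([-prec[j, k] / np.sqrt(prec[j, j] * prec[k, k])
                     for j in range(k)])


class TestPRCC:
    def test_matches_matrix_inversion_oracle(self, rng):
        n, k = 50, 3
        X = rng.uniform(size=(n, k))
        y = 2 * X[:, 0] - X[:, 1] ** 2 + 0.3 * rng.normal(size=n)
        report = prcc(X, y, ["a", "b", "c"])
        want = prcc_by_matrix_inversion(X, y)
        got = report.to_frame()["prcc"].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_detects_single_monotone_driver(self, rng):
        n, k = 200, 6
        X = rng.uniform(size=(n, k))
        y = np.exp(2 * X[:, 2]) + 0.01 * rng.normal(size=n)
        report = prcc(X, y, [f"x{j}" for j in range(k)])
        assert report["x2"] > 0.95
        for j in (0, 1, 3, 4, 5):
            assert abs(report[f"x{j}"]) < 0.2

    def test_null_p_values_uniform(self, rng):
        pvals = []
        for _ in range(40):
            X = rng.uniform(size=(100, 5))
            y = rng.normal(size=100)
            pvals.extend(prcc(X, y, list("abcde")).to_frame()["p_t"])
        pvals = np.asarray(pvals)
        frac = np.mean(pvals < 0.05)
        assert abs(frac - 0.05) < 0.05
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_invariant_under_monotone_output_transform(self, rng):
        X = rng.uniform(size=(80, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.1 * rng.normal(size=80)
        a = prcc(X, y, list("wxyz")).to_frame()["prcc"]
        b = prcc(X, np.exp(3 * y), list("wxyz")).to_frame()["prcc"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_derived_bud_covariates(self, rng):
        names = table2_ranges("raw").names
        design = lhs_sample(table2_ranges("raw"), 60, seed=2)
        y = rng.normal(size=60)
        rep = prcc(design.samples, y, names, derive_bud_covariates=True)
        out_names = list(rep.to_frame()["parameter"])
        assert "total_buds" in out_names and "pct_female" in out_names
        assert "B_m" not in out_names

    def test_rejects_constant_column(self, rng):
        X = rng.uniform(size=(30, 3))
        X[:, 1] = 5.0
        with pytest.raises(ValueError):
            prcc(X, rng.normal(size=30), list("abc"))


class TestMonotonicityCheck:
    def test_identity_is_monotone(self, rng):
        x = rng.uniform(size=400)
        res = monotonicity_check(x, x)
        assert res.monotone and res.split_points == ()

    def test_quadratic_flagged_with_mid_split(self, rng):
        x = rng.uniform(size=500)
        y = -(x - 0.5) ** 2 + rng.normal(0, 0.02, 500)
        res = monotonicity_check(x, y)
        assert not res.monotone
        assert 0.4 <= res.split_points[0] <= 0.6

    def test_decreasing_is_monotone(self, rng):
        x = rng.uniform(size=300)
        res = monotonicity_check(x, np.exp(-3 * x))
        assert res.monotone


class TestBatchAndTruncation:
    def test_single_row_at_base_values_matches_integrate(self, baseline,
                                                         baseline_result):
        ranges = table2_ranges("raw")
        base_vals = {"alpha": 480, "beta": 0.0011, "delta": 0.0634,
                     "epsilon": 0.0725, "B_m": 600_000, "B_f": 600_000,
                     "t_m": 6, "t_f": 6, "sigma_m": 2.5, "sigma_f": 2,
                     "tau_m": 4, "tau_f": 5, "rho": 6,
                     "p1": 0.66, "p2": 0.55, "p3": 0.22}
        row = np.array([base_vals[nm] for nm in ranges.names], dtype=float)
        design = LHSDesign(ranges=ranges, unit=np.zeros((1, 16)),
                           samples=row[None, :], seed=0)
        yields, failures = run_batch(design, baseline)
        assert not failures
        assert yields[0] == pytest.approx(baseline_result.total_yield,
                                          rel=1e-12)

    def test_scenario_from_sample_derived_covariates(self, baseline):
        names = ["total_buds", "pct_female", "rho"]
        scen = scenario_from_sample(names, np.array([1.0e6, 0.25, 3.0]),
                                    baseline)
        assert scen.flowers.buds_female == pytest.approx(250_000)
        assert scen.flowers.buds_male == pytest.approx(750_000)
        assert scen.pollinators.density == 3.0

    def test_scenario_from_sample_rejects_unknown(self, baseline):
        with pytest.raises(KeyError):
            scenario_from_sample(["bogus"], np.array([1.0]), baseline)

    def test_more_bees_raise_mean_yield(self, baseline):
        ranges = table2_ranges("raw")
        design = lhs_sample(ranges, 20, seed=5)
        j = ranges.names.index("rho")
        lo = LHSDesign(ranges=ranges, unit=design.unit,
                       samples=design.samples.copy(), seed=5)
        lo.samples[:, j] = 1.0
        hi = LHSDesign(ranges=ranges, unit=design.unit,
                       samples=design.samples.copy(), seed=5)
        hi.samples[:, j] = 20.0
        y_lo, _ = run_batch(lo, baseline)
        y_hi, _ = run_batch(hi, baseline)
        assert np.nanmean(y_hi) > np.nanmean(y_lo)

    def test_identity_truncation_reproduces_full_range(self, baseline):
        ranges = table2_ranges("derived")
        n, seed = 30, 4
        design = lhs_sample(ranges, n, seed)
        yields, _ = run_batch(design, baseline)
        full = prcc(design.samples, yields, design.names)
        lo, hi = dict(zip(ranges.names, ranges.bounds))["pct_female"]
        trunc = truncated_prcc(baseline, ranges,
                               {"pct_female": (lo, hi)}, n, seed)
        np.testing.assert_allclose(trunc.to_frame()["prcc"],
                                   full.to_frame()["prcc"], atol=1e-12)
        assert trunc.truncation == {"pct_female": (lo, hi)}
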