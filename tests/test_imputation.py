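"""Chained-equations imputation, Rubin pooling and the D1 comparison."""

import numpy as np
import pandas as pd
import pytest

from survtab.cox_models import fit_cox
from survtab.datatypes import FeatureMeta, SurvivalDataset
from survtab.imputation import (
    choose_m,
    imputation_bias_check,
    mice_impute,
    quickpred,
    rubin_pool,
    wald_compare_pooled,
)
from tests.conftest import weibull_cox_data


def _mcar_dataset(seed=0, n=3000, rate=0.2, mean=10.0):
    """Normal target column correlated with a helper, MCAR-masked."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(mean, 2.0, n)
    x2 = 0.6 * x1 + rng.normal(0, 1, n)
    t = rng.uniform(1, 12, n)
    d = rng.integers(0, 2, n)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    X.loc[rng.uniform(size=n) < rate, "x1"] = np.nan
    meta = [FeatureMeta("x1", "continuous"), FeatureMeta("x2", "continuous")]
    return SurvivalDataset(t, d, X, meta)


class TestQuickpred:
    def test_correlated_candidate_included(self):
        ds = _mcar_dataset(seed=1)
        pm = quickpred(ds, min_correlation=0.1)
        assert pm.loc["x1", "x2"] == 1

    def test_fully_observed_row_is_zero(self):
        ds = _mcar_dataset(seed=2)
        pm = quickpred(ds)
        assert pm.loc["x2"].sum() == 0 and pm.loc["time"].sum() == 0

    def test_forced_in_overrides_correlation(self):
        ds = _mcar_dataset(seed=3)
        pm = quickpred(ds, min_correlation=0.99, forced_in=("event",))
        assert pm.loc["x1", "event"] == 1

    def test_monotone_in_threshold(self):
        ds = _mcar_dataset(seed=4)
        loose = quickpred(ds, min_correlation=0.05)
        tight = quickpred(ds, min_correlation=0.4)
        assert ((tight.to_numpy() == 1) <= (loose.to_numpy() == 1)).all()

    def test_zero_diagonal(self):
        pm = quickpred(_mcar_dataset(seed=5))
        assert np.diag(pm.to_numpy()).sum() == 0


class TestChooseM:
    @pytest.mark.parametrize("pct,m", [(33.5, 40), (0, 5), (71, 80), (5, 10)])
    def test_rule(self, pct, m):
        assert choose_m(pct) == m

    def test_range_check(self):
        with pytest.raises(ValueError):
            choose_m(100)


class TestMice:
    def test_complete_data_warns_identity(self):
        ds = weibull_cox_data(5, 100, [0.5])
        with pytest.warns(UserWarning, match="no missing"):
            stack = mice_impute(ds, quickpred(ds), m=3, iterations=2, seed=1)
        assert len(stack) == 3
        for s in stack:
            pd.testing.assert_frame_equal(s.features, ds.features)

    def test_observed_cells_bit_identical(self):
        ds = _mcar_dataset(seed=6)
        stack = mice_impute(ds, quickpred(ds), m=4, iterations=3, seed=2)
        obs = ds.features.notna().to_numpy()
        orig = ds.features.to_numpy()
        for s in stack:
            assert np.array_equal(s.features.to_numpy()[obs], orig[obs])
            assert s.is_complete

    def test_mcar_pooled_mean_unbiased(self):
        rng = np.random.default_rng(77)
        n = 4000
        x1_full = rng.normal(0.0, 1.0, n)
        x2 = 0.7 * x1_full + rng.normal(0, 1, n)
        X = pd.DataFrame({"x1": x1_full.copy(), "x2": x2})
        X.loc[rng.uniform(size=n) < 0.2, "x1"] = np.nan
        ds = SurvivalDataset(rng.uniform(1, 12, n), rng.integers(0, 2, n), X,
                             [FeatureMeta("x1", "continuous"),
                              FeatureMeta("x2", "continuous")])
        stack = mice_impute(ds, quickpred(ds), m=10, iterations=5, seed=3)
        pooled = np.mean([s.features["x1"].mean() for s in stack])
        se = x1_full.std() / np.sqrt(n)
        assert abs(pooled - x1_full.mean()) < 3 * se

    def test_binary_imputations_in_01(self):
        rng = np.random.default_rng(8)
        n = 800
        z = rng.standard_normal(n)
        b = (z + rng.standard_normal(n) > 0).astype(float)
        X = pd.DataFrame({"b": b, "z": z})
        X.loc[rng.uniform(size=n) < 0.3, "b"] = np.nan
        ds = SurvivalDataset(rng.uniform(1, 10, n), rng.integers(0, 2, n), X,
                             [FeatureMeta("b", "binary"),
                              FeatureMeta("z", "continuous")])
        stack = mice_impute(ds, quickpred(ds), m=3, iterations=4, seed=4)
        for s in stack:
            assert set(s.features["b"].unique()) <= {0.0, 1.0}

    def test_empty_predictor_row_rejected(self):
        ds = _mcar_dataset(seed=9)
        pm = quickpred(ds)
        pm.loc["x1"] = 0
        with pytest.raises(ValueError, match="x1"):
            mice_impute(ds, pm, m=2, iterations=1, seed=5)

    def test_stack_roundtrip(self, tmp_path):
        from survtab.imputation import ImputedStack

        ds = _mcar_dataset(seed=10, n=200)
        stack = mice_impute(ds, quickpred(ds), m=2, iterations=2, seed=6)
        stack.to_dir(tmp_path / "stack")
        back = ImputedStack.from_dir(tmp_path / "stack")
        assert back.m == 2 and back.iterations == 2
        pd.testing.assert_frame_equal(back.datasets[0].features,
                                      stack.datasets[0].features,
                                      check_exact=False, rtol=1e-12)


class TestBiasCheck:
    def test_no_missing_empty_report(self):
        ds = weibull_cox_data(11, 100, [0.5])
        stack = mice_impute.__wrapped__ if hasattr(mice_impute, "__wrapped__") else None
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = mice_impute(ds, quickpred(ds), m=2, iterations=1, seed=1)
        assert imputation_bias_check(ds, st).empty

    def test_mcar_passes_bias_rule(self):
        """MCAR 20% on a mean-10 column: <=5% bias nearly always."""
        passed = 0
        runs = 25
        for r in range(runs):
            ds = _mcar_dataset(seed=100 + r, n=3000)
            stack = mice_impute(ds, quickpred(ds), m=5, iterations=5,
                                seed=200 + r)
            rep = imputation_bias_check(ds, stack)
            passed += bool(rep.passed.all())
        assert passed / runs >= 0.9

    def test_broken_imputer_fails(self):
        ds = _mcar_dataset(seed=12, n=500, mean=10.0)
        stack = mice_impute(ds, quickpred(ds), m=2, iterations=2, seed=7)
        for s in stack.datasets:   # sabotage: constant-zero fill
            s.features.loc[ds.features["x1"].isna(), "x1"] = 0.0
        rep = imputation_bias_check(ds, stack)
        row = rep[rep.variable == "x1"].iloc[0]
        assert row.bias > 90 and not row.passed


class TestRubinPool:
    def test_worked_example(self):
        p = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert p.qbar == 2.0 and p.within == 1.0 and p.between == 1.0
        assert p.total == pytest.approx(1.0 + 4.0 / 3.0, abs=1e-12)

    def test_identical_estimates_zero_between(self):
        p = rubin_pool([0.5] * 6, [2.0] * 6)
        assert p.between == 0.0 and p.total == p.within
        assert np.isinf(p.df)

    def test_m2_example(self):
        p = rubin_pool([0.0, 0.0], [2.0, 4.0])
        assert p.qbar == 0.0 and p.within == 3.0 and p.between == 0.0
        assert p.total == 3.0

    def test_total_identity(self):
        rng = np.random.default_rng(13)
        q = rng.standard_normal(8)
        u = rng.uniform(0.5, 2.0, 8)
        p = rubin_pool(q, u)
        assert abs(p.total - (p.within + (1 + 1 / 8) * p.between)) < 1e-12

    def test_order_invariant(self):
        q = [0.3, 1.1, -0.4, 0.9]
        u = [1.0, 1.3, 0.7, 1.1]
        a = rubin_pool(q, u)
        b = rubin_pool(q[::-1], u[::-1])
        for field in ("qbar", "within", "between", "total", "df"):
            assert getattr(a, field) == pytest.approx(getattr(b, field),
                                                      rel=1e-12)

    def test_m1_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            rubin_pool([1.0], [1.0])


class _FakeFit:
    def __init__(self, terms, beta, cov):
        self.terms, self.beta, self.cov = terms, np.asarray(beta), np.asarray(cov)


class TestWaldComparePooled:
    def test_zero_extras_give_p_one(self):
        fits = [_FakeFit(["a", "b"], [0.5, 0.0], np.eye(2) * 0.1)
                for _ in range(5)]
        d1, p = wald_compare_pooled(fits, ["a"])
        assert d1 == 0.0 and p == 1.0

    def test_converges_to_complete_data_wald(self):
        """B -> 0: D1 approaches the ordinary Wald statistic / k."""
        ds = weibull_cox_data(14, 800, [0.6, -0.6, 0.0, 0.0],
                              censor_rate=0.05)
        fit = fit_cox(ds)
        m_fits = [fit] * 12       # identical imputations: B = 0 exactly
        d1, p = wald_compare_pooled(m_fits, ["x0", "x1"])
        idx = [2, 3]
        sub_cov = fit.cov[np.ix_(idx, idx)]
        wald = fit.beta[idx] @ np.linalg.inv(sub_cov) @ fit.beta[idx]
        assert d1 == pytest.approx(wald / 2, rel=0.02)

    def test_null_rejection_rate(self):
        """Noise extras: D1 rejects at ~ alpha over many replicates."""
        rej = 0
        reps = 150
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            ds = weibull_cox_data(3000 + r, 600, [0.5, 0.0, 0.0],
                                  censor_rate=0.05)
            # light MCAR on x1 then a quick chained-equations run
            feats = ds.features.copy()
            feats.loc[rng.uniform(size=600) < 0.1, "x1"] = np.nan
            dsm = SurvivalDataset(ds.time, ds.event, feats,
                                  list(ds.feature_meta))
            stack = mice_impute(dsm, quickpred(dsm), m=5, iterations=3,
                                seed=4000 + r)
            fits = [fit_cox(s) for s in stack]
            _, p = wald_compare_pooled(fits, ["x0"])
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_non_nested_rejected(self):
        fits = [_FakeFit(["a"], [0.1], [[0.1]]) for _ in range(3)]
        with pytest.raises(ValueError, match="subset"):
            wald_compare_pooled(fits, ["z"])
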