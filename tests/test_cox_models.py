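"""Cox fitting, the elastic net, tuning and stability selection."""

import numpy as np
import pandas as pd
import pytest

from survtab._coxcore import breslow_neg_log_pl
from survtab.cox_models import (
    consensus_candidates,
    coxsf_finalize,
    fit_cox,
    fit_coxnet,
    stability_select,
    tune_coxnet,
    SelectionProfile,
)
from survtab.datatypes import FeatureMeta, SurvivalDataset
from survtab.imputation import ImputedStack, quickpred
from tests.conftest import weibull_cox_data


def _as_stack(datasets):
    m = len(datasets)
    pm = quickpred(datasets[0]) * 0
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ImputedStack(datasets=[d.copy() for d in datasets], m=m,
                            iterations=0, seed=0, predictor_matrix=pm)


class TestFitCox:
    def test_matches_1d_grid_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        ds = SurvivalDataset(t, d, pd.DataFrame({"x": x}),
                             [FeatureMeta("x", "continuous")])
        grid = np.arange(-3, 3, 1e-4)
        nlls = [breslow_neg_log_pl(x * b, t, d, normalize=False) for b in grid]
        b_star = grid[int(np.argmin(nlls))]
        fit = fit_cox(ds)
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-3)

    def test_constant_feature_rejected(self):
        ds = weibull_cox_data(1, 50, [0.5])
        ds.features["x0"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(ds)

    def test_parameter_recovery_within_3se(self):
        ds = weibull_cox_data(2, 2000, [0.5, -0.5, 0.0], censor_rate=0.05)
        fit = fit_cox(ds)
        truth = np.array([0.5, -0.5, 0.0])
        assert (np.abs(fit.beta - truth) < 3 * fit.se).all()

    def test_matches_sksurv_breslow(self, small_cox_dataset):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        ds = small_cox_dataset
        y = np.array(list(zip(ds.event.astype(bool), ds.time)),
                     dtype=[("e", bool), ("t", float)])
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(
            ds.features.to_numpy(), y)
        fit = fit_cox(ds)
        assert np.allclose(fit.beta, ref.coef_, atol=1e-8)

    def test_covariance_symmetric_psd_and_gradient_small(self, small_cox_dataset):
        fit = fit_cox(small_cox_dataset)
        assert np.allclose(fit.cov, fit.cov.T)
        assert (np.linalg.eigvalsh(fit.cov) > 0).all()
        assert fit.grad_norm < 1e-8

    def test_loglik_concave_at_optimum(self, small_cox_dataset):
        ds = small_cox_dataset
        fit = fit_cox(ds)
        X = ds.features.to_numpy()
        rng = np.random.default_rng(3)
        direction = rng.standard_normal(len(fit.beta))
        direction /= np.linalg.norm(direction)

        def nll(b):
            return breslow_neg_log_pl(X @ b, ds.time, ds.event, normalize=False)

        mid = nll(fit.beta)
        for eps in (1e-2, 1e-1):
            assert nll(fit.beta + eps * direction) > mid
            assert nll(fit.beta - eps * direction) > mid

    def test_row_duplication_invariance(self, small_cox_dataset):
        ds = small_cox_dataset
        doubled = SurvivalDataset(
            np.r_[ds.time, ds.time], np.r_[ds.event, ds.event],
            pd.concat([ds.features] * 2, ignore_index=True),
            list(ds.feature_meta))
        f1, f2 = fit_cox(ds), fit_cox(doubled)
        assert np.allclose(f1.beta, f2.beta, atol=1e-6)


class TestFitCoxnet:
    def test_huge_lambda_all_zero(self, small_cox_dataset):
        beta = fit_coxnet(small_cox_dataset, alpha=0.5, lam=1e6)
        assert (beta == 0.0).all()

    def test_lambda_zero_matches_fit_cox(self, small_cox_dataset):
        beta = fit_coxnet(small_cox_dataset, alpha=0.5, lam=0.0,
                          max_iter=5000, tol=1e-9)
        ref = fit_cox(small_cox_dataset).beta
        assert np.abs(beta.to_numpy() - ref).max() < 1e-3

    def test_pure_ridge_never_sparsifies(self, small_cox_dataset):
        beta = fit_coxnet(small_cox_dataset, alpha=0.0, lam=0.05)
        assert (beta != 0.0).all()

    def test_no_events_rejected(self):
        ds = weibull_cox_data(4, 60, [0.5])
        ds.event[:] = 0
        with pytest.raises(ValueError, match="event"):
            fit_coxnet(ds, alpha=0.5, lam=0.1)

    def test_matches_sksurv_coxnet(self, small_cox_dataset):
        """Independent cross-check of the penalized solution path."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        ds = small_cox_dataset
        X = ds.features.to_numpy()
        y = np.array(list(zip(ds.event.astype(bool), ds.time)),
                     dtype=[("e", bool), ("t", float)])
        for lam in (0.05, 0.02):
            ref = CoxnetSurvivalAnalysis(alphas=[lam], l1_ratio=0.9,
                                         normalize=False, tol=1e-9)
            ref.fit(X, y)
            mine = fit_coxnet(ds, alpha=0.9, lam=lam, max_iter=5000, tol=1e-9)
            assert np.abs(mine.to_numpy() - ref.coef_.ravel()).max() < 2e-3

    def test_path_continuity_in_lambda(self, small_cox_dataset):
        lams = np.geomspace(0.2, 0.01, 12)
        prev = None
        for lam in lams:
            b = fit_coxnet(small_cox_dataset, alpha=0.5, lam=float(lam)).to_numpy()
            if prev is not None:
                assert np.abs(b - prev).max() < 0.25   # no jumps along the path
            prev = b


class TestTuneCoxnet:
    def test_single_point_grid(self, small_cox_dataset):
        res = tune_coxnet(_as_stack([small_cox_dataset]), [0.5], [0.05],
                          repeats=1, seed=0)
        assert res.alpha == 0.5 and res.lam == 0.05
        assert np.isfinite(res.mean_deviance.to_numpy()).all()

    def test_noise_features_prefer_largest_lambda(self):
        """Pure-noise features: CV deviance prefers the null (largest-lambda)
        model over grid points sparse enough to overfit."""
        hits = 0
        runs = 25
        for r in range(runs):
            ds = weibull_cox_data(600 + r, 400, [0.0] * 8, censor_rate=0.02)
            res = tune_coxnet(_as_stack([ds]), [0.9],
                              [0.2, 0.02, 0.005], repeats=1, seed=r)
            hits += res.lam == 0.2
        assert hits / runs >= 0.8

    def test_informative_features_recovered_at_optimum(self):
        ds = weibull_cox_data(7, 1500, [0.5, 0.5, 0.5, 0.5, 0.5] + [0.0] * 10,
                              censor_rate=0.02)
        res = tune_coxnet(_as_stack([ds]), [0.9], [0.3, 0.1, 0.03, 0.01],
                          repeats=1, seed=1)
        beta = fit_coxnet(ds, alpha=res.alpha, lam=res.lam)
        assert int((beta.iloc[:5] != 0).sum()) >= 4


class TestStabilitySelection:
    def _informative_stack(self, seed, m=3, n=800, p_true=3, p_noise=12):
        datasets = []
        for i in range(m):
            ds = weibull_cox_data(seed + i, n,
                                  [0.6] * p_true + [0.0] * p_noise,
                                  censor_rate=0.02)
            datasets.append(ds)
        return _as_stack(datasets)

    def test_reproducible_under_seed(self):
        stack = self._informative_stack(40)
        a = stability_select(stack, alpha=0.9, lam=0.05, seed=9)
        b = stability_select(stack, alpha=0.9, lam=0.05, seed=9)
        pd.testing.assert_frame_equal(a.split_counts, b.split_counts)

    def test_true_features_pass_noise_does_not(self):
        stack = self._informative_stack(50, m=4)
        prof = stability_select(stack, alpha=0.9, lam=0.06, seed=3)
        true_pass = prof.dataset_pass.iloc[:3]
        noise_pass = prof.dataset_pass.iloc[3:]
        assert (true_pass >= 3).all()
        assert noise_pass.median() <= 1

    def test_counts_bounded(self):
        stack = self._informative_stack(60, m=2)
        prof = stability_select(stack, alpha=0.9, lam=0.05, seed=1)
        assert prof.split_counts.to_numpy().max() <= 10
        assert prof.dataset_pass.max() <= 2


class TestConsensus:
    def _profile(self, counts, m=40):
        names = [f"f{i}" for i in range(len(counts))]
        return SelectionProfile(
            split_counts=pd.DataFrame(np.zeros((m, len(counts)), dtype=int),
                                      columns=names),
            dataset_pass=pd.Series(counts, index=names),
            n_splits=10, split_keep_threshold=8, m=m)

    def test_constructed_counts(self):
        prof = self._profile([40, 40, 31, 30])
        cands = consensus_candidates(prof, [30, 31, 40])
        assert len(cands[31]) == 3 and len(cands[30]) == 4 and len(cands[40]) == 2

    def test_nestedness(self):
        rng = np.random.default_rng(5)
        prof = self._profile(list(rng.integers(0, 41, 20)))
        cands = consensus_candidates(prof, [10, 20, 30, 40])
        for lo, hi in zip([10, 20, 30], [20, 30, 40]):
            assert set(cands[hi]) <= set(cands[lo])

    def test_threshold_range_checked(self):
        prof = self._profile([40, 10])
        with pytest.raises(ValueError):
            consensus_candidates(prof, [0])


class TestCoxsfFinalize:
    def _stack_with_truth(self, seed, m=4, n=900):
        datasets = [weibull_cox_data(seed + i, n,
                                     [0.6, -0.6, 0.5, 0.0, 0.0],
                                     censor_rate=0.02) for i in range(m)]
        return _as_stack(datasets)

    def test_noise_extension_rejected_usually(self):
        chosen_small = 0
        runs = 12
        for r in range(runs):
            stack = self._stack_with_truth(700 + 10 * r)
            _, chosen, _ = coxsf_finalize(
                stack, [["x0", "x1", "x2"], ["x0", "x1", "x2", "x3"]])
            chosen_small += chosen == ["x0", "x1", "x2"]
        assert chosen_small / runs >= 0.8

    def test_true_extension_accepted(self):
        stack = self._stack_with_truth(800)
        pooled, chosen, comps = coxsf_finalize(
            stack, [["x0", "x1"], ["x0", "x1", "x2"], ["x0", "x1", "x2", "x3"]])
        assert chosen == ["x0", "x1", "x2"]
        summary = pooled.summary()
        assert set(summary.index) == {"x0", "x1", "x2"}
        # pooled hazard ratios land near the generating values
        assert summary.loc["x0", "HR"] == pytest.approx(np.exp(0.6), rel=0.2)

    def test_identical_lists_rejected(self):
        stack = self._stack_with_truth(900, m=2, n=300)
        with pytest.raises(ValueError, match="distinct"):
            coxsf_finalize(stack, [["x0"], ["x0"]])

    def test_non_nested_rejected(self):
        stack = self._stack_with_truth(901, m=2, n=300)
        with pytest.raises(ValueError, match="nested"):
            coxsf_finalize(stack, [["x0"], ["x1", "x2"]])
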