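"""Penalized and unpenalized Cox proportional-hazards fitting.

``fit_cox`` maximizes the Breslow partial likelihood by Newton iteration
and reports the observed-information variance-covariance matrix.
``fit_coxnet`` minimizes the elastic-net-penalized objective

    -(1/n) log PL(beta) + lambda * [alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2]

by accelerated proximal gradient (FISTA with backtracking); the soft
threshold produces exact zeros, so "selected" means coefficient != 0
exactly.  On top of these sit cross-validated deviance tuning of
(alpha, lambda), the two-level stability-selection procedure (>= 8 of 10
training splits within an imputed dataset, then a consensus count across
imputed datasets), and the Rubin-pooled final model with its nested Wald
comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold

from ._coxcore import (
    RiskSetIndex,
    breslow_neg_log_pl,
    breslow_eta_gradient,
    cox_gradient_information,
)
from .datatypes import SurvivalDataset, child_seed
from .imputation import rubin_pool, wald_compare_pooled

__all__ = [
    "CoxFit",
    "fit_cox",
    "fit_coxnet",
    "EnTuningResult",
    "tune_coxnet",
    "SelectionProfile",
    "stability_select",
    "consensus_candidates",
    "PooledCoxFit",
    "coxsf_finalize",
]


@dataclass
class CoxFit:
    """Converged Cox partial-likelihood fit (Breslow ties)."""

    terms: list[str]
    beta: np.ndarray
    cov: np.ndarray
    log_partial_likelihood: float
    n_iter: int
    grad_norm: float
    tie_method: str = "breslow"
    flags: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Linear log-risk score x beta for new rows."""
        return features[self.terms].to_numpy(dtype=float) @ self.beta

    def summary(self, z: float = 1.959963984540054) -> pd.DataFrame:
        se = self.se
        hr = np.exp(self.beta)
        pvals = 2 * stats.norm.sf(np.abs(self.beta / se))
        return pd.DataFrame({
            "term": self.terms, "coef": self.beta, "se": se, "HR": hr,
            "ci_low": np.exp(self.beta - z * se),
            "ci_high": np.exp(self.beta + z * se), "p": pvals,
        }).set_index("term")


def _design(dataset: SurvivalDataset, terms) -> tuple[np.ndarray, list[str]]:
    terms = list(terms) if terms is not None else dataset.feature_names
    X = dataset.features[terms].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("Cox fitting requires complete features")
    return X, terms


def fit_cox(dataset: SurvivalDataset, terms=None, tol: float = 1e-8,
            max_iter: int = 100) -> CoxFit:
    """Newton--Raphson maximization of the Breslow partial likelihood."""
    X, terms = _design(dataset, terms)
    if dataset.event.sum() < 1:
        raise ValueError("at least one event is required")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [terms[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant feature(s): {bad}")
    index = RiskSetIndex.build(dataset.time, dataset.event)
    p = X.shape[1]
    beta = np.zeros(p)
    flags: list[str] = []
    nll, grad, info = cox_gradient_information(X, beta, index)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), -grad)
        except np.linalg.LinAlgError:
            flags.append("singular information")
            break
        # step-halving line search on the negative log PL
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            nll_new, grad_new, info_new = cox_gradient_information(X, cand, index)
            if nll_new <= nll + 1e-12:
                break
            scale *= 0.5
        beta, nll, grad, info = cand, nll_new, grad_new, info_new
        if np.linalg.norm(grad, ord=np.inf) < tol:
            break
    if np.any(np.abs(beta) > 25):
        flags.append("monotone likelihood suspected: a covariate may perfectly "
                     "separate the event order")
        warnings.warn(flags[-1], UserWarning, stacklevel=2)
    gnorm = float(np.linalg.norm(grad, ord=np.inf))
    if gnorm >= tol and "singular information" not in flags:
        flags.append("did not reach gradient tolerance")
    cov = np.linalg.inv(info + 1e-12 * np.eye(p))
    cov = 0.5 * (cov + cov.T)
    return CoxFit(terms=terms, beta=beta, cov=cov, log_partial_likelihood=-nll,
                  n_iter=it, grad_norm=gnorm, flags=flags)


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------


def _coxnet_solve(X: np.ndarray, index: RiskSetIndex, alpha: float, lam: float,
                  beta0: np.ndarray | None = None, max_iter: int = 1000,
                  tol: float = 1e-7) -> np.ndarray:
    """FISTA with backtracking on the penalized (1/n)-scaled objective."""
    n, p = X.shape
    n_ev = index.n_events
    if n_ev == 0:
        raise ValueError("no events: penalized partial likelihood undefined")
    ridge = lam * (1.0 - alpha)
    l1 = lam * alpha

    def smooth(b):
        eta = X @ b
        return (breslow_neg_log_pl(eta, index=index, normalize=False) / n
                + 0.5 * ridge * float(b @ b))

    def smooth_grad(b):
        eta = X @ b
        g_eta = breslow_eta_gradient(eta, index=index, normalize=False)
        return X.T @ g_eta / n + ridge * b

    def prox(b, step):
        return np.sign(b) * np.maximum(np.abs(b) - step * l1, 0.0)

    beta = np.zeros(p) if beta0 is None else beta0.copy()
    y = beta.copy()
    t_mom = 1.0
    L = max(1.0, float((X**2).sum(axis=0).max()) / n)
    f_prev = smooth(beta) + l1 * np.abs(beta).sum()
    for _ in range(max_iter):
        g = smooth_grad(y)
        fy = smooth(y)
        while True:
            z = prox(y - g / L, 1.0 / L)
            dz = z - y
            if smooth(z) <= fy + g @ dz + 0.5 * L * float(dz @ dz) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom**2))
        beta_new = z
        f_new = smooth(beta_new) + l1 * np.abs(beta_new).sum()
        if f_new > f_prev + 1e-12:   # objective increased: restart momentum
            y = beta_new.copy()
            t_mom = 1.0
        else:
            y = beta_new + ((t_mom - 1.0) / t_new) * (beta_new - beta)
            t_mom = t_new
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        f_prev = min(f_prev, f_new)
        if delta < tol * max(1.0, np.max(np.abs(beta))):
            break
        L = max(L * 0.9, 1e-3)
    return beta


def fit_coxnet(dataset: SurvivalDataset, alpha: float, lam: float, terms=None,
               beta0: np.ndarray | None = None, max_iter: int = 1000,
               tol: float = 1e-7) -> pd.Series:
    """Elastic-net penalized Cox coefficients (exact zeros via soft threshold)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X, terms = _design(dataset, terms)
    if dataset.event.sum() < 1:
        raise ValueError("no events in dataset")
    index = RiskSetIndex.build(dataset.time, dataset.event)
    beta = _coxnet_solve(X, index, alpha, lam, beta0=beta0, max_iter=max_iter, tol=tol)
    return pd.Series(beta, index=terms)


@dataclass
class EnTuningResult:
    """Cross-validated deviance surface and the selected (alpha, lambda)."""

    alpha_grid: list[float]
    lambda_grid: list[float]
    mean_deviance: pd.DataFrame      # index alpha, columns lambda
    alpha: float
    lam: float


def _stratified_folds(event: np.ndarray, folds: int, repeats: int, seed: int):
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed % (2**31 - 1))
    dummy = np.zeros(len(event))
    return list(rskf.split(dummy, event))


def tune_coxnet(stack, alpha_grid, lambda_grid, folds: int = 5, repeats: int = 2,
                seed: int = 0, terms=None, row_idx: np.ndarray | None = None,
                max_datasets: int | None = None) -> EnTuningResult:
    """Pick (alpha, lambda) minimizing repeated-CV penalized deviance.

    Deviance follows the V&VH convention: for a fold k with model beta_k
    fitted on the fold complement, the contribution is
    -2 [ logPL_all(beta_k) - logPL_complement(beta_k) ], summed over folds
    and averaged over repeats and imputed datasets.  Ties prefer the
    largest lambda (then largest alpha), i.e. the most parsimonious model.
    """
    datasets = list(stack)
    if max_datasets is not None:
        datasets = datasets[:max_datasets]
    alphas = sorted({float(a) for a in alpha_grid})
    lambdas = sorted({float(l) for l in lambda_grid}, reverse=True)
    if not alphas or not lambdas:
        raise ValueError("grids must be non-empty")
    dev = np.zeros((len(alphas), len(lambdas)))
    count = np.zeros_like(dev)
    for di, ds in enumerate(datasets):
        if row_idx is not None:
            ds = ds.subset(row_idx)
        X, used_terms = _design(ds, terms)
        full_index = RiskSetIndex.build(ds.time, ds.event)
        splits = _stratified_folds(ds.event, folds, repeats,
                                   child_seed(seed, "tune", di))
        for tr, _te in splits:
            Xtr = X[tr]
            idx_tr = RiskSetIndex.build(ds.time[tr], ds.event[tr])
            for ai, a in enumerate(alphas):
                beta_warm = None
                for li, l in enumerate(lambdas):
                    beta = _coxnet_solve(Xtr, idx_tr, a, l, beta0=beta_warm,
                                         max_iter=400, tol=1e-5)
                    beta_warm = beta
                    ll_all = -breslow_neg_log_pl(X @ beta, index=full_index,
                                                 normalize=False)
                    ll_tr = -breslow_neg_log_pl(Xtr @ beta, index=idx_tr,
                                                normalize=False)
                    d = -2.0 * (ll_all - ll_tr)
                    if np.isfinite(d):
                        dev[ai, li] += d
                        count[ai, li] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dev = dev / count
    if not np.isfinite(mean_dev).any():
        raise ValueError("all grid points produced non-finite deviance")
    best = np.nanmin(mean_dev)
    cand = np.argwhere(mean_dev <= best + 1e-10)
    # prefer largest lambda, then largest alpha (lambdas sorted descending)
    cand = sorted(cand.tolist(), key=lambda ij: (ij[1], -ij[0]))
    ai, li = cand[0]
    table = pd.DataFrame(mean_dev, index=alphas, columns=lambdas)
    return EnTuningResult(alpha_grid=alphas, lambda_grid=lambdas,
                          mean_deviance=table, alpha=alphas[ai], lam=lambdas[li])


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionProfile:
    """Per-imputation split-selection counts and cross-imputation tallies."""

    split_counts: pd.DataFrame     # rows: imputation id, cols: features (0..n_splits)
    dataset_pass: pd.Series        # per feature: # imputed datasets passing threshold
    n_splits: int
    split_keep_threshold: int
    m: int

    def to_csv(self, path) -> None:
        self.split_counts.to_csv(path)


def stability_select(stack, alpha: float, lam: float, n_splits: int = 10,
                     split_keep_threshold: int = 8, seed: int = 0, terms=None,
                     row_idx: np.ndarray | None = None) -> SelectionProfile:
    """Two-level stability selection across splits and imputed datasets.

    Within each imputed dataset, 10 training sets (2x repeated 5-fold CV,
    each 80% of rows) are fitted with the elastic net at (alpha, lambda);
    a feature passes the dataset when selected (nonzero) in at least
    ``split_keep_threshold`` of the splits.  The profile also tallies in
    how many of the m datasets each feature passes.
    """
    if split_keep_threshold > n_splits:
        raise ValueError("split threshold cannot exceed the number of splits")
    if n_splits % 5 != 0:
        raise ValueError("n_splits must be repeats x 5 for the repeated 5-fold scheme")
    repeats = n_splits // 5
    datasets = list(stack)
    rows = []
    feature_names = None
    for di, ds in enumerate(datasets):
        if row_idx is not None:
            ds = ds.subset(row_idx)
        X, used_terms = _design(ds, terms)
        feature_names = used_terms
        splits = _stratified_folds(ds.event, 5, repeats,
                                   child_seed(seed, "stability", di))
        counts = np.zeros(len(used_terms), dtype=int)
        for tr, _te in splits:
            idx_tr = RiskSetIndex.build(ds.time[tr], ds.event[tr])
            beta = _coxnet_solve(X[tr], idx_tr, alpha, lam, max_iter=400, tol=1e-5)
            counts += (beta != 0.0).astype(int)
        rows.append(counts)
    split_counts = pd.DataFrame(rows, columns=feature_names)
    dataset_pass = (split_counts >= split_keep_threshold).sum(axis=0)
    return SelectionProfile(split_counts=split_counts, dataset_pass=dataset_pass,
                            n_splits=n_splits,
                            split_keep_threshold=split_keep_threshold,
                            m=len(datasets))


def consensus_candidates(profile: SelectionProfile, thresholds) -> dict[int, list[str]]:
    """Feature lists passing at least t imputed datasets, per threshold t.

    Lists are nested: a higher threshold yields a subset of a lower one.
    """
    out = {}
    for t in thresholds:
        if not (1 <= t <= profile.m):
            raise ValueError(f"threshold {t} outside [1, m={profile.m}]")
        out[int(t)] = list(profile.dataset_pass.index[profile.dataset_pass >= t])
    return out


# ---------------------------------------------------------------------------
# Pooled final model
# ---------------------------------------------------------------------------


@dataclass
class PooledCoxFit:
    """Rubin-pooled Cox model across imputed datasets."""

    terms: list[str]
    qbar: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total: np.ndarray
    df: np.ndarray
    m: int

    def summary(self, z: float = 1.959963984540054) -> pd.DataFrame:
        se = np.sqrt(self.total)
        pvals = 2 * stats.norm.sf(np.abs(self.qbar / se))
        return pd.DataFrame({
            "term": self.terms,
            "HR": np.exp(self.qbar),
            "ci_low": np.exp(self.qbar - z * se),
            "ci_high": np.exp(self.qbar + z * se),
            "p": pvals,
        }).set_index("term")


def pool_cox_fits(fits) -> PooledCoxFit:
    """Rubin's rules applied coefficient-wise to per-imputation Cox fits."""
    fits = list(fits)
    terms = list(fits[0].terms)
    pooled = [rubin_pool([f.beta[i] for f in fits],
                         [f.cov[i, i] for f in fits]) for i in range(len(terms))]
    return PooledCoxFit(
        terms=terms,
        qbar=np.array([p.qbar for p in pooled]),
        within=np.array([p.within for p in pooled]),
        between=np.array([p.between for p in pooled]),
        total=np.array([p.total for p in pooled]),
        df=np.array([p.df for p in pooled]),
        m=len(fits),
    )


def coxsf_finalize(stack, candidate_lists, alpha_level: float = 0.05,
                   row_idx: np.ndarray | None = None, mode: str = "lowest_p"):
    """Choose among nested candidate feature lists and pool the winner.

    Each list is fitted per imputed dataset with :func:`fit_cox`; adjacent
    nested pairs are compared with the pooled D1 Wald test on the extra
    coefficients.  The default choice takes the comparison with the
    lowest p-value and keeps its larger list when that p-value clears
    ``alpha_level``, falling back to the smallest list otherwise
    (``mode='sequential'`` instead walks up while each addition is
    significant).  Returns (PooledCoxFit, chosen_terms, comparisons).
    """
    lists = sorted((list(c) for c in candidate_lists), key=len)
    if len(lists) < 2:
        raise ValueError("need at least two candidate lists")
    for a, b in zip(lists[:-1], lists[1:]):
        if len(set(a)) == len(set(b)):
            raise ValueError("candidate lists must be distinct")
        if not set(a).issubset(b):
            raise ValueError("candidate lists must be nested")
    datasets = list(stack)
    if row_idx is not None:
        datasets = [ds.subset(row_idx) for ds in datasets]

    fits_per_list = {tuple(c): [fit_cox(ds, terms=c) for ds in datasets]
                     for c in lists}
    comparisons = []
    for small, big in zip(lists[:-1], lists[1:]):
        d1, p = wald_compare_pooled(fits_per_list[tuple(big)], small)
        comparisons.append({"smaller": small, "larger": big, "D1": d1, "p": p})
    if mode == "lowest_p":
        best = min(comparisons, key=lambda c: c["p"])
        chosen = best["larger"] if best["p"] < alpha_level else lists[0]
    elif mode == "sequential":
        chosen = lists[0]
        for comp in comparisons:
            if comp["smaller"] == chosen and comp["p"] < alpha_level:
                chosen = comp["larger"]
            else:
                break
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pooled = pool_cox_fits(fits_per_list[tuple(chosen)])
    return pooled, chosen, comparisons
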