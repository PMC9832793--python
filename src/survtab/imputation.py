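"""Multiple imputation by chained equations with Rubin-rules pooling.

The imputation model is built once on the full predictor set: quickpred
screening picks, for each incomplete variable, the candidates whose
correlation with the target (or with the target's missingness indicator)
clears a threshold, always forcing in the outcome (follow-up time, event)
and any designated confounders.  Chains are initialized from observed
marginals and swept ``iterations`` times; continuous targets are imputed
by predictive mean matching (5 donors, Bayesian parameter draw), binary
targets by a logistic-model draw.  The outcome itself is never imputed.

Pooling across the m completed datasets follows Rubin's rules
(total variance T = W + (1 + 1/m) B) and nested pooled models are
compared with the multi-parameter D1 Wald statistic.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SurvivalDataset, child_rng

__all__ = [
    "quickpred",
    "choose_m",
    "mice_impute",
    "ImputedStack",
    "imputation_bias_check",
    "rubin_pool",
    "PooledEstimate",
    "wald_compare_pooled",
]

_OUTCOME_VARS = ("time", "event")


def _full_table(dataset: SurvivalDataset) -> pd.DataFrame:
    """Features plus outcome columns, as one frame."""
    df = dataset.features.copy()
    df["time"] = dataset.time
    df["event"] = dataset.event.astype(float)
    return df


def quickpred(
    dataset: SurvivalDataset,
    min_correlation: float = 0.1,
    min_usable_fraction: float = 0.0,
    forced_in: tuple[str, ...] = _OUTCOME_VARS,
) -> pd.DataFrame:
    """Correlation/usable-cases screening of imputation predictors.

    Returns a square 0/1 frame over all variables (features plus the
    outcome columns ``time`` and ``event``): entry (target, candidate) = 1
    means the candidate is used to impute the target.  A candidate
    qualifies when max(|cor(candidate, target)| over complete pairs,
    |cor(candidate, missingness indicator of target)|) >= min_correlation
    and the fraction of target-missing rows where the candidate is
    observed is >= min_usable_fraction.  ``forced_in`` variables are
    always predictors of every incomplete target.  Fully observed
    variables get all-zero rows (they are never imputed).
    """
    df = _full_table(dataset)
    if df.shape[1] < 2:
        raise ValueError("quickpred needs at least two variables")
    cols = list(df.columns)
    miss = df.isna()
    # pairwise-complete correlations among variables and with missingness
    # indicators, computed in one pass (constant columns give NaN -> treated 0)
    ind = miss.astype(float)
    ind.columns = [f"__miss__{c}" for c in cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = pd.concat([df, ind], axis=1).corr(min_periods=3)
    c_vv = corr.loc[cols, cols].abs().fillna(0.0).to_numpy()
    c_vm = corr.loc[[f"__miss__{c}" for c in cols], cols].abs().fillna(0.0).to_numpy()
    # usable-cases fraction: P(candidate observed | target missing)
    mm = miss.to_numpy(dtype=float)
    obs = 1.0 - mm
    n_miss = mm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        usable = (mm.T @ obs) / np.where(n_miss > 0, n_miss, np.nan)[:, None]
    strength = np.maximum(c_vv, c_vm)  # rows: target, cols: candidate
    keep = (strength >= min_correlation) & (np.nan_to_num(usable, nan=1.0)
                                            >= min_usable_fraction)
    for c in forced_in:
        if c in cols:
            keep[:, cols.index(c)] = True
    np.fill_diagonal(keep, False)
    incomplete = miss.any(axis=0).to_numpy() & ~np.isin(cols, _OUTCOME_VARS)
    keep[~incomplete, :] = False   # fully observed variables are never imputed
    return pd.DataFrame(keep.astype(int), index=cols, columns=cols)


def _safe_corr(a: np.ndarray, b: np.ndarray, name_a: str, name_b: str,
               pairwise: bool = False) -> float:
    if pairwise:
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        # constant column: correlation undefined, treated as 0
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def choose_m(max_missing_pct: float) -> int:
    """Number of imputations from the maximum per-variable missing percentage.

    Rounded up to the next multiple of 10, with a floor of 5 (so a 33.5%
    maximum yields 40 imputations).
    """
    if not (0 <= max_missing_pct < 100):
        raise ValueError("max_missing_pct must lie in [0, 100)")
    return max(5, 10 * math.ceil(max_missing_pct / 10.0))


@dataclass
class ImputedStack:
    """m completed copies of one dataset sharing a provenance record."""

    datasets: list[SurvivalDataset]
    m: int
    iterations: int
    seed: int
    predictor_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.datasets) != self.m:
            raise ValueError("stack must contain exactly m datasets")
        for ds in self.datasets:
            if not ds.is_complete:
                raise ValueError("imputed datasets must be complete")

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return self.m

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, ds in enumerate(self.datasets):
            ds.to_csv(path / f"imputation_{i:03d}.csv")
        manifest = {
            "m": self.m, "iterations": self.iterations, "seed": self.seed,
            "predictor_matrix": {
                "index": list(self.predictor_matrix.index),
                "values": self.predictor_matrix.to_numpy().tolist(),
            },
        }
        (path / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ImputedStack":
        path = Path(path)
        man = json.loads((path / "manifest.json").read_text())
        datasets = [SurvivalDataset.from_csv(path / f"imputation_{i:03d}.csv")
                    for i in range(man["m"])]
        pm = pd.DataFrame(man["predictor_matrix"]["values"],
                          index=man["predictor_matrix"]["index"],
                          columns=man["predictor_matrix"]["index"])
        return cls(datasets=datasets, m=man["m"], iterations=man["iterations"],
                   seed=man["seed"], predictor_matrix=pm)


def mice_impute(
    dataset: SurvivalDataset,
    predictor_matrix: pd.DataFrame,
    m: int,
    iterations: int = 20,
    seed: int = 0,
    pmm_donors: int = 5,
) -> ImputedStack:
    """Chained-equations multiple imputation.

    Runs m independent chains for ``iterations`` sweeps each.  Continuous
    targets use predictive mean matching with ``pmm_donors`` donors and a
    Bayesian regression-parameter draw; binary targets use a logistic
    draw.  Observed cells are never altered.
    """
    df = _full_table(dataset)
    kinds = dataset.kinds()
    incomplete = [c for c in dataset.feature_names if df[c].isna().any()]
    if not incomplete:
        warnings.warn("dataset has no missing cells; returning identical copies",
                      UserWarning, stacklevel=2)
        return ImputedStack(datasets=[dataset.copy() for _ in range(m)], m=m,
                            iterations=iterations, seed=seed,
                            predictor_matrix=predictor_matrix)
    for var in incomplete:
        preds = predictor_matrix.loc[var]
        if preds.sum() == 0:
            raise ValueError(f"incomplete variable {var!r} has an empty predictor row")

    completed = []
    for chain in range(m):
        rng = child_rng(seed, "mice", chain)
        work = df.copy()
        # initialize missing cells from observed marginals
        for var in incomplete:
            obs = df[var].dropna().to_numpy()
            nmis = int(df[var].isna().sum())
            work.loc[df[var].isna(), var] = rng.choice(obs, size=nmis, replace=True)
        for _ in range(iterations):
            for var in incomplete:
                preds = [c for c in predictor_matrix.columns
                         if predictor_matrix.loc[var, c] == 1]
                mis = df[var].isna().to_numpy()
                Z = work[preds].to_numpy(dtype=float)
                Z = np.hstack([np.ones((len(Z), 1)), Z])
                y_obs = df[var].to_numpy(dtype=float)[~mis]
                if kinds.get(var) == "binary":
                    imp = _logistic_draw(Z[~mis], y_obs, Z[mis], rng)
                else:
                    imp = _pmm_draw(Z[~mis], y_obs, Z[mis], rng, pmm_donors)
                work.loc[mis, var] = imp
        feats = work[dataset.feature_names].astype(float)
        completed.append(SurvivalDataset(
            time=dataset.time.copy(), event=dataset.event.copy(),
            features=feats, feature_meta=list(dataset.feature_meta)))
    return ImputedStack(datasets=completed, m=m, iterations=iterations, seed=seed,
                        predictor_matrix=predictor_matrix)


def _ridge_solve(Z: np.ndarray, y: np.ndarray, eps: float = 1e-8):
    q = Z.shape[1]
    A = Z.T @ Z + eps * np.eye(q)
    coef = np.linalg.solve(A, Z.T @ y)
    return coef, A


def _pmm_draw(Z_obs, y_obs, Z_mis, rng, donors: int) -> np.ndarray:
    """Predictive mean matching (type-1) with a Bayesian beta draw."""
    n_obs, q = Z_obs.shape
    coef, A = _ridge_solve(Z_obs, y_obs)
    resid = y_obs - Z_obs @ coef
    dfree = max(n_obs - q, 1)
    sigma2 = float(resid @ resid) / dfree
    sigma2_star = sigma2 * dfree / max(rng.chisquare(dfree), 1e-12)
    cov = np.linalg.inv(A)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(q))
    beta_star = coef + math.sqrt(sigma2_star) * (L @ rng.standard_normal(q))
    yhat_obs = Z_obs @ coef
    yhat_mis = Z_mis @ beta_star
    order = np.argsort(yhat_obs, kind="stable")
    sorted_hat = yhat_obs[order]
    out = np.empty(len(yhat_mis))
    k = min(donors, n_obs)
    for i, v in enumerate(yhat_mis):
        pos = np.searchsorted(sorted_hat, v)
        lo = max(0, pos - k)
        hi = min(n_obs, pos + k)
        window = np.arange(lo, hi)
        d = np.abs(sorted_hat[window] - v)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        donor = order[rng.choice(nearest)]
        out[i] = y_obs[donor]
    return out


def _logistic_draw(Z_obs, y_obs, Z_mis, rng, ridge: float = 1e-4,
                   max_iter: int = 30) -> np.ndarray:
    """Logistic-model imputation draw for a binary target."""
    n, q = Z_obs.shape
    beta = np.zeros(q)
    for _ in range(max_iter):
        eta = np.clip(Z_obs @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-8)
        H = (Z_obs * w[:, None]).T @ Z_obs + ridge * np.eye(q)
        g = Z_obs.T @ (y_obs - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-6:
            break
    eta = np.clip(Z_obs @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-8)
    H = (Z_obs * w[:, None]).T @ Z_obs + ridge * np.eye(q)
    cov = np.linalg.inv(H)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(q))
    beta_star = beta + L @ rng.standard_normal(q)
    p_mis = 1.0 / (1.0 + np.exp(-np.clip(Z_mis @ beta_star, -30, 30)))
    return (rng.uniform(size=len(Z_mis)) < p_mis).astype(float)


def imputation_bias_check(original: SurvivalDataset, stack: ImputedStack,
                          threshold_pct: float = 5.0) -> pd.DataFrame:
    """Mean-bias check of imputed values against observed cells.

    For each imputed variable: bias% = 100 |mean(imputed cells pooled over
    the m datasets) - mean(observed cells)| / |mean(observed cells)|; the
    variable passes when bias% <= threshold (default 5%).  When the
    observed mean is 0 the absolute difference is reported instead.
    """
    rows = []
    for var in original.feature_names:
        mis = original.features[var].isna()
        if not mis.any():
            continue
        obs_mean = float(original.features[var].dropna().mean())
        imput_vals = np.concatenate([
            ds.features.loc[mis, var].to_numpy(dtype=float) for ds in stack
        ])
        imp_mean = float(imput_vals.mean())
        if obs_mean == 0.0:
            bias = abs(imp_mean - obs_mean)
            rows.append((var, bias, "absolute", bias <= threshold_pct / 100.0))
        else:
            bias = 100.0 * abs(imp_mean - obs_mean) / abs(obs_mean)
            rows.append((var, bias, "percent", bias <= threshold_pct))
    return pd.DataFrame(rows, columns=["variable", "bias", "scale", "passed"])


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-rules pooled scalar estimate."""

    qbar: float
    within: float
    between: float
    total: float
    df: float

    @property
    def se(self) -> float:
        return math.sqrt(self.total)


def rubin_pool(estimates, variances, df_complete: float | None = None) -> PooledEstimate:
    """Rubin's rules for a scalar parameter across m imputations.

    Qbar = mean estimate; W = mean within-imputation variance; B = sample
    variance of the estimates; T = W + (1 + 1/m) B.  Degrees of freedom
    use the large-sample formula by default, or the Barnard--Rubin
    small-sample correction when ``df_complete`` is supplied.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if len(q) != len(u):
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B == 0.0 or T == 0.0:
        nu = float("inf")
    else:
        lam = (1.0 + 1.0 / m) * B / T
        nu_large = (m - 1) / lam**2
        if df_complete is None:
            nu = nu_large
        else:
            nu_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
            nu = 1.0 / (1.0 / nu_large + 1.0 / nu_obs)
    return PooledEstimate(qbar=qbar, within=W, between=B, total=T, df=nu)


def wald_compare_pooled(full_fits, nested_terms) -> tuple[float, float]:
    """D1 multi-parameter Wald comparison of nested pooled models.

    ``full_fits`` are per-imputation fits of the FULL model (objects with
    ``terms``, ``beta`` and ``cov``); ``nested_terms`` is a subset of the
    full model's terms.  Tests whether the k extra coefficients are
    jointly zero: r = (1 + 1/m) tr(B Wbar^-1)/k; D1 = Qbar' Wbar^-1 Qbar /
    (k (1+r)); reference F(k, nu1) with the standard D1 denominator df.
    Returns (D1, p).
    """
    fits = list(full_fits)
    m = len(fits)
    if m < 2:
        raise ValueError("need fits from at least two imputations")
    full_terms = list(fits[0].terms)
    nested = set(nested_terms)
    if not nested.issubset(full_terms):
        raise ValueError("nested model's terms must be a subset of the full model's")
    extra_idx = [i for i, t in enumerate(full_terms) if t not in nested]
    k = len(extra_idx)
    if k < 1:
        raise ValueError("nested comparison needs at least one extra parameter")
    Q = np.stack([np.asarray(f.beta)[extra_idx] for f in fits])       # m x k
    U = np.stack([np.asarray(f.cov)[np.ix_(extra_idx, extra_idx)] for f in fits])
    qbar = Q.mean(axis=0)
    Wbar = U.mean(axis=0)
    cond = np.linalg.cond(Wbar)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"within-imputation covariance is singular (condition number {cond:.3g})")
    dev = Q - qbar
    B = dev.T @ dev / (m - 1)
    Winv = np.linalg.inv(Wbar)
    r = (1.0 + 1.0 / m) * float(np.trace(B @ Winv)) / k
    D1 = float(qbar @ Winv @ qbar) / (k * (1.0 + r))
    t = k * (m - 1)
    if r <= 0:
        nu1 = np.inf
    elif t > 4:
        nu1 = 4.0 + (t - 4.0) * (1.0 + (1.0 - 2.0 / t) / r) ** 2
    else:
        nu1 = 0.5 * t * (1.0 + 1.0 / k) * (1.0 + 1.0 / r) ** 2
    if not np.isfinite(nu1):
        p = float(stats.chi2.sf(k * D1, k))
    else:
        p = float(stats.f.sf(D1, k, nu1))
    if D1 == 0.0:
        p = 1.0
    return D1, p
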