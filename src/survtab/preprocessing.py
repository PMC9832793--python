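"""Feature transformations, collinearity pruning and the PH diagnostic.

Categorical predictors are dichotomized to 0/1; skewed positive
predictors get a base-2 logarithm; features are min-max normalized with
statistics computed on training rows only; multicollinearity is pruned by
sequentially removing the feature with the largest variance inflation
factor (VIF) above a threshold; and the proportional-hazards assumption
is checked with a score test on scaled Schoenfeld residuals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._coxcore import RiskSetIndex, km_survival, km_eval, schoenfeld_residuals

__all__ = [
    "dichotomize",
    "log2_shift",
    "NormalizationStats",
    "fit_minmax",
    "apply_minmax",
    "compute_vif",
    "prune_collinear",
    "VifReport",
    "schoenfeld_ph_check",
]


def dichotomize(column: pd.Series, positive_level) -> pd.Series:
    """Map a categorical column to 1 where value == positive_level, else 0.

    Missing values stay missing.  An absent positive level yields an
    all-zero column with a warning.
    """
    observed = column.dropna()
    if observed.nunique() < 1:
        raise ValueError("column has no observed levels")
    if positive_level not in set(observed):
        warnings.warn(
            f"positive level {positive_level!r} not among observed levels; "
            "result is all zeros", UserWarning, stacklevel=2,
        )
    out = (column == positive_level).astype(float)
    out[column.isna()] = np.nan
    return out


def log2_shift(column: pd.Series, variant: str = "literal") -> pd.Series:
    """Base-2 log transform for skewed positive predictors.

    ``literal`` computes y = log2(x) + 1 (requires x > 0); ``shifted``
    computes y = log2(x + 1) (requires x >= 0), a variant provided for
    columns that contain zeros.  Missing values stay missing.
    """
    x = pd.to_numeric(column, errors="coerce")
    obs = x.dropna()
    if variant == "literal":
        bad = int((obs <= 0).sum())
        if bad:
            raise ValueError(
                f"{bad} observed cells are <= 0; the literal log2(x)+1 form is "
                "undefined there (consider variant='shifted')"
            )
        return np.log2(x) + 1.0
    elif variant == "shifted":
        bad = int((obs < 0).sum())
        if bad:
            raise ValueError(f"{bad} observed cells are negative; log2(x+1) undefined")
        return np.log2(x + 1.0)
    raise ValueError(f"unknown log variant {variant!r}")


@dataclass
class NormalizationStats:
    """Per-feature training min/max, tagged with the split that made them."""

    mins: pd.Series
    maxs: pd.Series
    split_id: str = "train"

    def __post_init__(self) -> None:
        if (self.maxs < self.mins).any():
            raise ValueError("max < min in normalization stats")

    def to_json(self) -> str:
        return json.dumps({
            "split_id": self.split_id,
            "mins": self.mins.to_dict(),
            "maxs": self.maxs.to_dict(),
        })

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(mins=pd.Series(d["mins"]), maxs=pd.Series(d["maxs"]),
                   split_id=d["split_id"])


def fit_minmax(train: pd.DataFrame, split_id: str = "train") -> NormalizationStats:
    """Column-wise min/max over training rows (missing cells ignored)."""
    if len(train) == 0:
        raise ValueError("training split is empty")
    return NormalizationStats(mins=train.min(), maxs=train.max(), split_id=split_id)


def apply_minmax(rows: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """(x - min) / (max - min), computed from the training statistics.

    Constant training columns map to 0 everywhere.  Values outside the
    training range are NOT clipped: the map stays affine so that Cox and
    network inputs are never silently distorted.
    """
    if list(rows.columns) != list(stats.mins.index):
        raise ValueError("normalization stats do not match the feature columns")
    span = stats.maxs - stats.mins
    out = rows.sub(stats.mins, axis=1).div(span.replace(0.0, np.inf), axis=1)
    return out


def compute_vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per feature: 1 / (1 - R^2_j).

    R^2_j comes from regressing feature j on all the others with an
    intercept.  Perfect collinearity is reported as +inf.
    """
    X = features.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF requires at least two features")
    if n <= p:
        raise ValueError(f"VIF requires more rows ({n}) than features ({p})")
    if np.isnan(X).any():
        raise ValueError("VIF requires a complete table")
    out = {}
    cols = list(features.columns)
    ones = np.ones((n, 1))
    for j, name in enumerate(cols):
        y = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        ss_res = np.sum(resid**2)
        if ss_tot == 0:
            out[name] = np.inf   # constant column: undefined, flag maximal
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class VifReport:
    """Ordered removal log and the retained feature set."""

    steps: list[tuple[str, float, bool]] = field(default_factory=list)  # (feature, vif, removed)
    retained: list[str] = field(default_factory=list)
    threshold: float = 10.0


def prune_collinear(features: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the feature with the largest VIF while any VIF > threshold.

    VIFs are recomputed after each removal; ties break by column order
    (first column wins) for determinism.
    """
    current = features.copy()
    report = VifReport(threshold=threshold)
    for _ in range(features.shape[1]):
        vifs = compute_vif(current)
        worst = vifs.max()
        if not (worst > threshold):
            break
        # first column attaining the max (deterministic tie-break)
        victim = vifs.index[int(np.argmax(vifs.to_numpy()))]
        report.steps.append((victim, float(worst), True))
        current = current.drop(columns=[victim])
        if current.shape[1] < 2:
            break
    final = compute_vif(current) if current.shape[1] >= 2 else pd.Series(dtype=float)
    for name in current.columns:
        report.steps.append((name, float(final.get(name, np.nan)), False))
    report.retained = list(current.columns)
    return report


def schoenfeld_ph_check(fit, dataset, transform: str = "km") -> pd.DataFrame:
    """Proportional-hazards score test on scaled Schoenfeld residuals.

    For each covariate, the correlation of its Schoenfeld residuals with a
    transform g(t) of event time is tested; time transforms: ``km``
    (1 - Kaplan-Meier survival, the default), ``identity`` and ``rank``.
    Returns a frame of per-covariate chi-square statistics and p-values
    plus a ``GLOBAL`` row.

    ``fit`` is a converged :class:`survtab.cox_models.CoxFit` on ``dataset``.
    """
    X = dataset.features[fit.terms].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PH check requires complete covariates")
    index = RiskSetIndex.build(dataset.time, dataset.event)
    if index.n_events < 2:
        raise ValueError("PH check requires at least two events")
    times, resid, vbar = schoenfeld_residuals(X, fit.beta, index)
    d = len(times)
    if transform == "km":
        kt, ks = km_survival(dataset.time, dataset.event)
        g = 1.0 - km_eval(kt, ks, times)
    elif transform == "identity":
        g = times.copy()
    elif transform == "rank":
        g = stats.rankdata(times)
    else:
        raise ValueError(f"unknown time transform {transform!r}")
    gc = g - g.mean()
    denom_t = float(np.sum(gc**2))
    u = gc @ resid                       # per-covariate score
    p = X.shape[1]
    rows = []
    for k, term in enumerate(fit.terms):
        chi2 = u[k] ** 2 / (denom_t * vbar[k, k])
        rows.append((term, chi2, 1, stats.chi2.sf(chi2, 1)))
    D = denom_t * vbar
    chi2_g = float(u @ np.linalg.solve(D, u))
    rows.append(("GLOBAL", chi2_g, p, stats.chi2.sf(chi2_g, p)))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"]).set_index("term")
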