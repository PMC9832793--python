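"""Discrimination and time-dependent performance under right censoring.

Global discrimination is measured with Harrell's C and with Uno's
IPCW-weighted C, whose inverse-probability-of-censoring weights
1/G(t_i)^2 (G = Kaplan--Meier of the censoring distribution) remove the
dependence on the study-specific censoring distribution.  Time-dependent
ROC curves use the cumulative-case / dynamic-control definition with the
Kaplan--Meier estimator of the survivalROC family: sensitivity and
specificity at horizon t are derived from S(t | score > c) via Bayes'
rule, which reduces exactly to the empirical binary ROC of the label
[T <= t] when there is no censoring.  Confidence intervals come from
subject-level bootstrap resampling; models are compared across imputed
datasets with one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._coxcore import km_eval, km_survival
from .datatypes import child_rng

__all__ = [
    "harrells_c",
    "unos_c",
    "td_roc",
    "td_auc",
    "youden_cutoff",
    "td_confusion",
    "MetricResult",
    "bootstrap_ci",
    "compare_models",
]


def _check_lengths(scores, times, events):
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times and events must have equal length")
    return scores, times, events


def _pair_concordance(scores, times, events, weights=None, tau=None):
    """Shared pairwise machinery: usable pairs have the earlier time an event."""
    s, t, d = scores, times, events
    earlier_event = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    if tau is not None:
        earlier_event &= t[:, None] < tau
    if weights is None:
        w = earlier_event.astype(float)
    else:
        w = earlier_event * weights[:, None]
    conc = (s[:, None] > s[None, :]).astype(float)
    conc += 0.5 * (s[:, None] == s[None, :])
    total = w.sum()
    if total == 0:
        return np.nan
    return float((w * conc).sum() / total)


def harrells_c(scores, times, events) -> float:
    """Harrell's concordance: concordant / comparable pairs, score ties 0.5.

    A pair is comparable iff the member with the strictly earlier time had
    the event.  Returns NaN when no pair is comparable.
    """
    scores, times, events = _check_lengths(scores, times, events)
    return _pair_concordance(scores, times, events)


def unos_c(scores, times, events, tau: float | None = None,
           weight_times=None, weight_events=None) -> float:
    """Uno's IPCW concordance with weights 1/G(t_i-)^2.

    G is the Kaplan--Meier estimator of the censoring distribution,
    computed by default on the evaluation sample itself (pass
    ``weight_times``/``weight_events`` to estimate it on, e.g., a training
    sample).  Pairs whose earlier time reaches ``tau`` are excluded;
    ``tau=None`` disables truncation.  Pairs with G = 0 are dropped.
    Without censoring this equals :func:`harrells_c` exactly.
    """
    scores, times, events = _check_lengths(scores, times, events)
    wt = times if weight_times is None else np.asarray(weight_times, dtype=float)
    we = events if weight_events is None else np.asarray(weight_events, dtype=int)
    gt, gs = km_survival(wt, 1 - we)
    G = km_eval(gt, gs, times, left=True)
    with np.errstate(divide="ignore"):
        w = np.where(G > 0, 1.0 / G**2, 0.0)   # zero-weight pairs are dropped
    return _pair_concordance(scores, times, events, weights=w, tau=tau)


def td_roc(scores, times, events, horizon: float,
           max_cutoffs: int | None = None) -> pd.DataFrame:
    """Cumulative/dynamic time-dependent ROC at a horizon (KM estimator).

    Cases: T <= t with the event; controls: T > t.  For each cutoff c
    (rule: score > c is test-positive):

        Se(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
        Sp(c) = 1 - S(t | X > c) P(X > c) / S(t)

    with the subgroup and marginal survival estimated by Kaplan--Meier.
    Returns a frame with columns cutoff, sensitivity, specificity sorted
    by descending cutoff.  ``max_cutoffs`` thins the cutoff grid to score
    quantiles for large samples (None = every distinct score).
    """
    scores, times, events = _check_lengths(scores, times, events)
    t0 = float(horizon)
    kt, ks = km_survival(times, events)
    S_t = km_eval(kt, ks, t0)
    if not (times <= t0).any() or not (times > t0).any():
        raise ValueError(f"no subjects on one side of horizon {t0}")
    if S_t in (0.0, 1.0):
        raise ValueError(f"no cases or no controls estimable at horizon {t0}")
    cuts = np.unique(scores)
    if max_cutoffs is not None and len(cuts) > max_cutoffs:
        cuts = np.unique(np.quantile(scores, np.linspace(0, 1, max_cutoffs)))
    rows = []
    for c in cuts[::-1]:
        grp = scores > c
        p_grp = grp.mean()
        if p_grp == 0:
            se, sp = 0.0, 1.0
        else:
            gt_, gs_ = km_survival(times[grp], events[grp])
            S_c = km_eval(gt_, gs_, t0)
            se = (1.0 - S_c) * p_grp / (1.0 - S_t)
            sp = 1.0 - S_c * p_grp / S_t
        rows.append((c, min(max(se, 0.0), 1.0), min(max(sp, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity"])


def td_auc(scores, times, events, horizon: float,
           max_cutoffs: int | None = None) -> float:
    """Trapezoidal area under the time-dependent ROC curve at a horizon."""
    roc = td_roc(scores, times, events, horizon, max_cutoffs=max_cutoffs)
    # integrate along the cutoff-descending path (the ROC curve's own order);
    # re-sorting by FPR would mis-handle the vertical segment at FPR = 1
    fpr = np.r_[0.0, 1.0 - roc.specificity.to_numpy(), 1.0]
    tpr = np.r_[0.0, roc.sensitivity.to_numpy(), 1.0]
    return float(np.sum(np.diff(fpr) * 0.5 * (tpr[1:] + tpr[:-1])))


def youden_cutoff(scores, times, events, horizon: float,
                  max_cutoffs: int | None = None) -> float:
    """Cutoff maximizing Youden's J = Se + Sp - 1 at the horizon."""
    roc = td_roc(scores, times, events, horizon, max_cutoffs=max_cutoffs)
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.cutoff.iloc[int(np.argmax(j.to_numpy()))])


def td_confusion(scores, times, events, horizon: float, cutoff: float) -> dict:
    """Sensitivity, specificity and balanced accuracy at a fixed cutoff.

    The cutoff is typically chosen on a TRAINING split with
    :func:`youden_cutoff` at the same horizon and applied here to test
    data.  Balanced accuracy = (Se + Sp) / 2 by definition.
    """
    scores, times, events = _check_lengths(scores, times, events)
    t0 = float(horizon)
    kt, ks = km_survival(times, events)
    S_t = km_eval(kt, ks, t0)
    if S_t >= 1.0:
        raise ValueError("no cases at this horizon: sensitivity undefined")
    if S_t <= 0.0:
        raise ValueError("no controls at this horizon: specificity undefined")
    grp = scores > cutoff
    p_grp = grp.mean()
    if p_grp == 0:
        se, sp = 0.0, 1.0
    else:
        gt_, gs_ = km_survival(times[grp], events[grp])
        S_c = km_eval(gt_, gs_, t0)
        se = min(max((1.0 - S_c) * p_grp / (1.0 - S_t), 0.0), 1.0)
        sp = min(max(1.0 - S_c * p_grp / S_t, 0.0), 1.0)
    return {"sensitivity": se, "specificity": sp,
            "balanced_accuracy": 0.5 * (se + sp), "cutoff": float(cutoff)}


@dataclass(frozen=True)
class MetricResult:
    """One metric with its percentile-bootstrap confidence interval."""

    name: str
    value: float
    ci_low: float
    ci_high: float
    horizon: float | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bootstrap > 0 and np.isfinite(self.value):
            if not (self.ci_low <= self.value + 1e-12
                    and self.value - 1e-12 <= self.ci_high):
                raise ValueError("CI must bracket the point value")


def bootstrap_ci(metric, n: int, B: int = 100, seed: int = 0, name: str = "metric",
                 horizon: float | None = None) -> MetricResult:
    """Subject-level percentile bootstrap (2.5/97.5) of a metric closure.

    ``metric`` maps an index array to a float; the point value uses the
    identity index.  Degenerate resamples where the closure returns NaN
    or raises ValueError (e.g. no events drawn) are skipped; more than
    50% degenerate resamples is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = child_rng(seed, "bootstrap", name, horizon)
    point = float(metric(np.arange(n)))
    vals = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            v = float(metric(idx))
        except ValueError:
            v = np.nan
        if np.isnan(v):
            dropped += 1
        else:
            vals.append(v)
    if dropped > B / 2:
        raise ValueError(f"{dropped}/{B} bootstrap resamples were degenerate")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return MetricResult(name=name, value=point, ci_low=float(lo), ci_high=float(hi),
                        horizon=horizon, n_bootstrap=B, seed=seed)


def compare_models(metric_table: pd.DataFrame) -> pd.DataFrame:
    """ANOVA + Tukey HSD across models on per-imputed-dataset metric values.

    ``metric_table`` has one column per model and one row per imputed
    dataset (or dataset x split).  Returns the pairwise table with Tukey
    adjusted p-values.  When all groups are identical the adjusted
    p-values are 1 by convention.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    models = list(metric_table.columns)
    if len(models) < 2:
        raise ValueError("need at least two models")
    for m in models:
        if metric_table[m].dropna().shape[0] < 2:
            raise ValueError(f"model {m} has fewer than two metric values")
    groups = [metric_table[m].dropna().to_numpy() for m in models]
    grand = np.concatenate(groups)
    labels = np.concatenate([[m] * len(g) for m, g in zip(models, groups)])
    # degenerate: no residual variance anywhere -> no detectable differences
    if np.allclose(grand.var(), 0.0):
        rows = [(a, b, 0.0, 1.0) for i, a in enumerate(models)
                for b in models[i + 1:]]
        return pd.DataFrame(rows, columns=["model_a", "model_b", "diff", "p_adj"])
    res = pairwise_tukeyhsd(grand, labels)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out = frame.rename(columns={"group1": "model_a", "group2": "model_b",
                                "meandiff": "diff", "p-adj": "p_adj"})
    out["p_adj"] = out["p_adj"].astype(float).clip(upper=1.0)
    return out[["model_a", "model_b", "diff", "p_adj"]]
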