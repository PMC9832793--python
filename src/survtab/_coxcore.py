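"""Shared Breslow partial-likelihood machinery.

Everything that touches Cox risk sets lives here: the negative log partial
likelihood with Breslow tie handling, its gradient with respect to the
linear predictor, Newton--Raphson score/information evaluation, Schoenfeld
residuals, and small Kaplan--Meier helpers.  Tied event times share the
full risk set (all subjects with follow-up >= the tied time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RiskSetIndex:
    """Sorted view of (time, event) with tie groups precomputed.

    ``order`` sorts ascending by time.  Positions sharing a time form a tie
    group; ``group_id`` maps each sorted position to its group,
    ``bounds[g]:bounds[g+1]`` are the positions of group g, and the Breslow
    risk set of an event in group g is all positions >= ``bounds[g]``.
    """

    order: np.ndarray
    time: np.ndarray        # sorted ascending
    event: np.ndarray       # sorted accordingly
    group_id: np.ndarray
    bounds: np.ndarray      # length n_groups + 1

    @classmethod
    def build(cls, time: np.ndarray, event: np.ndarray) -> "RiskSetIndex":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        order = np.argsort(time, kind="stable")
        t = time[order]
        d = event[order]
        n = len(t)
        new_group = np.empty(n, dtype=bool)
        new_group[0] = True
        new_group[1:] = t[1:] != t[:-1]
        gid = np.cumsum(new_group) - 1
        starts = np.nonzero(new_group)[0]
        return cls(order=order, time=t, event=d, group_id=gid,
                   bounds=np.r_[starts, n])

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def group_start(self) -> np.ndarray:
        """Per-position start index of the tie group (risk-set boundary)."""
        return self.bounds[self.group_id]

    @property
    def group_end(self) -> np.ndarray:
        """Per-position last index of the tie group."""
        return self.bounds[self.group_id + 1] - 1


def _suffix_logsumexp(x: np.ndarray) -> np.ndarray:
    """log(sum_{j>=k} exp(x_j)) for every k, numerically stabilized."""
    c = x.max()
    s = np.cumsum(np.exp(x - c)[::-1])[::-1]
    return np.log(s) + c


def breslow_neg_log_pl(
    log_risk: np.ndarray,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    normalize: bool = True,
    index: RiskSetIndex | None = None,
) -> float:
    """Negative log Cox partial likelihood, Breslow tie handling.

    L = -sum_{i: d_i=1} [ h_i - log sum_{j: t_j >= t_i} exp(h_j) ].
    With ``normalize`` the sum is divided by the number of events so the
    scale is independent of cohort size (an optimizer convenience; the
    minimizer is unchanged).  Zero events yield 0.0.
    """
    h = np.asarray(log_risk, dtype=float)
    idx = index if index is not None else RiskSetIndex.build(time, event)
    hs = h[idx.order]
    d = idx.event
    n_ev = int(d.sum())
    if n_ev == 0:
        return 0.0
    lse = _suffix_logsumexp(hs)[idx.group_start]
    loss = float(np.sum((lse - hs)[d == 1]))
    return loss / n_ev if normalize else loss


def breslow_eta_gradient(
    log_risk: np.ndarray,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    normalize: bool = True,
    index: RiskSetIndex | None = None,
) -> np.ndarray:
    """d(neg log PL)/d(log_risk), returned in the original subject order.

    For subject j: g_j = -d_j + exp(h_j) * sum over event times t_i <= t_j
    of d(t_i)/S0(t_i), where S0 is the Breslow risk-set sum.
    """
    h = np.asarray(log_risk, dtype=float)
    idx = index if index is not None else RiskSetIndex.build(time, event)
    hs = h[idx.order]
    d = idx.event
    n_ev = int(d.sum())
    n = len(hs)
    if n_ev == 0:
        return np.zeros(n)
    c = hs.max()
    w = np.exp(hs - c)
    s0_pos = np.cumsum(w[::-1])[::-1]
    s0 = s0_pos[idx.group_start]  # risk-set sum per position (common exp(-c) scale cancels)
    contrib = np.where(d == 1, 1.0 / s0, 0.0)
    pref = np.cumsum(contrib)
    cum = pref[idx.group_end]  # ties count for each other (t_i <= t_j incl. equal)
    g_sorted = -d + w * cum
    g = np.empty(n)
    g[idx.order] = g_sorted
    return g / n_ev if normalize else g


def cox_gradient_information(
    X: np.ndarray,
    beta: np.ndarray,
    index: RiskSetIndex,
    want_information: bool = True,
):
    """Score and observed information of the Breslow negative log PL.

    Returns (neg_log_pl, gradient, information); the information matrix is
    positive semidefinite.  A fully vectorized path is used when n*p^2 is
    modest, otherwise risk sets are accumulated group by group.
    """
    n, p = X.shape
    Xs = X[index.order]
    d = index.event
    eta = Xs @ beta
    c = eta.max()
    w = np.exp(eta - c)
    gs = index.group_start
    ev_pos = np.nonzero(d == 1)[0]
    if len(ev_pos) == 0:
        raise ValueError("at least one event is required")

    S0_pos = np.cumsum(w[::-1])[::-1]
    S1_pos = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    S0 = S0_pos[gs[ev_pos]]
    S1 = S1_pos[gs[ev_pos]]
    xbar = S1 / S0[:, None]

    nll = float(np.sum(np.log(S0) + c - eta[ev_pos]))
    grad = xbar.sum(axis=0) - Xs[ev_pos].sum(axis=0)

    info = None
    if want_information:
        if n * p * p <= int(4e6):
            outer = np.einsum("ij,ik->ijk", Xs, Xs) * w[:, None, None]
            S2_pos = np.cumsum(outer[::-1], axis=0)[::-1]
            S2 = S2_pos[gs[ev_pos]]
            info = np.einsum("ijk->jk", S2 / S0[:, None, None]) - np.einsum(
                "ij,ik->jk", xbar, xbar
            )
        else:
            info = np.zeros((p, p))
            S0r = 0.0
            S1r = np.zeros(p)
            S2r = np.zeros((p, p))
            nb = len(index.bounds) - 1
            for gi in range(nb - 1, -1, -1):
                lo, hi = index.bounds[gi], index.bounds[gi + 1]
                wg = w[lo:hi]
                Xg = Xs[lo:hi]
                S0r += wg.sum()
                S1r += wg @ Xg
                S2r += (Xg * wg[:, None]).T @ Xg
                dg = int(d[lo:hi].sum())
                if dg:
                    xb = S1r / S0r
                    info += dg * (S2r / S0r - np.outer(xb, xb))
    return nll, grad, info


def schoenfeld_residuals(X: np.ndarray, beta: np.ndarray, index: RiskSetIndex):
    """Per-event Schoenfeld residuals x_i - xbar(t_i) at beta.

    Returns (event_times, residuals [n_events x p], vbar) where vbar is the
    average per-event risk-set covariance (observed information / n_events).
    """
    n, p = X.shape
    Xs = X[index.order]
    d = index.event
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    gs = index.group_start
    ev_pos = np.nonzero(d == 1)[0]
    S0_pos = np.cumsum(w[::-1])[::-1]
    S1_pos = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    S0 = S0_pos[gs[ev_pos]]
    xbar = S1_pos[gs[ev_pos]] / S0[:, None]
    resid = Xs[ev_pos] - xbar

    vbar = np.zeros((p, p))
    S0r = 0.0
    S1r = np.zeros(p)
    S2r = np.zeros((p, p))
    nb = len(index.bounds) - 1
    n_ev = 0
    for gi in range(nb - 1, -1, -1):
        lo, hi = index.bounds[gi], index.bounds[gi + 1]
        wg = w[lo:hi]
        Xg = Xs[lo:hi]
        S0r += wg.sum()
        S1r += wg @ Xg
        S2r += (Xg * wg[:, None]).T @ Xg
        dg = int(d[lo:hi].sum())
        if dg:
            xb = S1r / S0r
            vbar += dg * (S2r / S0r - np.outer(xb, xb))
            n_ev += dg
    return index.time[ev_pos], resid, vbar / max(n_ev, 1)


def km_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan--Meier survival estimate; returns (times, surv) step arrays.

    ``surv[k]`` is S(t) for t in [times[k], times[k+1]).  Events are
    taken to precede censorings at tied times.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    uniq, start = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - start
    d_count = np.add.reduceat(d, start)
    surv = np.cumprod(1.0 - d_count / at_risk)
    return uniq, surv


def km_eval(times: np.ndarray, surv: np.ndarray, t, left: bool = False):
    """Evaluate a KM step function at t (scalar or array).

    With ``left`` the left limit S(t-) is returned.
    """
    tq = np.atleast_1d(np.asarray(t, dtype=float))
    side = "left" if left else "right"
    pos = np.searchsorted(times, tq, side=side) - 1
    out = np.where(pos >= 0, surv[np.clip(pos, 0, len(surv) - 1)], 1.0)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out
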