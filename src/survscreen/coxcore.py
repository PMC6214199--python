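"""Vectorized Cox partial-likelihood engine.

Supplies the primitives the screening layer is built on: the log partial
likelihood with Breslow ties, a Newton-Raphson maximizer vectorized over
thousands of univariate models at once (marginal utilities and MPLEs), an
offset variant for conditional utilities, and a small dense multivariate
Newton solver for refits of selected variable sets.

Risk sets follow R(y_i) = {j : y_j >= y_i}; tied times share a risk set
(Breslow convention).  All solvers enforce a monotone-increasing likelihood
trajectory via step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarginalFit",
    "CoxFit",
    "logpl",
    "logpl_lp",
    "null_logpl",
    "fit_marginal",
    "fit_marginal_many",
    "marginal_utilities",
    "conditional_utilities",
    "fit_cox",
    "breslow_cumhaz",
]

_BETA_CAP = 15.0
_SCORE_TOL = 1e-8
_MAX_NEWTON = 50


@dataclass
class MarginalFit:
    """Univariate Cox fit: MPLE, maximized log partial likelihood, and
    observed information at the maximum."""

    beta_hat: float
    utility: float
    information: float
    converged: bool


@dataclass
class CoxFit:
    """Multivariate Cox MPLE with observed information matrix."""

    beta: np.ndarray
    logpl: float
    information: np.ndarray
    converged: bool

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta


class _RiskSets:
    """Precomputed sort order and tie-group indices for one outcome."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if event.sum() < 1:
            raise ValueError("outcome has no events; partial likelihood degenerate")
        self.order = np.argsort(time, kind="stable")
        t = time[self.order]
        self.delta = event[self.order].astype(float)
        # g[i] = first sorted index of i's tie group; risk set of i = [g[i], n)
        new_group = np.empty(t.size, dtype=bool)
        new_group[0] = True
        new_group[1:] = t[1:] > t[:-1]
        self.g = np.maximum.accumulate(np.where(new_group, np.arange(t.size), 0))
        self.n = t.size
        self.d_total = float(self.delta.sum())

    def suffix(self, A: np.ndarray) -> np.ndarray:
        """Risk-set sums: out[i] = sum_{j in R(y_i)} A[j] (A already sorted)."""
        cs = np.cumsum(A[::-1], axis=0)[::-1]
        return cs[self.g]


def _as_arrays(outcome):
    return np.asarray(outcome.time, dtype=float), np.asarray(outcome.event)


def _values(X) -> np.ndarray:
    v = getattr(X, "values", X)
    return np.asarray(v, dtype=float)


def _subset(arr, rows):
    return arr if rows is None else arr[rows]


def logpl_lp(lp, outcome, rows=None) -> np.ndarray | float:
    """Log partial likelihood evaluated at given linear predictors.

    ``lp`` may be (n,) or (n, m) for m models at once; returns scalar or (m,).
    """
    time, event = _as_arrays(outcome)
    rs = _RiskSets(_subset(time, rows), _subset(event, rows))
    lp = np.asarray(lp, dtype=float)
    squeeze = lp.ndim == 1
    lp2 = lp.reshape(-1, 1) if squeeze else lp
    lp2 = _subset(lp2, rows)[rs.order]
    shift = lp2.max(axis=0)
    s0 = rs.suffix(np.exp(lp2 - shift))
    val = rs.delta @ (lp2 - shift) - rs.delta @ np.log(s0)
    return float(val[0]) if squeeze else val


def logpl(x, outcome, beta, offset=None, rows=None):
    """Cox log partial likelihood for covariate(s) ``x`` at coefficient(s).

    With a single covariate vector and scalar beta returns a scalar; with an
    (n, m) matrix and length-m beta returns one value per column (each column
    its own univariate model, sharing the optional offset).
    """
    xv = _values(x)
    beta = np.asarray(beta, dtype=float)
    if xv.ndim == 1:
        lp = xv * float(beta)
    else:
        lp = xv * beta[np.newaxis, :]
    if offset is not None:
        off = np.asarray(offset, dtype=float)
        lp = lp + (off[:, np.newaxis] if lp.ndim == 2 else off)
    return logpl_lp(lp, outcome, rows=rows)


def null_logpl(outcome, offset=None, rows=None) -> float:
    """Log partial likelihood of the covariate-free model (offset only)."""
    time, event = _as_arrays(outcome)
    time, event = _subset(time, rows), _subset(event, rows)
    rs = _RiskSets(time, event)
    if offset is None:
        lp = np.zeros(time.size)
    else:
        lp = _subset(np.asarray(offset, dtype=float), rows)
    return float(_lp_sorted(lp[rs.order], rs))


def fit_marginal_many(
    X,
    outcome,
    offset=None,
    rows=None,
    max_iter: int = _MAX_NEWTON,
    tol: float = _SCORE_TOL,
    beta_cap: float = _BETA_CAP,
    chunk_cols: int = 20_000,
):
    """Newton-Raphson MPLEs for every column of X as its own univariate model.

    Returns (beta_hat, utility, information, converged) arrays of length p.
    Constant columns get the degenerate convention beta=0, utility = null
    log partial likelihood, information 0.  Monotone likelihoods are capped
    at |beta| = beta_cap and flagged non-converged.
    """
    time, event = _as_arrays(outcome)
    time, event = _subset(time, rows), _subset(event, rows)
    rs = _RiskSets(time, event)
    Xv = _values(X)
    Xv = _subset(Xv, rows)
    off = None
    if offset is not None:
        off = _subset(np.asarray(offset, dtype=float), rows)[rs.order]
        off = off - off.max()
    p = Xv.shape[1]
    beta = np.zeros(p)
    util = np.zeros(p)
    info = np.zeros(p)
    conv = np.zeros(p, dtype=bool)
    for start in range(0, p, chunk_cols):
        cols = slice(start, min(start + chunk_cols, p))
        b, u, i, c = _newton_chunk(Xv[:, cols][rs.order], rs, off,
                                   max_iter, tol, beta_cap)
        beta[cols], util[cols], info[cols], conv[cols] = b, u, i, c
    return beta, util, info, conv


def _chunk_logpl(Xs, rs, off, beta):
    lp = Xs * beta[np.newaxis, :]
    if off is not None:
        lp = lp + off[:, np.newaxis]
    shift = lp.max(axis=0)
    s0 = rs.suffix(np.exp(lp - shift))
    return rs.delta @ (lp - shift) - rs.delta @ np.log(s0)


def _newton_chunk(Xs, rs, off, max_iter, tol, beta_cap):
    """Vectorized univariate Newton over the columns of sorted Xs."""
    m = Xs.shape[1]
    degenerate = Xs.max(axis=0) == Xs.min(axis=0)
    beta = np.zeros(m)
    lp_cur = _chunk_logpl(Xs, rs, off, beta)
    info_cur = np.zeros(m)
    converged = degenerate.copy()
    for _ in range(max_iter):
        eta = Xs * beta[np.newaxis, :]
        if off is not None:
            eta = eta + off[:, np.newaxis]
        eta -= eta.max(axis=0)
        e = np.exp(eta)
        s0 = rs.suffix(e)
        s1 = rs.suffix(Xs * e)
        s2 = rs.suffix(Xs * Xs * e)
        r1 = s1 / s0
        score = rs.delta @ (Xs - r1)
        info_cur = rs.delta @ (s2 / s0 - r1 * r1)
        newly = (~converged) & (np.abs(score) < tol)
        converged |= newly
        active = ~converged
        at_cap = (np.abs(beta) >= beta_cap) & (score * np.sign(beta) > 0)
        active &= ~at_cap
        if not active.any():
            break
        step = np.zeros(m)
        ok = info_cur > 1e-12
        step[active & ok] = (score[active & ok] / info_cur[active & ok])
        np.clip(step, -5.0, 5.0, out=step)
        new_beta = np.clip(beta + step, -beta_cap, beta_cap)
        lp_new = _chunk_logpl(Xs, rs, off, new_beta)
        # step-halving: likelihood trajectory must be non-decreasing
        bad = active & (lp_new < lp_cur - 1e-10)
        for _h in range(30):
            if not bad.any():
                break
            step[bad] *= 0.5
            new_beta[bad] = np.clip(beta[bad] + step[bad], -beta_cap, beta_cap)
            lp_new[bad] = _chunk_logpl(Xs[:, bad], rs, off, new_beta[bad])
            bad = bad & (lp_new < lp_cur - 1e-10)
        beta = np.where(active, new_beta, beta)
        lp_cur = np.where(active, lp_new, lp_cur)
    # utility at the returned beta; degenerate columns kept beta=0, so their
    # utility is the null log partial likelihood by construction
    utility = _chunk_logpl(Xs, rs, off, beta)
    capped = np.abs(beta) >= beta_cap - 1e-9
    converged = (converged & ~capped) | degenerate
    beta[degenerate] = 0.0
    info_cur[degenerate] = 0.0
    return beta, utility, np.maximum(info_cur, 0.0), converged


def fit_marginal(x, outcome, offset=None, rows=None, **kw) -> MarginalFit:
    """Univariate Cox MPLE for a single covariate (see fit_marginal_many)."""
    xv = _values(x)
    if xv.ndim == 1:
        xv = xv[:, np.newaxis]
    b, u, i, c = fit_marginal_many(xv, outcome, offset=offset, rows=rows, **kw)
    return MarginalFit(beta_hat=float(b[0]), utility=float(u[0]),
                       information=float(i[0]), converged=bool(c[0]))


def marginal_utilities(X, outcome, rows=None) -> np.ndarray:
    """Marginal utilities u_k: maximized univariate log partial likelihood of
    each column, computed on the given row subset (a screening partition)."""
    _, util, _, _ = fit_marginal_many(X, outcome, rows=rows)
    return util


def conditional_utilities(
    X,
    outcome,
    conditioning_set,
    rows=None,
    candidates=None,
    joint_refit: bool = False,
) -> np.ndarray:
    """Utilities of candidate columns given an already-selected set.

    Default (offset form): the conditioning set is fit once by unpenalized
    Cox regression on the full sample, its linear predictor is frozen as an
    offset, and each candidate's coefficient is maximized on top of it.
    ``joint_refit=True`` instead refits conditioning set + candidate jointly
    per candidate (slower, kept for comparison).

    Returns utilities for ``candidates`` (default: all columns not in the
    conditioning set), aligned with the candidate order.
    """
    Xv = _values(X)
    conditioning_set = np.asarray(conditioning_set, dtype=int)
    if candidates is None:
        mask = np.ones(Xv.shape[1], dtype=bool)
        mask[conditioning_set] = False
        candidates = np.flatnonzero(mask)
    candidates = np.asarray(candidates, dtype=int)
    if conditioning_set.size == 0:
        return marginal_utilities(Xv[:, candidates], outcome, rows=rows)
    if joint_refit:
        out = np.empty(candidates.size)
        for j, k in enumerate(candidates):
            fit = fit_cox(Xv[:, np.append(conditioning_set, k)], outcome,
                          rows=rows)
            out[j] = fit.logpl
        return out
    base = fit_cox(Xv[:, conditioning_set], outcome)
    off = base.linear_predictor(Xv[:, conditioning_set])
    return fit_marginal_many(Xv[:, candidates], outcome, offset=off,
                             rows=rows)[1]


def fit_cox(
    X,
    outcome,
    offset=None,
    rows=None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Dense multivariate Cox MPLE by Newton-Raphson with step-halving.

    Intended for the small refits this pipeline needs (selected sets of at
    most a few hundred variables); raises if the observed information is
    numerically singular beyond a small ridge jitter.
    """
    time, event = _as_arrays(outcome)
    time, event = _subset(time, rows), _subset(event, rows)
    rs = _RiskSets(time, event)
    Xv = _subset(_values(X), rows)
    if Xv.ndim == 1:
        Xv = Xv[:, np.newaxis]
    Xs = Xv[rs.order]
    off = None
    if offset is not None:
        off = _subset(np.asarray(offset, dtype=float), rows)[rs.order]
    p = Xs.shape[1]
    if p == 0:
        lp = np.zeros(rs.n) if off is None else off
        return CoxFit(beta=np.zeros(0), logpl=float(_lp_sorted(lp, rs)),
                      information=np.zeros((0, 0)), converged=True)
    beta = np.zeros(p)
    converged = False
    info = np.zeros((p, p))

    def lp_of(b):
        eta = Xs @ b
        if off is not None:
            eta = eta + off
        return eta

    cur = _lp_sorted(lp_of(beta), rs)
    for _ in range(max_iter):
        eta = lp_of(beta)
        shift = eta.max()
        e = np.exp(eta - shift)
        s0 = rs.suffix(e)
        s1 = rs.suffix(Xs * e[:, np.newaxis])
        r1 = s1 / s0[:, np.newaxis]
        score = rs.delta @ (Xs - r1)
        # S2/S0 as weighted second moment: sum_i delta_i E_i[xx'] - r1 r1'
        s2 = rs.suffix(np.einsum("ij,ik->ijk", Xs, Xs * e[:, np.newaxis]))
        w2 = s2 / s0[:, np.newaxis, np.newaxis]
        info = np.einsum("i,ijk->jk", rs.delta, w2) - \
            np.einsum("i,ij,ik->jk", rs.delta, r1, r1)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(p), score)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular observed information in Cox refit")
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        new = beta + step
        val = _lp_sorted(lp_of(new), rs)
        h = 0
        while val < cur - 1e-10 and h < 40:
            step *= 0.5
            new = beta + step
            val = _lp_sorted(lp_of(new), rs)
            h += 1
        if val < cur - 1e-10:
            break  # cannot improve; monotone likelihood or numerical limit
        beta, cur = new, val
    return CoxFit(beta=beta, logpl=float(cur), information=info,
                  converged=converged)


def _lp_sorted(lp_sorted, rs):
    shift = lp_sorted.max()
    s0 = rs.suffix(np.exp(lp_sorted - shift))
    return rs.delta @ (lp_sorted - shift) - rs.delta @ np.log(s0)


def breslow_cumhaz(lp_train, outcome_train, times) -> np.ndarray:
    """Breslow baseline cumulative hazard H0 at the requested times.

    H0(t) = sum over event times y_i <= t of d_i / sum_{j in R(y_i)} e^{lp_j},
    the baseline for a linear predictor of zero.
    """
    time, event = _as_arrays(outcome_train)
    rs = _RiskSets(time, event)
    lp = np.asarray(lp_train, dtype=float)[rs.order]
    shift = lp.max()
    s0 = rs.suffix(np.exp(lp - shift)) * np.exp(shift)
    t_sorted = time[rs.order]
    increments = rs.delta / s0
    times = np.atleast_1d(np.asarray(times, dtype=float))
    cum = np.cumsum(increments)
    idx = np.searchsorted(t_sorted, times, side="right") - 1
    return np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
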