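"""Dimension-reduction screening for ultra-high-dimensional survival data.

Three screeners:

* ``sis_aggressive`` — aggressive sure independence screening: split the
  sample into two random halves, rank variables within each half by marginal
  Cox utility, keep the top s = floor(n / log n) per half, return the
  intersection of the two top sets.
* ``isis`` — iterative SIS: alternate (conditional) screening with a
  penalized/forest selector until the selected set stabilizes.
* ``psis`` — principled SIS: keep variables whose standardized marginal MPLE
  statistic sqrt(I_k) |beta_k| exceeds the standard-normal quantile
  Phi^{-1}(1 - q_m / 2), controlling a marginal false-positive rate q_m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats

from . import coxcore

__all__ = ["ScreenResult", "sis_screen_size", "sis_aggressive", "isis", "psis"]


@dataclass
class ScreenResult:
    """Outcome of a screening pass.

    ``selected`` indexes the original columns.  For SIS, ``per_partition_top``
    holds the two top-s index sets I_1, I_2 whose intersection was returned;
    for ISIS, ``trace`` lists the selected set after each iteration.
    """

    selected: np.ndarray
    method: str
    per_partition_top: tuple[np.ndarray, np.ndarray] | None = None
    cutoffs: dict = field(default_factory=dict)
    n_iterations: int = 0
    trace: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return int(np.asarray(self.selected).size)


def sis_screen_size(n: int) -> int:
    """Aggressive-SIS per-partition retention size s = floor(n / log n)."""
    return int(n / math.log(n))


def _top_s(utilities: np.ndarray, s: int) -> np.ndarray:
    """Indices of the s largest utilities; ties broken by lower index."""
    order = np.lexsort((np.arange(utilities.size), -utilities))
    return np.sort(order[:s])


def _split_halves(n: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    n1 = (n + 1) // 2
    return perm[:n1], perm[n1:]


def _partition_utilities(X, outcome, rows, conditioning_set, candidates):
    if conditioning_set is None or len(conditioning_set) == 0:
        Xv = coxcore._values(X)
        return coxcore.marginal_utilities(Xv[:, candidates], outcome, rows=rows)
    return coxcore.conditional_utilities(X, outcome, conditioning_set,
                                         rows=rows, candidates=candidates)


def _screen_once(X, outcome, rng, s, conditioning_set=None):
    """One aggressive screening pass; returns (I1, I2, intersection) as
    original-column indices."""
    Xv = coxcore._values(X)
    n, p = Xv.shape
    event = np.asarray(outcome.event)
    if conditioning_set is None:
        candidates = np.arange(p)
    else:
        mask = np.ones(p, dtype=bool)
        mask[np.asarray(conditioning_set, dtype=int)] = False
        candidates = np.flatnonzero(mask)
    for attempt in range(20):
        rows1, rows2 = _split_halves(n, rng)
        if event[rows1].sum() > 0 and event[rows2].sum() > 0:
            break
    else:
        raise ValueError(
            "could not find a sample split with events in both partitions; "
            "resplit with a new seed")
    tops = []
    for rows in (rows1, rows2):
        u = _partition_utilities(X, outcome, rows, conditioning_set, candidates)
        tops.append(candidates[_top_s(u, min(s, candidates.size))])
    inter = np.intersect1d(tops[0], tops[1])
    return tops[0], tops[1], inter


def sis_aggressive(X, outcome, seed=0, s: int | None = None) -> ScreenResult:
    """Aggressive sure independence screening.

    Splits the n samples into halves of size ceil(n/2) and floor(n/2) by a
    seeded random permutation, ranks every column by its marginal utility
    within each half, keeps the top s = floor(n / log n) per half, and
    returns the intersection I_1 ∩ I_2.
    """
    Xv = coxcore._values(X)
    n = Xv.shape[0]
    if n < 20:
        raise ValueError("aggressive SIS needs n >= 20")
    if s is None:
        s = sis_screen_size(n)
    rng = np.random.default_rng(seed)
    I1, I2, inter = _screen_once(X, outcome, rng, s)
    return ScreenResult(selected=inter, method="SIS",
                        per_partition_top=(I1, I2), cutoffs={"s": s})


def isis(
    X,
    outcome,
    selector,
    max_iter: int = 5,
    seed=0,
    s: int | None = None,
) -> ScreenResult:
    """Iterative sure independence screening.

    Iteration 1 runs aggressive SIS and applies ``selector`` to the screened
    set, giving O_1.  Each later iteration re-splits the sample, screens the
    remaining columns by conditional utility given the current set O_{j-1}
    (linear predictor of the O_{j-1} refit frozen as an offset), forms the
    union of the new top-s intersection with O_{j-1}, and applies the
    selector to that union.  Stops at a fixed point (O_j = O_{j-1}) or after
    ``max_iter`` iterations.

    ``selector(X_sub, outcome, seed)`` must return an object with a
    ``selected`` attribute indexing the columns of X_sub (the module
    ``selection`` procedures qualify).
    """
    Xv = coxcore._values(X)
    n = Xv.shape[0]
    if s is None:
        s = sis_screen_size(n)
    ss = np.random.SeedSequence(seed if np.ndim(seed) == 0 else list(seed))
    child = ss.spawn(2 * max_iter)
    trace = []
    current = np.array([], dtype=int)
    n_iter = 0
    for j in range(max_iter):
        rng = np.random.default_rng(child[2 * j])
        sel_seed = int(child[2 * j + 1].generate_state(1)[0] % (2**31))
        cond = current if current.size else None
        _, _, new_inter = _screen_once(X, outcome, rng, s,
                                       conditioning_set=cond)
        pool = np.union1d(new_inter, current)
        if pool.size == 0:
            trace.append(current.copy())
            n_iter = j + 1
            break
        result = selector(Xv[:, pool], outcome, seed=sel_seed)
        new_set = pool[np.asarray(result.selected, dtype=int)]
        trace.append(new_set.copy())
        n_iter = j + 1
        if j == 0 and new_set.size == 0:
            current = new_set
            break  # empty first-pass selection is a valid (null) outcome
        if new_set.size == current.size and np.array_equal(new_set, current):
            current = new_set
            break
        current = new_set
    return ScreenResult(selected=current, method="ISIS", cutoffs={"s": s},
                        n_iterations=n_iter, trace=trace)


def psis(X, outcome, q_m: float = 0.001) -> ScreenResult:
    """Principled sure independence screening.

    Fits all p marginal MPLEs on the full sample and keeps columns whose
    standardized statistic sqrt(I_k(beta_k)) |beta_k| reaches the normal
    cutoff gamma_m = Phi^{-1}(1 - q_m / 2).
    """
    if not (0 < q_m <= 1):
        raise ValueError("q_m must lie in (0, 1]")
    beta, _, info, _ = coxcore.fit_marginal_many(X, outcome)
    gamma_m = float(stats.norm.ppf(1 - q_m / 2))
    stat = np.sqrt(info) * np.abs(beta)
    degenerate = info <= 0
    selected = np.flatnonzero((stat >= gamma_m) & ~degenerate)
    return ScreenResult(selected=selected, method="PSIS",
                        cutoffs={"gamma_m": gamma_m, "q_m": q_m})
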