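"""Final-model variable selection on a screened (or full) variable set.

Three selectors share one result type:

* ``lasso_cox`` — L1-penalized Cox regression along a glmnet-style path,
  with the penalty chosen by 10-fold cross-validated partial-likelihood
  deviance (Verweij & Van Houwelingen criterion).
* ``alasso_cox`` — adaptive LASSO: the same path with penalty weights
  1/|beta_tilde| from an initial maximum partial likelihood estimate.
* ``rsf_minimal_depth`` — random survival forest with log-rank splitting and
  randomized split points; variables kept when their forest-averaged minimal
  depth is at or below the mean minimal depth of a noise variable under the
  topology-conditional null distribution.

The penalized paths are computed by scikit-survival's coordinate-descent
Coxnet solver (columns standardized internally, coefficients returned on the
original scale); the CV rule, adaptive weights, forest and minimal-depth
thresholding are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from . import coxcore
from ._survtree import grow_tree, null_depth_mean

__all__ = ["SelectionResult", "lasso_cox", "alasso_cox", "rsf_minimal_depth"]

_MAX_WEIGHT = 1e8


@dataclass
class SelectionResult:
    """Selected column indices plus method-specific by-products."""

    selected: np.ndarray
    method: str
    coefficients: np.ndarray | None = None
    lambda_chosen: float | None = None
    depth_threshold: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(np.asarray(self.selected).size)


def _empty(method, **meta) -> SelectionResult:
    return SelectionResult(selected=np.array([], dtype=int), method=method,
                           coefficients=np.array([]), metadata=meta)


def _surv_y(outcome):
    return Surv.from_arrays(event=np.asarray(outcome.event, dtype=bool),
                            time=np.asarray(outcome.time, dtype=float))


def _cv_folds(event, n_folds, seed):
    """Event-stratified fold assignment (plain KFold if a class is tiny)."""
    event = np.asarray(event)
    if min(event.sum(), (1 - event).sum()) >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        return list(splitter.split(np.zeros(event.size), event))
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(event.size)))


def _subset_outcome(outcome, rows):
    from .simdata import SurvivalOutcome

    return SurvivalOutcome(time=np.asarray(outcome.time)[rows],
                           event=np.asarray(outcome.event)[rows])


def _cv_deviance(X, outcome, alphas, n_folds, seed, penalty_factor):
    """Cross-validated partial-likelihood deviance per penalty value.

    Verweij & Van Houwelingen: the fold-k contribution at penalty lambda is
    -2 [ l(beta_{-k}(lambda)) - l_{-k}(beta_{-k}(lambda)) ], with l the
    full-sample and l_{-k} the training-sample log partial likelihood.
    """
    y = _surv_y(outcome)
    dev = np.zeros(alphas.size)
    for train_rows, _ in _cv_folds(outcome.event, n_folds, seed):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, penalty_factor=penalty_factor,
            normalize=True, fit_baseline_model=False)
        model.fit(X[train_rows], y[train_rows])
        B = model.coef_  # (p, n_alphas)
        fitted = np.asarray(model.alphas_)
        lp_full = X @ B
        lp_train = lp_full[train_rows]
        l_full = coxcore.logpl_lp(lp_full, outcome)
        l_train = coxcore.logpl_lp(lp_train, _subset_outcome(outcome, train_rows))
        d = -2.0 * (l_full - l_train)
        if fitted.size == alphas.size:
            dev += d
        else:  # solver may truncate the path; align by alpha value
            pos = np.searchsorted(-alphas, -fitted)
            full_d = np.full(alphas.size, np.nan)
            full_d[pos] = d
            # carry the last fitted value forward for truncated tail
            last = d[-1] if d.size else 0.0
            full_d = np.where(np.isnan(full_d), last, full_d)
            dev += full_d
    return dev


def _penalized_path(X_sub, outcome, n_folds, seed, penalty_factor, method,
                    **meta):
    X_sub = np.asarray(coxcore._values(X_sub), dtype=float)
    if X_sub.ndim == 1:
        X_sub = X_sub[:, np.newaxis]
    if X_sub.shape[1] == 0:
        return _empty(method, **meta)
    if int(np.asarray(outcome.event).sum()) < n_folds:
        raise ValueError(f"need at least {n_folds} events for {n_folds}-fold CV")
    keep = X_sub.max(axis=0) > X_sub.min(axis=0)
    if not keep.any():
        return _empty(method, **meta)
    cols = np.flatnonzero(keep)
    Xk = X_sub[:, cols]
    pf = None if penalty_factor is None else penalty_factor[cols]
    y = _surv_y(outcome)
    full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=100,
                                  alpha_min_ratio="auto",
                                  penalty_factor=pf, normalize=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(Xk, y)
        alphas = np.asarray(full.alphas_)
        dev = _cv_deviance(Xk, outcome, alphas, n_folds, seed, pf)
    best = int(np.argmin(dev))  # ties: first index = largest penalty
    coef = full.coef_[:, best]
    nz = np.flatnonzero(coef != 0)
    return SelectionResult(
        selected=cols[nz], method=method, coefficients=coef[nz],
        lambda_chosen=float(alphas[best]),
        metadata={"cv_deviance": dev, "alphas": alphas, **meta})


def lasso_cox(X_sub, outcome, n_folds: int = 10, seed=0) -> SelectionResult:
    """Cox LASSO with penalty chosen by cross-validated deviance.

    Variables with nonzero coefficients at the chosen penalty are selected;
    an empty active set is a valid outcome.
    """
    return _penalized_path(X_sub, outcome, n_folds, seed,
                           penalty_factor=None, method="LASSO")


def alasso_cox(X_sub, outcome, n_folds: int = 10, seed=0) -> SelectionResult:
    """Adaptive Cox LASSO with weights 1/|beta_tilde|.

    beta_tilde is the joint unpenalized MPLE of the reduced model when the
    problem is comfortably overdetermined (p_sub < n/2); otherwise marginal
    (univariate) MPLEs are used as initial estimates, which keeps the method
    defined at any p.  The weight regime is recorded in the result metadata.
    """
    Xv = np.asarray(coxcore._values(X_sub), dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, np.newaxis]
    if Xv.shape[1] == 0:
        return _empty("ALASSO", weights="none")
    n, p_sub = Xv.shape
    if p_sub < n / 2:
        try:
            beta_tilde = coxcore.fit_cox(Xv, outcome).beta
            mode = "joint_mple"
        except np.linalg.LinAlgError:
            beta_tilde = coxcore.fit_marginal_many(Xv, outcome)[0]
            mode = "marginal_mple"
    else:
        beta_tilde = coxcore.fit_marginal_many(Xv, outcome)[0]
        mode = "marginal_mple"
    weights = 1.0 / np.maximum(np.abs(beta_tilde), 1.0 / _MAX_WEIGHT)
    result = _penalized_path(Xv, outcome, n_folds, seed,
                             penalty_factor=weights, method="ALASSO")
    result.metadata["weights"] = mode
    return result


def rsf_minimal_depth(
    X_sub,
    outcome,
    n_trees: int = 100,
    n_split: int = 10,
    seed=0,
    nodesize: int = 15,
    mtry: int | None = None,
) -> SelectionResult:
    """Random-survival-forest selection by mean minimal-depth thresholding.

    Grows ``n_trees`` bootstrap survival trees (log-rank splitting,
    ``n_split`` random split points per candidate variable), averages each
    variable's minimal depth over the forest (a variable absent from a tree
    contributes that tree's depth D(S)), and keeps variables whose average
    is at or below the forest-averaged mean minimal depth of a noise
    variable under the topology-conditional null distribution.
    """
    Xv = np.asarray(coxcore._values(X_sub), dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, np.newaxis]
    n, p_sub = Xv.shape
    if p_sub < 2:
        raise ValueError("rsf_minimal_depth needs at least 2 variables")
    if mtry is None:
        mtry = int(math.ceil(math.sqrt(p_sub)))
    rng = np.random.default_rng(seed)
    time = np.asarray(outcome.time, dtype=float)
    event = np.asarray(outcome.event)
    depths = np.zeros(p_sub)
    null_means = []
    n_valid = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        tree = grow_tree(Xv[boot], time[boot], event[boot], rng,
                         mtry=mtry, n_split=n_split, nodesize=nodesize)
        if tree.depth == 0:
            continue  # no valid split in this tree
        depths += tree.minimal_depths(p_sub)
        null_means.append(null_depth_mean(tree.nodes_at_depth(), p_sub))
        n_valid += 1
    if n_valid == 0:
        warnings.warn("forest contains no valid splits; empty selection")
        return _empty("RSF", n_trees=n_trees)
    depths /= n_valid
    threshold = float(np.mean(null_means))
    selected = np.flatnonzero(depths <= threshold)
    return SelectionResult(
        selected=selected, method="RSF", coefficients=None,
        depth_threshold=threshold,
        metadata={"minimal_depth": depths, "n_valid_trees": n_valid})
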