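"""Prognostic-model performance metrics for right-censored outcomes.

Discrimination (Harrell's c-index), overall performance (Brier-score R^2 at
a fixed horizon, censoring handled by inverse-probability-of-censoring
weights), calibration (slope and quartile table), and optimism-corrected
internal validation by the bootstrap.

Conventions (they differ across implementations, so they are pinned here):
a subject pair is comparable when the smaller observed time is an event;
pairs with tied event times are not comparable; ties in the predictor count
one half.  IPCW weights come from the reverse Kaplan-Meier estimate of the
censoring distribution on the evaluation sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coxcore

__all__ = [
    "EvalReport",
    "harrell_c",
    "km_survival",
    "brier_r2",
    "calibration_slope",
    "calibration_quartiles",
    "bootstrap_optimism",
    "predict_survival",
]


@dataclass
class EvalReport:
    """Bundle of the evaluation metrics for one fitted model."""

    c_index: float
    r2_bs: float | None = None
    cal_slope: float | None = None
    cal_table: np.ndarray | None = None
    optimism: float | None = None
    c_corrected: float | None = None


def harrell_c(linear_predictor, outcome) -> float:
    """Harrell's concordance index of risk scores against censored outcomes.

    Higher scores must predict earlier events: a comparable pair (the
    earlier observed time is an event, times not tied) is concordant when
    the earlier subject has the higher score; score ties count 1/2.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(outcome.time, dtype=float)
    event = np.asarray(outcome.event)
    n = time.size
    conc = 0.0
    comp = 0.0
    # loop over event subjects; vectorize over their later partners
    for i in np.flatnonzero(event == 1):
        later = time > time[i]
        m = int(later.sum())
        if m == 0:
            continue
        comp += m
        conc += np.sum(lp[later] < lp[i]) + 0.5 * np.sum(lp[later] == lp[i])
    if comp == 0:
        raise ValueError("no comparable pairs; c-index undefined")
    return float(conc / comp)


def km_survival(time, event, eval_times) -> np.ndarray:
    """Kaplan-Meier survival estimate evaluated at the requested times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order].astype(float)
    uniq, first = np.unique(t, return_index=True)
    at_risk = t.size - first
    deaths = np.add.reduceat(d, first)
    with np.errstate(invalid="ignore"):
        factors = 1.0 - deaths / at_risk
    surv = np.cumprod(factors)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    idx = np.searchsorted(uniq, eval_times, side="right") - 1
    return np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)


def _censor_km(time, event, eval_times):
    """Reverse Kaplan-Meier: survival of the censoring distribution G."""
    return km_survival(time, 1 - np.asarray(event), eval_times)


def brier_r2(pred_surv, outcome, t_star: float = 2.0) -> float:
    """Brier-score R^2 at horizon t_star: 1 - BS_model / BS_null.

    BS is the IPCW Brier score; the null model predicts the marginal
    Kaplan-Meier survival at t_star for everyone.  Positive values mean the
    model beats the null model at t_star; the score can be negative.
    """
    pred_surv = np.asarray(pred_surv, dtype=float)
    if np.any((pred_surv < 0) | (pred_surv > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    time = np.asarray(outcome.time, dtype=float)
    event = np.asarray(outcome.event)
    if not np.any(time > t_star):
        raise ValueError(f"no subjects under observation beyond t*={t_star}; "
                         "Brier score undefined")
    null_pred = np.full(time.size, km_survival(time, event, t_star)[0])
    bs_model = _ipcw_brier(pred_surv, time, event, t_star)
    bs_null = _ipcw_brier(null_pred, time, event, t_star)
    if bs_null == 0:
        return 0.0 if bs_model == 0 else -np.inf
    return float(1.0 - bs_model / bs_null)


def _ipcw_brier(pred_surv, time, event, t_star):
    n = time.size
    # G evaluated just before each event time, and at t_star
    g_at_event = _censor_km(time, event, np.maximum(time - 1e-12, 0.0))
    g_at_tstar = _censor_km(time, event, t_star)[0]
    w = np.zeros(n)
    died = (time <= t_star) & (event == 1)
    alive = time > t_star
    if np.any(died & (g_at_event <= 0)) or (alive.any() and g_at_tstar <= 0):
        raise ValueError("zero censoring-survival weight; Brier score undefined")
    w[died] = 1.0 / g_at_event[died]
    w[alive] = 1.0 / g_at_tstar
    resid = np.where(alive, 1.0 - pred_surv, 0.0 - pred_surv)
    return float(np.sum(w * resid**2) / n)


def calibration_slope(prognostic_index, outcome) -> float:
    """Calibration slope of a prognostic index on new outcomes.

    Proportional-hazards regression of the outcomes on the single covariate
    ``prognostic_index``; 1 means the index is correctly scaled on new data,
    values below 1 indicate overfitting of the training model.
    """
    pi = np.asarray(prognostic_index, dtype=float)
    if pi.max() == pi.min():
        raise ValueError("constant prognostic index; calibration slope undefined")
    fit = coxcore.fit_marginal(pi, outcome)
    return float(fit.beta_hat)


def calibration_quartiles(pred_surv, outcome, t_star: float = 2.0) -> np.ndarray:
    """Quartile calibration table at horizon t_star.

    Subjects are binned into quartiles of predicted survival; each row holds
    (mean predicted survival, Kaplan-Meier observed survival) for one bin,
    ordered from lowest to highest predicted survival.  Bins with nobody
    under observation at t_star get NaN observed values.
    """
    pred_surv = np.asarray(pred_surv, dtype=float)
    time = np.asarray(outcome.time, dtype=float)
    event = np.asarray(outcome.event)
    if pred_surv.size < 8:
        raise ValueError("need n >= 8 for quartile calibration")
    # rank-based equal-sized groups (robust to heavily tied predictions)
    order = np.argsort(pred_surv, kind="stable")
    bins = np.empty(pred_surv.size, dtype=int)
    bins[order] = np.arange(pred_surv.size) * 4 // pred_surv.size
    table = np.full((4, 2), np.nan)
    for b in range(4):
        mask = bins == b
        if not mask.any():
            continue
        table[b, 0] = pred_surv[mask].mean()
        if np.any(time[mask] > t_star) or np.any(
                (time[mask] <= t_star) & (event[mask] == 1)):
            table[b, 1] = km_survival(time[mask], event[mask], t_star)[0]
    return table


def predict_survival(fit: coxcore.CoxFit, X_train, outcome_train, X_new,
                     t_star: float = 2.0) -> np.ndarray:
    """Predicted survival at t_star from a fitted proportional-hazards model.

    Uses the Breslow baseline cumulative hazard of the training fit:
    S(t*|x) = exp(-H0(t*) exp(lp(x))).
    """
    lp_train = fit.linear_predictor(coxcore._values(X_train))
    h0 = coxcore.breslow_cumhaz(lp_train, outcome_train, t_star)[0]
    lp_new = fit.linear_predictor(coxcore._values(X_new))
    return np.exp(-h0 * np.exp(lp_new))


def bootstrap_optimism(X, outcome, pipeline, B: int = 100, seed=0):
    """Harrell-style bootstrap optimism of the c-index.

    ``pipeline(X, outcome, seed)`` must return a risk-score function
    lp(X_new) -> scores (or raise/return None on failure).  For each of B
    bootstrap resamples the pipeline is refit; optimism is the mean of
    (c on the resample - c on the original data), and the corrected c-index
    is the apparent c minus the optimism.  Replicates where the pipeline
    fails are dropped and counted; more than 20% failures is an error.

    Returns (optimism, c_corrected, n_failed).
    """
    Xv = coxcore._values(X)
    rng = np.random.default_rng(seed)
    apparent_rule = pipeline(Xv, outcome, _child_seed(rng))
    if apparent_rule is None:
        raise ValueError("pipeline failed on the original sample")
    c_apparent = harrell_c(apparent_rule(Xv), outcome)
    diffs = []
    n_failed = 0
    from .simdata import SurvivalOutcome

    n = Xv.shape[0]
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        yb = SurvivalOutcome(time=np.asarray(outcome.time)[rows],
                             event=np.asarray(outcome.event)[rows])
        try:
            rule = pipeline(Xv[rows], yb, _child_seed(rng))
            if rule is None:
                raise ValueError("pipeline returned None")
            c_boot = harrell_c(rule(Xv[rows]), yb)
            c_orig = harrell_c(rule(Xv), outcome)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        diffs.append(c_boot - c_orig)
    if n_failed > 0.2 * B:
        raise RuntimeError(
            f"bootstrap pipeline failed on {n_failed}/{B} resamples")
    optimism = float(np.mean(diffs))
    return optimism, float(c_apparent - optimism), n_failed


def _child_seed(rng) -> int:
    return int(rng.integers(0, 2**31 - 1))
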