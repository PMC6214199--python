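"""Simulation-study orchestration.

Runs a grid of (scenario x method) combinations over replicated synthetic
datasets, evaluating each fitted prognostic model on its training set and on
an independent test set, and aggregates per-replicate records into mean/SD
summary tables.

A "method" is a screening stage (none, SIS, ISIS, PSIS) combined with a
selection stage (none, LASSO, ALASSO, RSF); ISIS embeds its selector in the
screening iteration, so it always requires one.  After selection, an
unpenalized proportional-hazards model is refit on the selected variables
and used for all predictions (risk scores and Breslow-baseline survival
probabilities); an empty selection yields the null model, recorded with
c-index 0.5 and Brier R^2 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import functools

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import coxcore, evaluation, screening, selection
from .simdata import ScenarioConfig, SimulatedData, gen_dataset

__all__ = ["MethodSpec", "BenchmarkResult", "run_method", "run_benchmark",
           "fit_pipeline"]

_SCREENS = (None, "SIS", "ISIS", "PSIS")
_SELECTS = (None, "LASSO", "ALASSO", "RSF")


@dataclass
class MethodSpec:
    """One screening/selection combination with its tuning parameters.

    ``params`` recognizes: q_m (PSIS), max_iter (ISIS), n_folds (penalized
    selectors), n_trees / n_split / nodesize (RSF).
    """

    screen: str | None = None
    select: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.screen not in _SCREENS:
            raise ValueError(f"unknown screen {self.screen!r}")
        if self.select not in _SELECTS:
            raise ValueError(f"unknown select {self.select!r}")
        if self.screen == "ISIS" and self.select is None:
            raise ValueError("ISIS cannot run alone; it needs a selector")

    @property
    def name(self) -> str:
        parts = [x for x in (self.screen, self.select) if x]
        return "-".join(parts) if parts else "null"

    @classmethod
    def parse(cls, name: str, **params) -> "MethodSpec":
        """Parse names like 'ISIS-LASSO', 'PSIS', 'ALASSO', 'null'."""
        if name == "null":
            return cls()
        screen = select = None
        for part in name.split("-"):
            if part in _SCREENS:
                screen = part
            elif part in _SELECTS:
                select = part
            else:
                raise ValueError(f"unknown method component {part!r}")
        return cls(screen=screen, select=select, params=params)


def _selector_fn(method: MethodSpec):
    p = method.params
    if method.select == "LASSO":
        return functools.partial(selection.lasso_cox,
                                 n_folds=p.get("n_folds", 10))
    if method.select == "ALASSO":
        return functools.partial(selection.alasso_cox,
                                 n_folds=p.get("n_folds", 10))
    if method.select == "RSF":
        return functools.partial(
            selection.rsf_minimal_depth, n_trees=p.get("n_trees", 100),
            n_split=p.get("n_split", 10), nodesize=p.get("nodesize", 15))
    return None


def fit_pipeline(X, outcome, method: MethodSpec, seed=0):
    """Screen + select + unpenalized refit; returns (selected, CoxFit).

    ``selected`` indexes the original columns; the refit is the prediction
    model.  An empty selection returns (empty index set, None).
    """
    Xv = coxcore._values(X)
    ss = np.random.SeedSequence(seed if np.ndim(seed) == 0 else list(seed))
    s_screen, s_select = (int(c.generate_state(1)[0] % 2**31)
                          for c in ss.spawn(2))
    selector = _selector_fn(method)
    p = method.params
    if method.screen == "ISIS":
        res = screening.isis(Xv, outcome, selector,
                             max_iter=p.get("max_iter", 5), seed=s_screen)
        selected = res.selected
    else:
        if method.screen == "SIS":
            pool = screening.sis_aggressive(Xv, outcome, seed=s_screen).selected
        elif method.screen == "PSIS":
            pool = screening.psis(Xv, outcome,
                                  q_m=p.get("q_m", 0.001)).selected
        else:
            pool = np.arange(Xv.shape[1])
        if selector is None:
            selected = pool if method.screen is not None else np.array([], int)
        elif pool.size == 0:
            selected = pool
        else:
            sub = selector(Xv[:, pool], outcome, seed=s_select)
            selected = pool[np.asarray(sub.selected, dtype=int)]
    if selected.size == 0:
        return selected, None
    fit = coxcore.fit_cox(Xv[:, selected], outcome)
    return selected, fit


def run_method(
    train: SimulatedData | tuple,
    test: tuple | None,
    method: MethodSpec,
    seed=0,
    informative_idx=None,
    t_star: float = 2.0,
) -> dict:
    """Run one method on one replicate and record all metrics.

    ``train`` is either a SimulatedData (test/model taken from it when not
    given) or an (X, outcome) pair.  Failures of individual metrics are
    recorded as NaN with a status code rather than raised.
    """
    if isinstance(train, SimulatedData):
        sim = train
        X, y = sim.X, sim.outcome
        if test is None and sim.X_test is not None:
            test = (sim.X_test, sim.outcome_test)
        if informative_idx is None:
            informative_idx = sim.model.informative_idx
    else:
        X, y = train
    Xv = coxcore._values(X)
    record = {
        "method": method.name, "n": Xv.shape[0], "p": Xv.shape[1],
        "seed": int(seed) if np.ndim(seed) == 0 else str(seed),
        "status": "ok",
        "model_size": np.nan, "n_informative": np.nan,
        "c_train": np.nan, "c_test": np.nan,
        "r2_train": np.nan, "r2_test": np.nan, "cal_slope": np.nan,
    }
    try:
        selected, fit = fit_pipeline(Xv, y, method, seed=seed)
    except (ValueError, np.linalg.LinAlgError) as exc:
        record["status"] = f"failed: {exc}"
        return record
    record["model_size"] = int(selected.size)
    if informative_idx is not None:
        record["n_informative"] = int(
            np.intersect1d(selected, informative_idx).size)
    if fit is None:  # empty selection -> null model
        record["status"] = "empty"
        record["c_train"] = 0.5
        record["r2_train"] = 0.0
        if test is not None:
            record["c_test"] = 0.5
            record["r2_test"] = 0.0
        return record
    lp_train = fit.linear_predictor(Xv[:, selected])
    record["c_train"] = evaluation.harrell_c(lp_train, y)
    try:
        pred_train = evaluation.predict_survival(fit, Xv[:, selected], y,
                                                 Xv[:, selected], t_star)
        record["r2_train"] = evaluation.brier_r2(pred_train, y, t_star)
    except ValueError:
        record["status"] = "no_train_r2"
    if test is not None:
        X_test, y_test = test
        Xt = coxcore._values(X_test)[:, selected]
        lp_test = fit.linear_predictor(Xt)
        record["c_test"] = evaluation.harrell_c(lp_test, y_test)
        try:
            pred_test = evaluation.predict_survival(
                fit, Xv[:, selected], y, Xt, t_star)
            record["r2_test"] = evaluation.brier_r2(pred_test, y_test, t_star)
            record["cal_slope"] = evaluation.calibration_slope(lp_test, y_test)
        except ValueError:
            record["status"] = "no_test_metrics"
    return record


@dataclass
class BenchmarkResult:
    """Tidy per-replicate records plus mean/SD summary tables."""

    records: pd.DataFrame
    summary: pd.DataFrame

    def to_files(self, records_path, summary_path) -> None:
        self.records.to_csv(records_path, sep="\t", index=False)
        self.summary.to_csv(summary_path, sep="\t")


_METRICS = ["model_size", "n_informative", "c_train", "c_test",
            "r2_train", "r2_test", "cal_slope"]


def _replicate_seed(master: int, scenario_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(master), scenario_idx, rep])
    return int(ss.generate_state(1)[0] % 2**31)


def _one_replicate(config: ScenarioConfig, scenario_idx: int, rep: int,
                   methods: list[MethodSpec], master_seed: int,
                   scenario_label: str):
    rep_seed = _replicate_seed(master_seed, scenario_idx, rep)
    cfg = replace(config, seed=rep_seed)
    sim = gen_dataset(cfg, include_test=True)
    out = []
    for mi, method in enumerate(methods):
        m_seed = _replicate_seed(master_seed, scenario_idx,
                                 1_000_003 * (mi + 1) + rep)
        rec = run_method(sim, None, method, seed=m_seed)
        rec.update(scenario=scenario_label, rep=rep)
        out.append(rec)
    return out


def run_benchmark(
    scenarios,
    methods,
    reps: int,
    seed: int = 0,
    workers: int = 1,
) -> BenchmarkResult:
    """Replicate every scenario ``reps`` times and run every method.

    Replicate seeds derive deterministically from (seed, scenario index,
    replicate index), so results are invariant to the worker count.  All
    methods within a replicate share the same dataset, mirroring the paired
    design of the simulation tables.  ``scenarios`` may be ScenarioConfig
    objects or (label, config) pairs.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    labeled = []
    for i, sc in enumerate(scenarios):
        if isinstance(sc, tuple):
            labeled.append((sc[0], sc[1]))
        else:
            label = sc.signal or f"scenario{i}"
            labeled.append((f"{label}_n{sc.n}", sc))
    tasks = [(cfg, si, rep, label)
             for si, (label, cfg) in enumerate(labeled)
             for rep in range(reps)]
    chunks = Parallel(n_jobs=workers)(
        delayed(_one_replicate)(cfg, si, rep, list(methods), seed, label)
        for cfg, si, rep, label in tasks)
    records = pd.DataFrame([r for chunk in chunks for r in chunk])
    grouped = records.groupby(["scenario", "method"])[_METRICS]
    summary = grouped.agg(["mean", "std", "count"])
    return BenchmarkResult(records=records, summary=summary)
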