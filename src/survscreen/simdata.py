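"""Synthetic SNP-survival data generation.

Emulates a germline-SNP study design: genotype matrices with entries coded
0/1/2 (minor-allele counts) drawn i.i.d. per variable under Hardy-Weinberg
equilibrium, and right-censored failure times from a Weibull
proportional-hazards model in which only a handful of variables carry signal.
Censoring times are uniform on [0, theta_c] with theta_c calibrated so the
marginal censoring probability hits a target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import itertools
import json
import math

import numpy as np
from scipy import optimize, special

__all__ = [
    "ScenarioConfig",
    "GenotypeMatrix",
    "TrueModel",
    "SurvivalOutcome",
    "SimulatedData",
    "fixture_beta",
    "gen_genotypes",
    "gen_beta",
    "gen_failure_times",
    "calibrate_theta_c",
    "gen_dataset",
]

# Reference coefficient vectors for the two signal-strength scenarios,
# each of the form (-1)^u (a + |z|) with a = 1 (weak) or a = 2 (strong).
_FIXTURE_BETA = {
    "strong": np.array(
        [2.527186, 2.443898, 2.152147, -2.388758, 2.156502, -2.003314]
    ),
    "weak": np.array(
        [1.036478, -1.073296, -1.250946, 1.138729, -1.128361, 1.145263]
    ),
}


def fixture_beta(name: str) -> np.ndarray:
    """Return one of the two reference informative-coefficient vectors."""
    try:
        return _FIXTURE_BETA[name].copy()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; use 'strong' or 'weak'")


@dataclass
class ScenarioConfig:
    """All knobs of one simulation scenario.

    Parameters
    ----------
    n : training sample size.
    p : total number of variables.
    p_star : number of informative variables (nonzero coefficients).
    a : signal-strength offset; informative |beta_j| >= a (1 weak, 2 strong).
    tau : Weibull shape parameter.
    cens_rate : target marginal censoring proportion in [0, 1).
    maf : minor allele frequency q in (0, 0.5].
    seed : master RNG seed for the scenario.
    test_n : size of the independent test set.
    signal : optional name of a fixed coefficient fixture ('strong'/'weak');
        when set, the informative coefficients are the fixture vector instead
        of a fresh random draw.
    """

    n: int
    p: int
    p_star: int = 6
    a: float = 2.0
    tau: float = 1.5
    cens_rate: float = 0.20
    maf: float = 0.15
    seed: int = 0
    test_n: int = 2000
    signal: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (0 <= self.cens_rate < 1):
            raise ValueError("cens_rate must lie in [0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.p_star > self.p:
            raise ValueError("p_star cannot exceed p")
        if self.n <= 0 or self.p <= 0:
            raise ValueError("n and p must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GenotypeMatrix:
    """n x p matrix of genotype codes with per-variable MAF metadata.

    ``values`` is float to allow NaN missingness and fractional imputed
    genotypes downstream; simulated matrices contain only {0, 1, 2}.
    """

    values: np.ndarray
    maf: np.ndarray | float | None = None
    ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class TrueModel:
    """Generating coefficients: beta is length-p, zero off informative_idx."""

    beta: np.ndarray
    informative_idx: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.informative_idx = np.asarray(self.informative_idx, dtype=int)

    @property
    def informative_beta(self) -> np.ndarray:
        return self.beta[self.informative_idx]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """x'beta using only the informative columns (the rest are zero)."""
        return X[:, self.informative_idx] @ self.informative_beta


@dataclass
class SurvivalOutcome:
    """Observed times t_i = min(T_i, C_i) and event indicators delta_i."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("observed times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0/1")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class SimulatedData:
    """One simulated scenario replicate: training data, optional test data."""

    X: GenotypeMatrix
    outcome: SurvivalOutcome
    model: TrueModel
    theta_c: float
    config: ScenarioConfig
    X_test: GenotypeMatrix | None = None
    outcome_test: SurvivalOutcome | None = None


def gen_genotypes(n: int, p: int, q: float, seed) -> GenotypeMatrix:
    """Draw an n x p genotype matrix i.i.d. under Hardy-Weinberg equilibrium.

    Codes 0/1/2 occur with probabilities (1-q)^2, 2q(1-q), q^2.  ``seed`` may
    be an int or a numpy Generator/SeedSequence.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must lie in (0, 0.5]")
    if n <= 0 or p <= 0:
        raise ValueError("n and p must be positive")
    rng = np.random.default_rng(seed)
    p0 = (1.0 - q) ** 2
    p1 = 2.0 * q * (1.0 - q)
    u = rng.random((n, p))
    codes = (u > p0).astype(np.int8) + (u > p0 + p1)
    return GenotypeMatrix(values=codes.astype(float), maf=q)


def gen_beta(p_star: int, a: float, seed, p: int | None = None) -> TrueModel:
    """Draw informative coefficients (-1)^u (a + |z|), u~Bern(1/2), z~N(0,1).

    The informative variables occupy the first ``p_star`` columns, matching
    the simulation design; ``p`` (default p_star) sets the full beta length.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    rng = np.random.default_rng(seed)
    signs = np.where(rng.random(p_star) < 0.5, 1.0, -1.0)
    mags = a + np.abs(rng.standard_normal(p_star))
    p_full = p_star if p is None else p
    beta = np.zeros(p_full)
    beta[:p_star] = signs * mags
    return TrueModel(beta=beta, informative_idx=np.arange(p_star))


def _fixture_model(name: str, p: int) -> TrueModel:
    b6 = fixture_beta(name)
    beta = np.zeros(p)
    beta[: b6.size] = b6
    return TrueModel(beta=beta, informative_idx=np.arange(b6.size))


def gen_failure_times(
    X: GenotypeMatrix | np.ndarray, model: TrueModel, tau: float, seed
) -> np.ndarray:
    """Draw Weibull failure times with cumulative hazard t^tau * exp(tau x'b).

    Inversion form: T = (-log U)^(1/tau) * exp(-x'beta).
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    if values.shape[1] < model.informative_idx.max() + 1:
        raise ValueError("X has fewer columns than the model's informative set")
    rng = np.random.default_rng(seed)
    lp = model.linear_predictor(values)
    u = rng.random(values.shape[0])
    return (-np.log(u)) ** (1.0 / tau) * np.exp(-lp)


def _genotype_combo_weights(model: TrueModel, q: float):
    """Enumerate the 3^p* informative-genotype combinations.

    Returns (lp values, probabilities) of x'beta over the informative block.
    """
    b = model.informative_beta
    probs1 = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    combos = np.array(list(itertools.product((0, 1, 2), repeat=b.size)))
    lp = combos @ b
    w = probs1[combos].prod(axis=1)
    return lp, w


def _censoring_prob_analytic(theta: float, lp: np.ndarray, w: np.ndarray,
                             tau: float) -> float:
    """P(T > C) for C ~ U(0, theta), T | lp Weibull with H(t)=t^tau e^{tau lp}.

    (1/theta) * Integral_0^theta exp(-rho t^tau) dt with rho = e^{tau lp}
    equals Gamma(1/tau) * P(1/tau, rho theta^tau) / (tau theta rho^{1/tau}),
    P being the regularized lower incomplete gamma function.
    """
    rho = np.exp(tau * lp)
    a = 1.0 / tau
    x = rho * theta**tau
    integral = special.gamma(a) * special.gammainc(a, x) / (tau * rho**a)
    return float(np.sum(w * integral) / theta)


def _censoring_prob_mc(theta: float, T: np.ndarray) -> float:
    # P(C < T | T) = min(T, theta)/theta for C ~ U(0, theta)
    return float(np.mean(np.minimum(T, theta)) / theta)


def calibrate_theta_c(
    config: ScenarioConfig,
    model: TrueModel,
    method: str = "analytic",
    mc_size: int = 200_000,
    tol: float = 1e-10,
) -> float:
    """Solve for the uniform-censoring upper bound theta_c.

    Finds theta such that the marginal censoring probability P(T > C), with
    C ~ Uniform(0, theta) independent of T and the expectation taken over the
    genotype distribution of the informative variables, equals
    ``config.cens_rate``.

    ``method='analytic'`` sums the closed-form integral over all 3^p*
    informative-genotype combinations (exact); ``method='mc'`` uses a
    large fixed-seed Monte-Carlo sample of failure times.  The censoring
    probability is continuous and strictly decreasing in theta (1 at 0+,
    0 at infinity), so a bracketed root always exists.
    """
    if not (0 < config.cens_rate < 1):
        raise ValueError("cens_rate must lie in (0, 1) to calibrate theta_c")
    if method == "analytic":
        lp, w = _genotype_combo_weights(model, config.maf)

        def achieved(theta):
            return _censoring_prob_analytic(theta, lp, w, config.tau)
    elif method == "mc":
        ss = np.random.SeedSequence([config.seed, 0x7E7A])
        Xmc = gen_genotypes(mc_size, model.informative_idx.size,
                            config.maf, ss.spawn(1)[0])
        sub = TrueModel(beta=model.informative_beta,
                        informative_idx=np.arange(model.informative_idx.size))
        T = gen_failure_times(Xmc, sub, config.tau, ss.spawn(1)[0])

        def achieved(theta):
            return _censoring_prob_mc(theta, T)
    else:
        raise ValueError("method must be 'analytic' or 'mc'")

    lo, hi = 1e-8, 1.0
    for _ in range(200):
        if achieved(hi) < config.cens_rate:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"could not bracket theta_c: censoring {achieved(hi):.4f} at "
            f"theta={hi:.3g} still above target {config.cens_rate}"
        )
    return float(optimize.brentq(
        lambda th: achieved(th) - config.cens_rate, lo, hi, xtol=tol))


def _draw_split(config: ScenarioConfig, model: TrueModel, theta_c: float,
                n: int, ss: np.random.SeedSequence):
    """Draw one dataset (genotypes + censored outcome) of size n."""
    s_geno, s_fail, s_cens = ss.spawn(3)
    X = gen_genotypes(n, config.p, config.maf, s_geno)
    T = gen_failure_times(X, model, config.tau, s_fail)
    if config.cens_rate > 0:
        C = np.random.default_rng(s_cens).uniform(0.0, theta_c, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return X, SurvivalOutcome(time=time, event=event)


def gen_dataset(
    config: ScenarioConfig,
    model: TrueModel | None = None,
    include_test: bool = False,
    theta_method: str = "analytic",
) -> SimulatedData:
    """Generate one replicate of a scenario.

    The coefficient vector comes from ``model`` if given, else from the named
    fixture ``config.signal``, else from a fresh seeded draw.  theta_c is
    calibrated once per call from the model (per-scenario calibration).
    Genotypes, coefficients, failure times and censoring times use
    independent sub-streams spawned from ``config.seed``, and the test set
    (when requested) uses fresh sub-streams with the same model and theta_c.
    """
    ss = np.random.SeedSequence(config.seed)
    s_beta, s_train, s_test = ss.spawn(3)
    if model is None:
        if config.signal is not None:
            model = _fixture_model(config.signal, config.p)
        else:
            model = gen_beta(config.p_star, config.a, s_beta, p=config.p)
    theta_c = (calibrate_theta_c(config, model, method=theta_method)
               if config.cens_rate > 0 else np.inf)
    X, outcome = _draw_split(config, model, theta_c, config.n, s_train)
    data = SimulatedData(X=X, outcome=outcome, model=model,
                         theta_c=theta_c, config=config)
    if include_test:
        data.X_test, data.outcome_test = _draw_split(
            config, model, theta_c, config.test_n, s_test)
    return data
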