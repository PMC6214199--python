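import numpy as np
import pytest

from survscreen.simdata import ScenarioConfig, SurvivalOutcome, gen_dataset


def make_censored(rng, n, x=None, beta=0.0, cens_scale=3.0):
    """Small censored dataset: exponential times with log-hazard beta*x."""
    if x is None:
        x = rng.standard_normal(n)
    T = rng.exponential(np.exp(-beta * np.asarray(x)))
    C = rng.uniform(0, cens_scale, n)
    out = SurvivalOutcome(time=np.minimum(T, C), event=(T <= C).astype(int))
    return x, out


@pytest.fixture(scope="session")
def strong2000():
    """One strong-signal replicate at n=300, p=2000, shared across tests."""
    cfg = ScenarioConfig(n=300, p=2000, signal="strong", seed=42)
    return gen_dataset(cfg, include_test=True)
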