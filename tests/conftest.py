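import numpy as np
import pytest

from coxprior import PriorSpec, SurvivalDataset, TrialConfig, gen_survival


@pytest.fixture(scope="session")
def std_normal_prior() -> PriorSpec:
    return PriorSpec(mu=0.0, sigma=1.0)


@pytest.fixture()
def two_subject_data() -> SurvivalDataset:
    """Treated subject fails first, control censored later: one risk set of 2."""
    return SurvivalDataset(time=[1.0, 2.0], event=[1, 0], arm=[1, 0])


@pytest.fixture(scope="session")
def effect_trial() -> SurvivalDataset:
    """Moderate two-arm trial with a true log-HR of 0.7."""
    return gen_survival(TrialConfig(n_per_arm=500, true_beta=0.7, seed=3))


@pytest.fixture(scope="session")
def null_trial() -> SurvivalDataset:
    return gen_survival(TrialConfig(n_per_arm=500, true_beta=0.0, seed=3))


def random_small_dataset(rng: np.random.Generator, n: int = 25) -> SurvivalDataset:
    """A small random censored two-arm dataset for oracle comparisons."""
    arm = rng.integers(0, 2, size=n)
    while arm.sum() in (0, n):  # keep both arms populated
        arm = rng.integers(0, 2, size=n)
    beta = rng.normal(0, 0.8)
    time = rng.exponential(1.0 / (0.2 * np.exp(beta * arm)))
    event = (rng.random(n) < 0.8).astype(int)
    return SurvivalDataset(time=time, event=event, arm=arm)
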