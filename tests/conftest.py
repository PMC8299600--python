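import numpy as np
import pytest

from neodl.peptide_features import FeatureVocabulary, PeptidePair
from neodl.survival_stats import SurvivalData
from neodl.synthetic_cohort import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def vocab() -> FeatureVocabulary:
    return FeatureVocabulary()


@pytest.fixture()
def pair() -> PeptidePair:
    return PeptidePair("P1", "ACDEFGHIK", "ACDQFGHIK", 4, 300.0, 800.0)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal synthetic cohort shared across tests."""
    return generate_cohort(SimConfig(n_patients=60, seed=123))


def exp_survival(n: int, beta: float, x: np.ndarray, seed: int,
                 h0: float = 1 / 400, censor: float = 1500.0) -> SurvivalData:
    """Exponential proportional-hazards survival helper for oracle tests."""
    rng = np.random.default_rng(seed)
    rate = h0 * np.exp(beta * x)
    t_event = rng.exponential(1 / rate)
    t_cens = rng.uniform(0, censor, n)
    return SurvivalData(np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int))
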