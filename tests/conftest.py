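import numpy as np
import pandas as pd
import pytest

from edflow import presets
from edflow.inference import extract_stats, fit_mle
from edflow.simulate import CohortConfig, simulate_cohort
from edflow.state_model import RateModel, generator_matrix


@pytest.fixture(scope="session")
def baseline_model() -> RateModel:
    return presets.default_model()


@pytest.fixture(scope="session")
def Q(baseline_model) -> np.ndarray:
    return generator_matrix(baseline_model)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """2,000-patient cohort at the reference rates (shared, fixed seed)."""
    return simulate_cohort(CohortConfig(n_patients=2000, seed=20130101))


@pytest.fixture(scope="session")
def big_cohort() -> pd.DataFrame:
    """200,000-patient cohort at the reference rates (shared, fixed seed)."""
    return simulate_cohort(CohortConfig(n_patients=200_000, seed=20130102))


def random_rate_model(rng: np.random.Generator) -> RateModel:
    """A random admissible homogeneous model (rates log-uniform)."""
    baseline = {
        t: float(np.exp(rng.uniform(np.log(1e-3), np.log(5.0))))
        for t in presets.BASELINE_RATES
    }
    return RateModel(baseline=baseline)


def wald_ci_coverage(
    n_reps: int = 200, n_patients: int = 2000, transition=(2, 4), seed: int = 909
) -> float:
    """Fraction of replicates whose 95% Wald CI for one rate covers the truth."""
    truth = presets.BASELINE_RATES[transition]
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % 2**31
    covered = 0
    for s in seeds:
        df = simulate_cohort(CohortConfig(n_patients=n_patients, seed=int(s)))
        iv = fit_mle(extract_stats(df)).rates[transition]
        covered += iv.low <= truth <= iv.high
    return covered / n_reps
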