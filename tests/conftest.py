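import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from reo_prognosis import SimConfig, fit_signature, generate, preprocess_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def split_roles(cohorts):
    training = [c for c in cohorts if c.role == "training"]
    test = next(c for c in cohorts if c.role == "test")
    validation = next(c for c in cohorts if c.role == "validation")
    return training, test, validation


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study-sized configuration.

    3 training cohorts of 150 samples, 1 test, 1 validation; 300 genes,
    30 planted prognostic genes, log-hazard 1 per latent-risk unit, ~30%
    censoring, platform distortions on. Shared across tests that need a
    fitted signature.
    """
    cohorts, truth = generate(SimConfig(seed=1))
    cohorts = [preprocess_cohort(c) for c in cohorts]
    training, test, validation = split_roles(cohorts)
    sig, info = fit_signature(training, test)
    return {"cohorts": cohorts, "truth": truth, "training": training,
            "test": test, "validation": validation, "signature": sig,
            "info": info}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, censor_frac=0.3, effect=0.0, score=None):
    """Simple exponential survival draw for statistics unit tests."""
    if score is None:
        score = np.zeros(n)
    t_event = rng.exponential(40.0 * np.exp(-effect * score))
    if censor_frac > 0:
        t_cens = rng.exponential(40.0 * (1 - censor_frac) / censor_frac, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)
    return time, event
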