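import numpy as np
import pytest

from elma import elma_core as ec
from elma import event_history as eh
from elma import exposure_weights as ew
from elma import synthetic_registry as sr
from elma.states import RECURRENT_STATES, STATE_INDEX


def start_vector(config: sr.SimConfig) -> np.ndarray:
    pi = np.zeros(7)
    for s, p in zip(RECURRENT_STATES, config.start_distribution):
        pi[STATE_INDEX[s]] = p
    return pi


def prepare(cohort: sr.SyntheticCohort, horizon: int = 730):
    """Simulated cohort -> (censored episodes, analysis baseline, records)."""
    base = ew.add_exposure_level(cohort.baseline)
    base = ew.assign_strata(base)
    epi = eh.apply_censoring(cohort.episodes, base, horizon=horizon)
    records = eh.to_transition_records(epi, base)
    return epi, base, records


@pytest.fixture(scope="session")
def small_cohort() -> sr.SyntheticCohort:
    """Multi-stratum cohort, default study conditions, modest size."""
    return sr.simulate_cohort(sr.default_sim_config(n_persons=600, seed=42))


@pytest.fixture(scope="session")
def single_stratum_cohort() -> sr.SyntheticCohort:
    """One stratum with balanced exposure cells for estimator tests."""
    cfg = sr.SimConfig(
        n_persons=2000, seed=7, strata=(("M", "35-49"),),
        stress_prevalence={"M:35-49": (0.3, 0.3, 0.3)},
    )
    return sr.simulate_cohort(cfg)
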