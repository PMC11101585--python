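import dataclasses
import logging
import warnings

import pytest

import ghqits as g

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")
logging.getLogger("ghqits").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A default-calibration cohort of 600 persons with missingness."""
    cfg = g.SimulationConfig(n_persons=600, seed=42)
    persons, observations, truth = g.simulate_cohort(cfg)
    observations = g.inject_missingness(observations, cfg)
    return persons, observations, truth, cfg


@pytest.fixture(scope="session")
def fast_model():
    """Reduced-draw model spec for desk-scale fits."""
    return dataclasses.replace(g.ITSModelSpec(), draws=200, warmup=100)


@pytest.fixture(scope="session")
def fast_imputation():
    return g.ImputationConfig(n_imputations=2, n_iterations=2)


@pytest.fixture(scope="session")
def main_result(small_cohort, fast_model, fast_imputation):
    persons, observations, _, _ = small_cohort
    plan = g.AnalysisPlan(
        persons=persons,
        observations=observations,
        model=fast_model,
        imputation=fast_imputation,
        seed=7,
    )
    return g.run_main(plan), plan
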