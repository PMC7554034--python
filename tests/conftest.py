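import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# statsmodels boundary fits legitimately warn; keep test output readable
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_config():
    from contrabias.design import TaskConfig

    return TaskConfig()


@pytest.fixture(scope="session")
def small_config():
    """Two blocks of 40: enough structure for model fits, fast to simulate."""
    from contrabias.design import TaskConfig

    return TaskConfig(block_diff_percent=(3.0, 2.0), trials_per_block=40)


@pytest.fixture(scope="session")
def labeled_cohort():
    """A small two-group labeled cohort with RTs, shared across tests."""
    from contrabias.bias import label_cohort
    from contrabias.design import TaskConfig
    from contrabias.observer import ObserverParams, simulate_cohort

    cfg = TaskConfig(block_diff_percent=(3.0, 2.0), trials_per_block=40)
    strong = ObserverParams(lambda_contraction=0.006, rt_model=("lognormal", 6.8, 0.25))
    weak = ObserverParams(lambda_contraction=0.001, rt_model=("lognormal", 6.84, 0.25))
    df = simulate_cohort([("TD", 6, strong), ("ASD", 6, weak)], config=cfg, seed=123)
    return label_cohort(df)


@pytest.fixture(scope="session")
def default_labeled_cohort():
    """The full default (included-sample) cohort, labeled."""
    from contrabias.bias import label_cohort
    from contrabias.observer import default_cohort

    return label_cohort(default_cohort(seed=7))
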