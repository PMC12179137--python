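import numpy as np
import pytest

from circabp import ModelParams, SyntheticConfig, eval_basic, generate_dataset


@pytest.fixture(scope="session")
def reference_params() -> ModelParams:
    return ModelParams(base=100, incr=20, k=0.3, t1=5, t2=22)


@pytest.fixture(scope="session")
def dense_day():
    """One noise-free day sampled on an even 48-point grid; truth lies
    strictly inside the systolic bounds."""
    truth = ModelParams(base=105, incr=18, k=0.5, t1=6, t2=22)
    t = np.linspace(0.0, 23.5, 48)
    return truth, [(ti, eval_basic(truth, ti)) for ti in t]


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort (3 subjects, 4 days) kept light so
    fitting-based tests stay fast."""
    cfg = SyntheticConfig(n_subjects=3, n_days=4, seed=7)
    measurements, truth = generate_dataset(cfg)
    return cfg, measurements, truth
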