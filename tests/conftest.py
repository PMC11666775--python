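import numpy as np
import pandas as pd
import pytest

from nedpd import io as nio
from nedpd.cognitive_model import MODEL_SPECS, ParameterSet
from nedpd.synthetic_cohort import CohortConfig, generate_cohort
from nedpd.task_env import RandomPolicy, SessionConfig, run_session


@pytest.fixture(scope="session")
def tiny_cohort():
    """Five model-driven participants, 120 trials each (shared, read-only)."""
    cfg = CohortConfig(n_participants=5, n_trials=120, rng_seed=42)
    records, truths = generate_cohort(cfg)
    return records, truths, cfg


@pytest.fixture(scope="session")
def one_session():
    cfg = SessionConfig(n_trials=150, rng_seed=7)
    records = run_session(cfg, RandomPolicy(0.6))
    return nio.records_to_frame(records)


@pytest.fixture()
def mid_params():
    """Parameter set at the fitted group-level posterior means."""
    return ParameterSet(V0C=1.366, VRD=3.481, VP=2.536, alpha=0.567, k=0.638)


@pytest.fixture(params=list(MODEL_SPECS))
def any_spec(request):
    return MODEL_SPECS[request.param]
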