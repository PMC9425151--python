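import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svhbench.svh_model import ScoreSheet, default_registry
from svhbench.synthetic_data import CohortConfig, TeamNoiseConfig, generate_cohort, generate_submission

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_cohort(registry):
    """Ten-patient synthetic ground-truth cohort, fixed seed."""
    return generate_cohort(CohortConfig(n_patients=10, seed=42), registry)


@pytest.fixture(scope="session")
def medium_cohort(registry):
    return generate_cohort(CohortConfig(n_patients=60, seed=7), registry)


@pytest.fixture
def make_submission(registry):
    def _make(truth, team_id="team", error_sd=0.3, seed=0, **kwargs):
        cfg = TeamNoiseConfig(team_id=team_id, error_sd=error_sd, seed=seed, **kwargs)
        return generate_submission(truth, cfg, registry)
    return _make


def make_sheet(registry, values, patient_id="P1"):
    """ScoreSheet from a per-area value array (or constant)."""
    if np.isscalar(values):
        values = [min(values, a.max_score) for a in registry]
    return ScoreSheet(patient_id, {a: int(v) for a, v in zip(registry, values)})


@pytest.fixture
def sheet_factory(registry):
    def _make(values, patient_id="P1"):
        return make_sheet(registry, values, patient_id)
    return _make
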