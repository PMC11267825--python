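import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulmotrack.config import AnalysisParams, SimConfig
from pulmotrack.pipeline import extract_subject
from pulmotrack.simulate import simulate_subject

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nonoise_cfg() -> SimConfig:
    """Single noise-free subject at the configured population baselines."""
    return SimConfig(noise_sd={}, inter_subject_sd={}, n_subjects=1)


@pytest.fixture(scope="session")
def nonoise_subject(nonoise_cfg):
    """Short noise-free baseline recording (apnea + 4 baseline breaths)."""
    return simulate_subject(nonoise_cfg, 0, t_end=-36.0)


@pytest.fixture(scope="session")
def nonoise_tables(nonoise_subject):
    eit, airway, events, truth = nonoise_subject
    tables = extract_subject("subject_01", eit, airway, events, AnalysisParams())
    return tables, truth


@pytest.fixture(scope="session")
def edema_subject():
    """Noise-free recording spanning baseline through the 120-s plateau."""
    cfg = SimConfig(noise_sd={}, inter_subject_sd={}, n_subjects=1)
    return cfg, simulate_subject(cfg, 0, t_end=126.0)


@pytest.fixture(scope="session")
def edema_tables(edema_subject):
    cfg, (eit, airway, events, truth) = edema_subject
    tables = extract_subject("subject_01", eit, airway, events, AnalysisParams())
    return cfg, tables, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240710)
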