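"""Shared fixtures: the reduced-study training runs are expensive, so the
sparsity grid and the recovery study are computed once per session and
shared by every test that needs a trained model."""

import pytest

from sparsebagnet.experiments import (
    ReducedStudyConfig,
    run_recovery_study,
    run_sparsity_grid,
)

STUDY_SEED = 0  # canonical seed of the reduced benchmark study


@pytest.fixture(scope="session")
def study_seed():
    return STUDY_SEED


@pytest.fixture(scope="session")
def study_config():
    return ReducedStudyConfig()


@pytest.fixture(scope="session")
def sparsity_grid(study_config):
    """Quick trainings across the sparsity grid (three reduced runs)."""
    return run_sparsity_grid(study_config, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def recovery_study(study_config):
    """The full reduced recovery study (one sparse training run)."""
    return run_recovery_study(study_config, seed=STUDY_SEED)
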