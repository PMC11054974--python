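"""Shared fixtures: phantom configs and the (expensive) seeded desk-scale
experiment results, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ripefuse.config import RunConfig
from ripefuse.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def desk_config():
    return RunConfig.desk(seed=1)


@pytest.fixture(scope="session")
def stage_result(desk_config):
    """One seeded desk-scale unimodal-versus-fusion run, shared by the
    end-to-end tests."""
    from ripefuse.pipeline import run_stage_experiment

    return run_stage_experiment(desk_config)


@pytest.fixture(scope="session")
def het_result(desk_config, stage_result):
    """The heterogeneous internal/external ripening validation run."""
    from ripefuse.pipeline import run_heterogeneous_experiment

    return run_heterogeneous_experiment(desk_config, stage_result=stage_result)
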