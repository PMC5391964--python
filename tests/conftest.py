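"""Shared fixtures: small circuits and cached mid-size ensembles.

Heavier ensembles used by several acceptance checks are session-scoped so
each is simulated once per test run.
"""

import numpy as np
import pytest

from racipe import (EnsembleConfig, SamplingConfig, SolverSettings,
                    builtin_circuit, run_ensemble)


@pytest.fixture(scope="session")
def ts():
    return builtin_circuit("TS")


@pytest.fixture(scope="session")
def ts_ensemble():
    """2,000-model toggle-switch ensemble under the default scheme."""
    return run_ensemble(EnsembleConfig(topology=builtin_circuit("TS"),
                                       n_models=2000, master_seed=101))


@pytest.fixture(scope="session")
def ts2sa_ensemble():
    """2,000-model ensemble of the toggle switch with both self-activations."""
    return run_ensemble(EnsembleConfig(topology=builtin_circuit("TS2SA"),
                                       n_models=2000, master_seed=103))


@pytest.fixture(scope="session")
def ts1sa_ensemble_large():
    """10,000-model one-sided self-activation ensemble (resolves the ~1%
    tristable fraction)."""
    return run_ensemble(EnsembleConfig(topology=builtin_circuit("TS1SA"),
                                       n_models=10_000, master_seed=107))
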