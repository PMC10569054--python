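"""Shared fixtures: small LJ references and the trained-pipeline studies.

Heavy Monte Carlo artifacts are session-scoped so the sampler tests, the
structure tests and the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nncg import protocols
from nncg.config_io import PeriodicConfiguration
from nncg.mc_sampler import ThermoState
from nncg.training import ReferenceSystem

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


desk_state = protocols.desk_state
desk_run = protocols.desk_run


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_config():
    r = np.random.default_rng(7)
    return PeriodicConfiguration(r.uniform(0, 20.0, size=(30, 3)), np.full(3, 20.0))


@pytest.fixture(scope="session")
def lj_bundle():
    """Desk-scale liquid-argon reference (2e6 MC steps, 200 frames)."""
    return protocols.desk_reference(seed=11)


@pytest.fixture(scope="session")
def lj_system(lj_bundle):
    return ReferenceSystem(
        "lj", lj_bundle.rdf, lj_bundle.frames, ThermoState(protocols.DESK_T)
    )


@pytest.fixture(scope="session")
def trained_lj(lj_bundle):
    """End-to-end LJ recovery study (pretrain + 15 training iterations)."""
    return protocols.lj_recovery_study(seed=1, bundle=lj_bundle)


@pytest.fixture(scope="session")
def imc_recovery(lj_bundle):
    return protocols.imc_recovery_study(seed=1, bundle=lj_bundle)


@pytest.fixture(scope="session")
def equivalence_report():
    return protocols.equivalence_study(seed=1)


@pytest.fixture(scope="session")
def transfer_result():
    return protocols.transfer_study(seed=1)


@pytest.fixture(scope="session")
def gradient_check():
    from nncg.training import gradient_estimator_check

    return gradient_estimator_check(seed=1)
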