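"""Shared fixtures: standard conditions and cached simulations.

Simulation-heavy fixtures are session-scoped so the voltammograms are
computed once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from voltdiff.conditions import (
    ExperimentConditions,
    Mechanism,
    MechanismSpec,
    NumericsConfig,
)
from voltdiff.cvsim import simulate_cv
from voltdiff.pipeline import standard_conditions


@pytest.fixture(scope="session")
def qr_conditions() -> ExperimentConditions:
    """Standard conditions over the quasi-reversible window (0 -> 0.5 V)."""
    return standard_conditions(0.5)


@pytest.fixture(scope="session")
def ec_conditions() -> ExperimentConditions:
    """Standard conditions over the follow-up-mechanism window (0 -> 0.7 V)."""
    return standard_conditions(0.7)


@pytest.fixture(scope="session")
def erev_spec() -> MechanismSpec:
    return MechanismSpec(kind=Mechanism.E_REV, e0=0.2108, D=1e-5)


@pytest.fixture(scope="session")
def cv_erev(erev_spec, qr_conditions):
    """Reversible one-electron voltammogram at the standard conditions."""
    return simulate_cv(erev_spec, qr_conditions)


@pytest.fixture(scope="session")
def cv_erev_refined(erev_spec, qr_conditions):
    """Same voltammogram on a grid refined 2x in space and time."""
    return simulate_cv(erev_spec, qr_conditions, NumericsConfig().refined(2))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20140528)
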