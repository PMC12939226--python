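"""Shared fixtures: material defaults and the calibrated 50 degC study runs.

The calibrated runs are expensive (a calibration search plus the final
simulation), so they are session-scoped and shared between the simulator
tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zandry import MaterialProperties
from zandry.scenarios import calibrated_run

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props() -> MaterialProperties:
    return MaterialProperties()


@pytest.fixture(scope="session")
def mvd_run():
    """Calibrated microwave-vacuum run at 50 degC (bulk-layer slab)."""
    return calibrated_run("MVD", 50.0)


@pytest.fixture(scope="session")
def had_run():
    """Calibrated hot-air run at 50 degC (bulk-layer slab)."""
    return calibrated_run("HAD", 50.0)


@pytest.fixture(scope="session")
def pvd_run():
    """Calibrated pulsed-vacuum infrared run at 50 degC (berry sphere)."""
    return calibrated_run("PVD", 50.0)
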