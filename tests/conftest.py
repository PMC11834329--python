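"""Shared fixtures.

Full-protocol runs (1.2e4 h burn-in) are expensive, so the handful that
several tests share are session-scoped. Unit tests that only need the
dynamics, not the published protocol, use a short burn-in instead.
"""

import pytest

from scn_poincare import (
    ForcingSchedule,
    PARAM_PRESETS,
    SimulationSettings,
    config1,
    simulate,
)

SET_A = PARAM_PRESETS["set_a"]


@pytest.fixture(scope="session")
def baseline_light_only():
    """Entrained light-only reference: config1, set_a, K_L=1, full protocol."""
    schedule = ForcingSchedule(light_strength=1.0, pa_strength=0.0)
    return simulate(SET_A, schedule, config1(), SimulationSettings(seed=1))


@pytest.fixture(scope="session")
def baseline_diurnal_pa():
    """Entrained diurnal run with excitatory PA (K_PA=0.5), full protocol."""
    schedule = ForcingSchedule(
        light_strength=1.0, pa_strength=0.5, chronotype="diurnal"
    )
    return simulate(SET_A, schedule, config1(), SimulationSettings(seed=1))


@pytest.fixture(scope="session")
def free_run():
    """Unforced limit cycle (K_L=K_PA=0, g=0), full protocol."""
    schedule = ForcingSchedule(light_strength=0.0, pa_strength=0.0)
    return simulate(SET_A, schedule, config1(), SimulationSettings(seed=2))


@pytest.fixture
def short_settings():
    """Reduced horizon for unit tests of mechanics, not of the protocol."""
    return SimulationSettings(burn_in=200.0, t_end=200.0 + 10 * 24.0, seed=0)
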