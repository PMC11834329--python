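"""Unit tests for the model right-hand side and its forcing terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scn_poincare import (
    ForcingSchedule,
    NetworkConfig,
    OscillatorParams,
    config1,
    config2,
    config3,
    derivatives,
    light_input,
    mean_field,
    pa_input,
    radius,
)

SET_A = OscillatorParams(0.4, 1.8, 24.0)


class TestLightInput:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, 1.0),      # lights-on instant belongs to the light phase
            (6.0, 1.0),
            (11.999, 1.0),
            (12.0, 0.0),     # lights-off boundary enters the dark phase
            (18.0, 0.0),
            (24.0, 1.0),     # next cycle
        ],
    )
    def test_square_wave(self, t, expected):
        sched = ForcingSchedule(light_strength=1.0)
        assert light_input(t, sched, 0, config1()) == expected

    def test_non_receptive_oscillator_gets_nothing(self):
        sched = ForcingSchedule(light_strength=1.0)
        cfg = config2()  # oscillator 1 is PA-only
        for t in (0.0, 6.0, 18.0):
            assert light_input(t, sched, 1, cfg) == 0.0

    def test_photoperiod_fraction_sets_light_duration(self):
        sched = ForcingSchedule(photoperiod_fraction=0.25, light_strength=0.7)
        assert light_input(5.9, sched, 0, config1()) == 0.7
        assert light_input(6.0, sched, 0, config1()) == 0.0


class TestPAInput:
    @pytest.mark.parametrize(
        "chronotype, t, k_pa, expected",
        [
            ("diurnal", 6.0, 0.8, 0.8),      # active in the light phase
            ("diurnal", 18.0, 0.8, 0.0),
            ("nocturnal", 6.0, -0.8, 0.0),   # inactive in the light phase
            ("nocturnal", 18.0, -0.8, -0.8),
        ],
    )
    def test_chronotype_gates_timing(self, chronotype, t, k_pa, expected):
        sched = ForcingSchedule(pa_strength=k_pa, chronotype=chronotype)
        assert pa_input(t, sched, 0, config1()) == expected

    def test_non_receptive_oscillator_gets_nothing(self):
        sched = ForcingSchedule(pa_strength=1.0, chronotype="diurnal")
        cfg = config3()  # oscillator 1 receives no input
        for t in (0.0, 6.0, 18.0):
            assert pa_input(t, sched, 1, cfg) == 0.0


def test_radius_examples():
    assert radius(3.0, 4.0) == pytest.approx(5.0)
    assert radius(0.0, 0.0) == 0.0
    assert radius(1.8, 0.0) == pytest.approx(1.8)


def test_mean_field():
    assert mean_field([1.0, 1.0]) == 1.0
    assert mean_field([2.0, 0.0]) == 1.0
    assert mean_field([0.37]) == 0.37  # single oscillator: F is itself
    with pytest.raises(ValueError):
        mean_field([])


class TestDerivatives:
    def test_point_on_free_limit_cycle(self):
        """At (a, 0) with no forcing the radial term vanishes: pure rotation."""
        sched = ForcingSchedule(light_strength=0.0, pa_strength=0.0)
        d = derivatives(3.0, np.array([1.8, 0.0]), [SET_A], sched, config1())
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[1] == pytest.approx(2 * np.pi * 1.8 / 24.0)

    def test_origin_is_a_fixed_point(self):
        sched = ForcingSchedule(light_strength=0.0, pa_strength=0.0)
        d = derivatives(0.0, np.zeros(2), [SET_A], sched, config1())
        assert np.allclose(d, 0.0)

    def test_two_oscillator_hand_computed(self):
        """Term-by-term hand evaluation of the coupled RHS (independent oracle).

        x=(1,3), y=(0,0), a=1.8, λ=0.4, τ=24, g=0.1, no inputs:
        F = 2, r = (1, 3), so
          dx1 = 0.4·1·(1.8−1) + 0.1·2 = 0.52
          dx2 = 0.4·3·(1.8−3) + 0.1·2 = −1.24
          dy_i = (2π/24)·x_i
        """
        sched = ForcingSchedule(light_strength=0.0, pa_strength=0.0)
        cfg = config2()
        state = np.array([1.0, 3.0, 0.0, 0.0])
        d = derivatives(0.0, state, [SET_A, SET_A], sched, cfg)
        assert d[0] == pytest.approx(0.4 * 1.0 * (1.8 - 1.0) + 0.1 * 2.0)
        assert d[1] == pytest.approx(0.4 * 3.0 * (1.8 - 3.0) + 0.1 * 2.0)
        assert d[2] == pytest.approx(2 * np.pi / 24.0 * 1.0)
        assert d[3] == pytest.approx(2 * np.pi / 24.0 * 3.0)

    def test_forcing_enters_dx_only(self):
        """Light and PA act on dx; dy is identical with and without them."""
        quiet = ForcingSchedule(light_strength=0.0, pa_strength=0.0)
        forced = ForcingSchedule(light_strength=1.0, pa_strength=0.8)
        state = np.array([0.3, -0.9])
        d0 = derivatives(3.0, state, [SET_A], quiet, config1())
        d1 = derivatives(3.0, state, [SET_A], forced, config1())
        assert d1[1] == d0[1]
        assert d1[0] == pytest.approx(d0[0] + 1.0 + 0.8)

    def test_mismatched_params_rejected(self):
        sched = ForcingSchedule()
        with pytest.raises(ValueError):
            derivatives(0.0, np.zeros(4), [SET_A], sched, config2())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        t=st.floats(0.0, 1000.0, allow_nan=False),
        x=st.floats(-3, 3),
        y=st.floats(-3, 3),
        k=st.integers(1, 5),
    )
    def test_periodic_in_time(self, t, x, y, k):
        """The only time dependence is the T-periodic forcing."""
        sched = ForcingSchedule(light_strength=1.0, pa_strength=-0.6,
                                chronotype="nocturnal")
        state = np.array([x, y])
        d1 = derivatives(t, state, [SET_A], sched, config1())
        d2 = derivatives(t + k * 24.0, state, [SET_A], sched, config1())
        assert np.allclose(d1, d2, atol=1e-12)

    def test_zero_pa_makes_config2_and_config3_inputs_identical(self):
        """With K_PA=0 the two network layouts receive the same drive."""
        sched = ForcingSchedule(light_strength=1.0, pa_strength=0.0)
        state = np.array([0.5, -0.2, 1.1, 0.4])
        d2 = derivatives(5.0, state, [SET_A, SET_A], sched, config2())
        d3 = derivatives(5.0, state, [SET_A, SET_A], sched, config3())
        assert np.array_equal(d2, d3)


class TestTypes:
    @pytest.mark.parametrize("bad", [dict(relaxation_rate=0.0),
                                     dict(intrinsic_amplitude=-1.0),
                                     dict(intrinsic_period=0.0)])
    def test_oscillator_params_validation(self, bad):
        with pytest.raises(ValueError):
            OscillatorParams(**bad)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            ForcingSchedule(photoperiod_fraction=1.0)
        with pytest.raises(ValueError):
            ForcingSchedule(chronotype="crepuscular")

    def test_named_presets(self):
        c1, c2, c3 = config1(), config2(), config3()
        assert (c1.n_oscillators, c1.coupling_strength) == (1, 0.0)
        assert c2.light_receptive == {0} and c2.pa_receptive == {1}
        assert c3.light_receptive == {0} and c3.pa_receptive == {0}
        assert c2.coupling_strength == c3.coupling_strength == 0.1

    def test_single_oscillator_must_have_zero_coupling(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_oscillators=1, coupling_strength=0.1)

    def test_receptive_sets_must_be_valid_indices(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_oscillators=1, pa_receptive=frozenset({3}))
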