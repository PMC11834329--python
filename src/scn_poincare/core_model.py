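"""Poincaré limit-cycle model of SCN subpopulations with light and activity drive.

Each neuronal subpopulation is a two-variable (x, y) Poincaré oscillator with
radial relaxation ``dr/dt = λ r (a − r)`` and angular speed ``2π/τ``.
Oscillators are coupled through the mean field of ``x`` (global
neurotransmitter diffusion), and two square-wave inputs act on the ``x``
equation only: light ``L`` during the light phase of the zeitgeber cycle, and
physical-activity (PA) feedback whose timing follows the chronotype — a
diurnal animal is active in the light phase, a nocturnal one in the dark
phase.

Everything here is a pure function of (t, state, parameters); integration
lives in :mod:`scn_poincare.simulation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Literal

import numpy as np

__all__ = [
    "OscillatorParams",
    "ForcingSchedule",
    "NetworkConfig",
    "config1",
    "config2",
    "config3",
    "light_input",
    "pa_input",
    "radius",
    "mean_field",
    "derivatives",
]

Chronotype = Literal["diurnal", "nocturnal"]


@dataclass(frozen=True)
class OscillatorParams:
    """Intrinsic dynamics of one oscillator (subpopulation).

    Parameters
    ----------
    relaxation_rate : float
        Amplitude relaxation rate λ (1/h). Larger values make the limit
        cycle stiffer. Optimised range 0.35–0.45.
    intrinsic_amplitude : float
        Free-running limit-cycle radius ``a`` (dimensionless), range 1.2–2.1.
    intrinsic_period : float
        Free-running period τ (h), range 23.5–24.5.
    """

    relaxation_rate: float = 0.4
    intrinsic_amplitude: float = 1.8
    intrinsic_period: float = 24.0

    def __post_init__(self) -> None:
        if self.relaxation_rate <= 0:
            raise ValueError("relaxation_rate must be > 0")
        if self.intrinsic_amplitude <= 0:
            raise ValueError("intrinsic_amplitude must be > 0")
        if self.intrinsic_period <= 0:
            raise ValueError("intrinsic_period must be > 0")


@dataclass(frozen=True)
class ForcingSchedule:
    """External drive: the zeitgeber cycle and the two square-wave inputs.

    ``photoperiod_fraction`` is the fraction of the cycle spent in light;
    0.5 is the 12:12 light-dark cycle. The chronotype encodes the (d, n)
    switch of the PA input: diurnal ⇒ PA during light, nocturnal ⇒ PA
    during darkness. ``pa_strength`` is signed — positive is excitatory,
    negative inhibitory.
    """

    cycle_period: float = 24.0
    photoperiod_fraction: float = 0.5
    light_strength: float = 1.0
    pa_strength: float = 0.0
    chronotype: Chronotype = "diurnal"

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be > 0")
        if not 0.0 < self.photoperiod_fraction < 1.0:
            raise ValueError("photoperiod_fraction must lie in (0, 1)")
        if self.chronotype not in ("diurnal", "nocturnal"):
            raise ValueError(f"unknown chronotype: {self.chronotype!r}")

    @property
    def d(self) -> int:
        """Diurnal gate: 1 when PA coincides with the light phase."""
        return 1 if self.chronotype == "diurnal" else 0

    @property
    def n(self) -> int:
        """Nocturnal gate: 1 when PA coincides with the dark phase."""
        return 1 - self.d

    def in_light_phase(self, t: float) -> bool:
        """True when the zeitgeber is in its light phase (right-continuous)."""
        return (t % self.cycle_period) < self.photoperiod_fraction * self.cycle_period


@dataclass(frozen=True)
class NetworkConfig:
    """Which oscillators exist and which receive light / PA input.

    ``light_receptive`` and ``pa_receptive`` are 0-based oscillator index
    sets (the A oscillator is index 0). Coupling is mean-field with
    strength ``g``; a single oscillator has no self-feedback, so g = 0.
    """

    n_oscillators: int = 1
    light_receptive: FrozenSet[int] = field(default_factory=lambda: frozenset({0}))
    pa_receptive: FrozenSet[int] = field(default_factory=lambda: frozenset({0}))
    coupling_strength: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_oscillators < 1:
            raise ValueError("need at least one oscillator")
        valid = set(range(self.n_oscillators))
        if not set(self.light_receptive) <= valid:
            raise ValueError("light_receptive indices out of range")
        if not set(self.pa_receptive) <= valid:
            raise ValueError("pa_receptive indices out of range")
        if self.n_oscillators == 1 and self.coupling_strength != 0.0:
            raise ValueError("single-oscillator network has no self-feedback (g must be 0)")


def config1() -> NetworkConfig:
    """Single oscillator, both light- and PA-receptive (g = 0)."""
    return NetworkConfig(1, frozenset({0}), frozenset({0}), 0.0, name="config1")


def config2(g: float = 0.1) -> NetworkConfig:
    """Two oscillators: A light-receptive, B PA-receptive."""
    return NetworkConfig(2, frozenset({0}), frozenset({1}), g, name="config2")


def config3(g: float = 0.1) -> NetworkConfig:
    """Two oscillators: A light- and PA-receptive, B receives no input."""
    return NetworkConfig(2, frozenset({0}), frozenset({0}), g, name="config3")


NAMED_CONFIGS = {"config1": config1, "config2": config2, "config3": config3}


def light_input(
    t: float, schedule: ForcingSchedule, i: int, config: NetworkConfig
) -> float:
    """Square-wave light drive L_i(t): K_L during the light phase for i ∈ LS.

    Right-continuous: the value at a switch instant belongs to the incoming
    phase (the light-phase condition is a strict inequality).
    """
    if i not in config.light_receptive:
        return 0.0
    return schedule.light_strength if schedule.in_light_phase(t) else 0.0


def pa_input(
    t: float, schedule: ForcingSchedule, i: int, config: NetworkConfig
) -> float:
    """Square-wave activity feedback PA_i(t) gated by chronotype.

    For i ∈ PAS returns ``d·K_PA`` in the light phase and ``n·K_PA`` in the
    dark phase; 0 otherwise. With d + n = 1 this is K_PA during the animal's
    active phase and 0 during rest.
    """
    if i not in config.pa_receptive:
        return 0.0
    if schedule.in_light_phase(t):
        return schedule.d * schedule.pa_strength
    return schedule.n * schedule.pa_strength


def radius(x, y):
    """Instantaneous oscillator amplitude r = sqrt(x² + y²)."""
    return np.hypot(x, y)


def mean_field(x_values) -> float:
    """Mean field F: the arithmetic mean of x over all oscillators.

    The average includes every oscillator (self-contribution included).
    """
    x_values = np.asarray(x_values, dtype=float)
    if x_values.size == 0:
        raise ValueError("mean_field of an empty population is undefined")
    return float(x_values.mean())


def derivatives(
    t: float,
    state: np.ndarray,
    params: list[OscillatorParams] | tuple[OscillatorParams, ...],
    schedule: ForcingSchedule,
    config: NetworkConfig,
) -> np.ndarray:
    """Right-hand side of the forced, coupled Poincaré system.

    ``state`` is ``[x_1..x_N, y_1..y_N]``. For each oscillator i:

        dx_i/dt = λ_i x_i (a_i − r_i) − (2π/τ_i) y_i + g F + L_i + PA_i
        dy_i/dt = λ_i y_i (a_i − r_i) + (2π/τ_i) x_i

    Coupling and both inputs act on dx only; dy carries no input term.
    """
    N = config.n_oscillators
    if len(params) != N:
        raise ValueError(f"expected {N} parameter sets, got {len(params)}")
    state = np.asarray(state, dtype=float)
    if state.shape != (2 * N,):
        raise ValueError(f"state must have length {2 * N}")

    x = state[:N]
    y = state[N:]
    r = radius(x, y)
    F = mean_field(x)

    lam = np.array([p.relaxation_rate for p in params])
    a = np.array([p.intrinsic_amplitude for p in params])
    omega = 2.0 * np.pi / np.array([p.intrinsic_period for p in params])

    drive = np.array(
        [
            light_input(t, schedule, i, config) + pa_input(t, schedule, i, config)
            for i in range(N)
        ]
    )

    dx = lam * x * (a - r) - omega * y + config.coupling_strength * F + drive
    dy = lam * y * (a - r) + omega * x
    return np.concatenate([dx, dy])
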