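"""Rhythm readouts: amplitude, peak zeitgeber time, period, entrainment.

A trace (the ensemble mean of x, or a single oscillator's x) is reduced to
the quantities the experiments report. Amplitude is the absolute
peak-to-trough difference; phase is the peak time expressed in zeitgeber
time (ZT), with ZT0 at lights-on and ZT12 at lights-off; the rhythm counts
as properly entrained when its period matches the zeitgeber cycle and the
peak falls between ZT3 and ZT9 (for a 24-h cycle).

Peak locations are refined below the sampling grid with a three-point
quadratic fit, and phase uses circular statistics so peaks straddling
ZT0/ZT24 do not average to ZT12.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import scipy.signal

from .simulation import Trajectory

__all__ = [
    "ArrhythmicError",
    "RhythmMetrics",
    "SyntheticTrace",
    "find_peaks",
    "find_troughs",
    "amplitude",
    "estimate_period",
    "peak_phase_zt",
    "is_entrained",
    "compute_metrics",
    "amplitude_increase_pct",
    "make_synthetic_trace",
]

#: number of trailing cycles averaged by default for amplitude/period/phase
DEFAULT_N_CYCLES = 10

#: entrainment period tolerance (h); the entrained-phase window is
#: [T/8, 3T/8], i.e. ZT3-ZT9 for a 24-h cycle
PERIOD_TOL = 0.1


class ArrhythmicError(ValueError):
    """The trace has no usable rhythm (too few peaks)."""


@dataclass(frozen=True)
class RhythmMetrics:
    """Summary of one rhythmic trace."""

    amplitude: float
    peak_zt: float
    period: float
    entrained: bool
    n_cycles_used: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class SyntheticTrace:
    """Periodic test trace whose amplitude/period/phase are known exactly."""

    times: np.ndarray
    values: np.ndarray
    true_amplitude: float
    true_period: float
    true_peak_zt: float


def _as_series(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, Trajectory):
        return trace.times, trace.ensemble_trace
    if isinstance(trace, SyntheticTrace):
        return trace.times, trace.values
    times, values = trace
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def _refine(times, values, idx, sign=1.0):
    """Sub-grid extremum via a parabola through the 3 samples around idx."""
    if idx == 0 or idx == len(times) - 1:
        return times[idx], values[idx]
    t0, t1, t2 = times[idx - 1 : idx + 2]
    v0, v1, v2 = sign * values[idx - 1 : idx + 2]
    denom = (v0 - 2 * v1 + v2)
    if denom >= 0:  # no downward curvature: keep the grid point
        return times[idx], values[idx]
    h = (t2 - t0) / 2.0
    delta = 0.5 * (v0 - v2) / denom * h
    delta = float(np.clip(delta, -h, h))
    v_ext = v1 - 0.25 * (v0 - v2) * delta / h
    return times[idx] + delta, sign * v_ext


def _extrema(times, values, sign):
    rng = values.max() - values.min()
    if rng <= 0 or not np.isfinite(rng):
        return []
    idx, _ = scipy.signal.find_peaks(sign * values, prominence=0.01 * rng)
    return [_refine(times, values, i, sign) for i in idx]


def find_peaks(trace) -> list[tuple[float, float]]:
    """One (time, height) pair per cycle peak, sub-grid refined.

    Raises :class:`ArrhythmicError` when fewer than 2 peaks exist (constant
    or too-short traces).
    """
    times, values = _as_series(trace)
    peaks = _extrema(times, values, +1.0)
    if len(peaks) < 2:
        raise ArrhythmicError("arrhythmic trace: fewer than 2 peaks found")
    return peaks


def find_troughs(trace) -> list[tuple[float, float]]:
    """One (time, height) pair per cycle trough, sub-grid refined."""
    times, values = _as_series(trace)
    troughs = _extrema(times, values, -1.0)
    if len(troughs) < 2:
        raise ArrhythmicError("arrhythmic trace: fewer than 2 troughs found")
    return troughs


def amplitude(trace, n_cycles: int = DEFAULT_N_CYCLES) -> float:
    """Mean peak-to-trough height difference over the trailing cycles.

    Each peak is paired with the first trough that follows it; the last
    ``n_cycles`` such pairs are averaged for robustness to residual
    transients.
    """
    peaks = find_peaks(trace)
    troughs = find_troughs(trace)
    trough_times = np.array([t for t, _ in troughs])
    pairs = []
    for t_p, h_p in peaks:
        j = np.searchsorted(trough_times, t_p, side="right")
        if j < len(troughs):
            pairs.append(h_p - troughs[j][1])
    if not pairs:
        raise ArrhythmicError("arrhythmic trace: no peak-trough pair found")
    return float(np.mean(pairs[-n_cycles:]))


def estimate_period(peak_times, n_cycles: int = DEFAULT_N_CYCLES) -> float:
    """Mean inter-peak interval over the trailing analysis window (h)."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 3:
        raise ArrhythmicError("period estimation needs at least 3 peaks")
    gaps = np.diff(peak_times)
    return float(gaps[-n_cycles:].mean())


def peak_phase_zt(peak_times, T: float, n_cycles: int = DEFAULT_N_CYCLES) -> float:
    """Circular mean of peak times modulo the zeitgeber period, in [0, T)."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 1:
        raise ArrhythmicError("no peaks to phase-average")
    ang = 2.0 * np.pi * peak_times[-n_cycles:] / T
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean_ang * T / (2.0 * np.pi)) % T)


def is_entrained(period: float, peak_zt: float, T: float = 24.0) -> bool:
    """Entrainment verdict: period within ±0.1 h of T, peak in [T/8, 3T/8].

    For the 12:12 cycle this is the peak-between-ZT3-and-ZT9 rule.
    """
    return abs(period - T) <= PERIOD_TOL and T / 8.0 <= peak_zt <= 3.0 * T / 8.0


def compute_metrics(
    trace, T: float = 24.0, n_cycles: int = DEFAULT_N_CYCLES
) -> RhythmMetrics:
    """Full readout of one trace: amplitude, peak ZT, period, entrainment."""
    peaks = find_peaks(trace)
    peak_times = [t for t, _ in peaks]
    period = estimate_period(peak_times, n_cycles)
    zt = peak_phase_zt(peak_times, T, n_cycles)
    amp = amplitude(trace, n_cycles)
    return RhythmMetrics(
        amplitude=amp,
        peak_zt=zt,
        period=period,
        entrained=is_entrained(period, zt, T),
        n_cycles_used=min(n_cycles, len(peak_times) - 1),
    )


def amplitude_increase_pct(amp_with_pa: float, amp_control: float) -> float:
    """Percent amplitude change relative to the light-only control."""
    if amp_control <= 0:
        raise ValueError("control amplitude must be positive")
    return 100.0 * (amp_with_pa - amp_control) / amp_control


def make_synthetic_trace(
    true_amplitude: float,
    true_period: float,
    true_peak_zt: float,
    duration: float,
    sampling_step: float,
    waveform: str = "sinusoid",
) -> SyntheticTrace:
    """Periodic trace with known truth values, for exercising the metrics.

    ``sinusoid`` is a cosine with peak-to-trough ``true_amplitude`` peaking
    at ``true_peak_zt`` (mod period). ``clipped`` saturates the cosine with
    a tanh nonlinearity, giving the flat-topped waveform shape of a driven
    oscillator while keeping the same exact amplitude, period and peak time.
    """
    if min(true_amplitude, true_period, duration, sampling_step) <= 0:
        raise ValueError("all parameters must be positive")
    if sampling_step > true_period / 10.0:
        raise ValueError("sampling_step under-resolves the rhythm")
    times = np.arange(0.0, duration + sampling_step / 2, sampling_step)
    base = np.cos(2.0 * np.pi * (times - true_peak_zt) / true_period)
    if waveform == "sinusoid":
        values = (true_amplitude / 2.0) * base
    elif waveform == "clipped":
        k = 2.5
        values = (true_amplitude / 2.0) * np.tanh(k * base) / np.tanh(k)
    else:
        raise ValueError(f"unknown waveform: {waveform!r}")
    return SyntheticTrace(
        times=times,
        values=values,
        true_amplitude=true_amplitude,
        true_period=true_period,
        true_peak_zt=true_peak_zt % true_period,
    )
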