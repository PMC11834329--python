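# scn-poincare

Coupled Poincaré-oscillator models of the suprachiasmatic nucleus (SCN)
under light and physical-activity (PA) forcing.

The SCN entrains to the light-dark cycle through light input, but the
animal's own activity also feeds back onto it: activity raises SCN firing
in diurnal species and suppresses it in nocturnal ones, and in both cases
well-timed activity enlarges the amplitude of the circadian rhythm. This
package asks a wiring question: if light and activity each reach only a
subpopulation of SCN neurons, which network layout maximises the
activity-induced amplitude gain, and is the answer different for diurnal
and nocturnal chronotypes?

Each subpopulation is a Poincaré limit-cycle oscillator

    dx_i/dt = λ x_i (a − r_i) − (2π/τ) y_i + g F + L_i + PA_i
    dy_i/dt = λ y_i (a − r_i) + (2π/τ) x_i,    r_i = √(x_i² + y_i²)

coupled through the mean field F = (1/N) Σ x_i. Light L_i is a square
wave of height K_L during the light phase for light-receptive
oscillators; PA_i is a square wave of signed strength K_PA during the
animal's active phase (light for diurnal, darkness for nocturnal) for
PA-receptive oscillators. The library provides the model, the simulation
protocol (random initial conditions, piecewise integration restarted at
every forcing discontinuity, 1.2 × 10⁴ h transient discard), rhythm
metrics (peak-to-trough amplitude, peak zeitgeber time, period,
entrainment verdict), and drivers for the feedback-strength sweeps and
the two-oscillator network comparison. See `docs/methods.md` for the full
model description and design choices.

## Worked example

```python
from scn_poincare import (ForcingSchedule, PARAM_PRESETS, SimulationSettings,
                          compute_metrics, config1, simulate)

params = PARAM_PRESETS["set_a"]            # λ=0.4, a=1.8, τ=24 h
for label, k_pa in [("light only", 0.0), ("light + PA (K_PA=0.5)", 0.5)]:
    schedule = ForcingSchedule(light_strength=1.0, pa_strength=k_pa,
                               chronotype="diurnal")
    traj = simulate(params, schedule, config1(), SimulationSettings(seed=1))
    m = compute_metrics(traj, T=24.0)
    print(f"{label:24s} amplitude={m.amplitude:.3f}  peak=ZT{m.peak_zt:.2f}  "
          f"period={m.period:.3f} h  entrained={m.entrained}")
```

prints

```
light only               amplitude=4.460  peak=ZT4.42  period=24.000 h  entrained=True
light + PA (K_PA=0.5)    amplitude=4.759  peak=ZT3.83  period=24.000 h  entrained=True
```

Both runs are properly entrained (period 24 h, peak between ZT3 and ZT9,
with ZT0 = lights-on); excitatory activity feedback timed to the light
phase raises the peak-to-trough amplitude of the ensemble rhythm from
4.46 to 4.76, i.e. a 6.7% increase over the light-only control.

The `examples/` scripts walk through each capability: single-oscillator
entrainment, feedback-strength sweeps for both chronotypes, the
two-oscillator network comparison (for diurnal animals the largest gain
occurs when light and PA target *different* subpopulations; for nocturnal
animals when they target the *same* one), and photoperiod variants.

A thin CLI mirrors the drivers:

```sh
scn-poincare sweep-kpa --preset set_a --chronotype diurnal --kl 1.0 --out fig2a.csv
scn-poincare compare-configs --chronotype nocturnal --out fig3.csv
scn-poincare photoperiod --grid 0.33,0.5,0.67 --out pp.csv
```

Every command writes a tidy CSV plus a resolved-configuration JSON so the
run can be reproduced exactly.

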