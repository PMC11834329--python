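# Methods

## Model

Each neuronal subpopulation of the suprachiasmatic nucleus (SCN) is a
Poincaré limit-cycle oscillator with state (x_i, y_i):

    dx_i/dt = λ x_i (a − r_i) − (2π/τ) y_i + g F + L_i(t) + PA_i(t)
    dy_i/dt = λ y_i (a − r_i) + (2π/τ) x_i

with r_i = √(x_i² + y_i²) the instantaneous amplitude and
F = (1/N) Σ x_i the mean field of x. The radial dynamics reduce to
dr/dt = λ r (a − r): any trajectory with r > 0 relaxes to the limit cycle
r = a at rate λ, while the phase advances uniformly at 2π/τ. The model has
no twist — the free-running period is independent of amplitude.

Two square-wave inputs act on dx only (no input ever enters dy):

* **Light** L_i = K_L while mod(t, T) < p·T for oscillators in the
  light-receptive set LS, otherwise 0. T is the zeitgeber period (24 h),
  p the photoperiod fraction (0.5 = a 12:12 light-dark cycle).
* **Physical activity (PA)** PA_i = d·K_PA in the light phase and
  n·K_PA in the dark phase for oscillators in the PA-receptive set PAS.
  A diurnal chronotype has (d, n) = (1, 0) — activity coincides with
  light; nocturnal has (0, 1). K_PA > 0 is excitatory, K_PA < 0
  inhibitory.

Both waves are right-continuous: the value at a switch instant belongs to
the incoming phase (the light condition is a strict inequality).

### Network configurations

* `config1`: one oscillator, light- and PA-receptive, g = 0 (a single
  oscillator has no self-feedback). A homogeneous population of identical
  mean-field-coupled oscillators collapses to this single oscillator, so
  one oscillator per subpopulation is fully general here.
* `config2`: two oscillators, A light-receptive, B PA-receptive, g = 0.1.
* `config3`: two oscillators, A light- and PA-receptive, B input-free,
  g = 0.1.

The mean field averages over all oscillators including the receiving one,
as the coupling models global neurotransmitter diffusion. In
two-oscillator runs both oscillators share (λ, a, τ) by default;
per-oscillator overrides are accepted by every simulation entry point.

## Parameters

| parameter | meaning | default | range used |
|---|---|---|---|
| λ (1/h) | amplitude relaxation rate | 0.4 | 0.35–0.45 |
| a (–) | intrinsic limit-cycle radius | 1.8 | 1.2–2.1 |
| τ (h) | intrinsic period | 24 | 23.5–24.5 |
| g (–) | mean-field coupling | 0 (N=1) / 0.1 (N=2) | 0–0.1 |
| K_L (–) | light intensity | 1.0 | 0.5–1.0 |
| K_PA (–) | PA feedback strength (signed) | 0 | −1.5–1.5 |
| T (h) | zeitgeber period | 24 | — |
| p (–) | photoperiod fraction | 0.5 | 0.33–0.67 |

The three named intrinsic parameter sets used by the single-oscillator
sweeps are `set_a` (0.4, 1.8, 24), `set_b` (0.35, 2.1, 23.5) and `set_c`
(0.45, 1.2, 24.5); λ sits in the upper part of its optimised range because
PA adds a second input whose acute amplitude effects imply a relatively
stiff oscillator.

## Simulation protocol

Initial (x_i, y_i) are i.i.d. uniform on [0, 1], drawn from a seeded
generator. Because the square-wave inputs make the right-hand side
discontinuous, integration proceeds segment by segment between
consecutive forcing switches (every p·T / (1−p)·T alternation; every 12 h
at equinox), handing the final state of one segment to the next. Each
segment is solved with an adaptive Runge-Kutta method (scipy `solve_ivp`,
DOP853 by default; RK45 available via `SimulationSettings.solver_method`)
at rtol 1e-8 / atol 1e-10 — amplitude comparisons in the network
experiments are percent-level, and tightening the tolerances tenfold
moves the reported amplitude by far less than 0.1% (tested). The
right-hand side is numba-compiled with a transparent NumPy fallback.

The first 1.2 × 10⁴ h are discarded as transient; the retained horizon
defaults to 40 zeitgeber cycles sampled every 0.1 h (period estimation
wants many peaks; phase refinement below the grid is done by the metrics
stage). The total duration beyond the transient is this package's choice.

## Rhythm metrics

The analysed trace is the ensemble mean of x (equal to F) — the coupling
itself is mean-field and each experiment reports a single amplitude per
condition; per-oscillator traces are stored so a single-population
readout can be evaluated instead. Metrics over the trailing 10 cycles:

* **amplitude** — mean absolute peak-to-trough difference; each peak is
  paired with the first following trough. Averaging over 10 cycles
  buffers residual transients and solver noise.
* **period** — mean inter-peak interval (≥ 3 peaks required).
* **peak phase** — circular mean of peak times modulo T, expressed in
  zeitgeber time (ZT0 = lights-on, ZT12 = lights-off at equinox).
  Circular statistics keep peaks straddling ZT0 from averaging to ZT12.
* **entrainment** — period within ±0.1 h of T (the source protocol states
  "24 h" without tolerance; ±0.1 h is this package's operationalisation)
  AND peak inside [T/8, 3T/8], i.e. ZT3–ZT9 for T = 24.
* **amplitude increase** — 100·(amp_PA − amp_control)/amp_control against
  the light-only control of the same configuration and light level.

Peaks come from `scipy.signal.find_peaks` with a prominence floor of 1%
of the trace range (rejects solver-level ripple on near-constant traces),
refined below the 0.1-h grid by a three-point quadratic fit; the fit
falls back to the grid point when the local curvature is not concave.
Constant or sub-two-peak traces raise an "arrhythmic trace" error, which
the sweep drivers record per row instead of aborting.

The synthetic-trace generator used to validate the metrics produces
cosines (and tanh-saturated, flat-topped cosines) whose amplitude, period
and peak time are exact by construction; recovery is within 1% / 0.05 h /
0.2 h over randomised fixtures. These fixtures validate the measurement
stage only — they say nothing about the dynamics.

## Design choices in open territory

* **Photoperiod generalisation.** The main protocol is 12:12. For p ≠ 0.5
  the light phase lasts p·T and the activity/rest split follows the same
  boundary (diurnal active during light, nocturnal during darkness). An
  alternative — keeping fixed 12-h activity blocks while only light
  stretches — was evaluated and produces strongly negative diurnal
  amplitude responses at short photoperiods, so the complement split is
  used.
* **Fig-3-style light levels.** The two light intensities of the network
  comparison default to K_L ∈ {0.5, 1.0}, the endpoints of the light
  range; the PA magnitude defaults to |K_PA| = 1.0 (mid-range). Both are
  exposed as arguments.
* **Entrained-phase window at p ≠ 0.5.** The ZT3–ZT9 window is defined
  for equinox; the package scales it as [T/8, 3T/8] in T and leaves it
  fixed in p, so entrainment verdicts at extreme photoperiods should be
  read with care.

## Known limitations

* The claimed loss of entrainment for short intrinsic periods (τ = 23.5,
  diurnal excitatory feedback) does not emerge from these equations: at
  K_L ≥ 0.1 the detuning of 0.5 h/cycle lies well inside the locking
  tongue and the rhythm phase-locks exactly (period 24.000 over 40 cycles,
  every seed tested). The metric pipeline does report non-entrainment
  once detuning/forcing actually warrant it (e.g. τ = 22 h at K_L = 0.05
  yields a 22.14-h drifting rhythm), so this reflects the dynamics, not
  the detector. The twistless Poincaré oscillator offers no mechanism for
  a short-period-specific failure at these forcing strengths.
* Under the complement-split photoperiod generalisation the diurnal
  configuration ordering (split wiring > shared wiring > 0) holds at
  p = 0.33 but reverses at p = 0.67, where the split wiring's amplitude
  response turns negative (about −4% at K_L = 1.0, K_PA = +1). The
  nocturnal ordering is robust at both photoperiods.
* No stochasticity, no N ≫ 2 lattices, no graded or skeleton photic
  input, and no spectral period estimation — out of scope by design.
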