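# vortexwell

Tools for studying how circular confinement organizes bacterial (polar
active) turbulence: the transition from a single stabilized vortex,
through periodically reversing vortices and antiphase four-vortex
pulsations, to developed active turbulence as the well radius grows.

The package is aimed at researchers in active matter who want a complete,
testable desk-scale implementation of this confinement problem: a
continuum solver, the corresponding linear and weakly nonlinear theory,
the velocimetry observables used on experimental data, and a synthetic
data generator so every stage runs without downloads.

## The model

All quantities are dimensionless.  The flow obeys the
Toner–Tu–Swift–Hohenberg vorticity equation

∂t ω + λ v·∇ω = a ω − b ∇×(|v|²v) − (1 + ∇²)² ω − γv ∇×(K v) − γω K ω,

with ω = ẑ·∇×v and v = ∇×(ψẑ), ω = −∇²ψ.  The Swift–Hohenberg operator
selects a vortex scale of 2π; the mask K(r) (≈0 inside each circular
well, ≈1 outside) confines the flow.  Reference parameters:
(λ, a, b, γv, γω) = (9, 0.5, 1.6, 40, 4).

Modules:

- `linear_stability` — azimuthal Bessel eigenmodes of the linearized
  equation in a disc; growth rates λn(R), critical radii, energy-
  normalized mode profiles.
- `ttshe` — pseudospectral ETDRK2 solver on a periodic square with
  volume-penalized wells; effective-radius calibration.
- `normal_form` — three-mode amplitude equations for (C, A1, A2)
  obtained by Galerkin projection; attractor classification; radius and
  advection-strength bifurcation sweeps (infinite-period reversal onset).
- `flow_analysis` — per-well spin, azimuthal mode energies, vorticity
  mode maps, spin statistics, eigenmode profile fits, state classifier.
- `model_regression` — term-library regression of ∂tω against the TTSH
  and Nikolaevskiy operator libraries; parameter recovery and ranking.
- `synthetic_data` — PIV-like gridded velocity time series for each
  confined state, with measurement noise and smoothing.

## Worked example

Growth rates and the onset of the single vortex:

```python
>>> from vortexwell.linear_stability import critical_radius, growth_rate
>>> round(critical_radius(0), 3)          # axisymmetric mode onset
4.181
>>> [round(growth_rate(n, 5.88), 4) for n in (0, 1, 2)]
[0.2085, 0.2459, -0.0519]
```

At R = 5.88 the first two azimuthal modes are unstable while n = 2 is
still (weakly) stable — the regime where their resonant interaction
drives vortex reversal.  The reduced amplitude equations make this
quantitative:

```python
>>> from vortexwell.normal_form import (compute_coefficients,
...     integrate_amplitudes, classify_attractor)
>>> m = compute_coefficients(5.9, lam=9.0, a=0.5, b=1.6)
>>> traj = integrate_amplitudes(m, (0.01, 0.005 + 0j, 0.002 + 0j), 4000.0)
>>> classify_attractor(traj)
('reversing_cycle', 579.1...)
```

— an attracting orbit on which the vortex amplitude C changes sign with
period ≈ 579 at R = 5.9, just above the onset; the period grows without
bound as the radius decreases toward the threshold (infinite-period
bifurcation).  A full sweep:

```python
>>> from vortexwell.normal_form import find_reversal_threshold
>>> res = find_reversal_threshold(lam=9.0, a=0.5, b=1.6, seed=1)
>>> res.R_cycle_min
5.9
```

Simulation and analysis round-trip from the shell:

```
vortexwell simulate --radius 5.6 --grid-n 128 --t-end 600 --seed-vortex --out run.nc
vortexwell analyze --in run.nc -R 5.6 --cx 10.24 --cy 10.24 --out well0
```

which writes the spin and mode-energy time series and a JSON summary
with the classified state (`reversing` for this radius).

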