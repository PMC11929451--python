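"""Synthetic velocimetry data with the statistical structure of confined
bacterial-vortex experiments.

Generates PIV-like gridded velocity time series for each dynamical state
observed in circular wells - steady vortex, periodically reversing
vortex, antiphase-pulsating four-vortex state, sub-threshold random
motion and developed turbulence - so the analysis and regression modules
are fully testable without experimental recordings.  Deterministic in the
seed.  Vortex states are built from the disc eigenmode profiles of
:mod:`vortexwell.linear_stability`; measurement imperfections are
emulated by additive Gaussian velocity noise followed by Gaussian spatial
smoothing (in that order, mirroring PIV post-processing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .fields import FlowField, WellGeometry
from .linear_stability import StabilityParams, eigenmode

__all__ = ["SyntheticSpec", "generate", "well_array"]

_STATES = ("random", "stable_vortex", "reversing", "four_vortex", "turbulent")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic well recording.

    Times are dimensionless model units.  The defaults mimic a
    150-second, 50 frame-per-second recording when one time unit is half
    a second (duration 300, frame interval 0.04); tests typically use
    shorter durations.
    """

    state: str = "stable_vortex"
    well: WellGeometry = field(default_factory=lambda: WellGeometry((8.0, 8.0), 5.5))
    domain_size: float = 16.0
    grid_spacing: float = 0.25
    frame_interval: float = 0.04
    duration: float = 20.0
    noise_sigma: float = 0.0
    smoothing_sigma: float = 0.0
    reversal_period: float = 10.0
    amplitude: float = 2.0
    sign: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}")
        if min(self.grid_spacing, self.frame_interval, self.duration) <= 0:
            raise ValueError("spacings and durations must be positive")
        if self.noise_sigma < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise_sigma and smoothing_sigma must be >= 0")


def _mode_velocity_grids(spec: SyntheticSpec, n: int):
    """Cartesian velocity pattern of azimuthal mode n on the grid.

    Returns ``(ux, uy)`` complex arrays such that the physical velocity of
    the mode with complex amplitude A is ``2 Re(A ux)`` (n >= 1) or
    ``Re(A ux)`` (n = 0, real A).
    """
    m = eigenmode(n, spec.well.R, StabilityParams())
    x = np.arange(0.0, spec.domain_size, spec.grid_spacing)
    X, Y = np.meshgrid(x - spec.well.center[0], x - spec.well.center[1], indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    th = np.arctan2(Y, X)
    vth = np.interp(r, m.r, m.v_theta, left=m.v_theta[0], right=0.0)
    vri = np.interp(r, m.r, m.v_r_imag, left=0.0, right=0.0)
    vth[r > spec.well.R] = 0.0
    vri[r > spec.well.R] = 0.0
    phase = np.exp(1j * n * th)
    vr_c = 1j * vri * phase
    vth_c = vth * phase
    ux = vr_c * np.cos(th) - vth_c * np.sin(th)
    uy = vr_c * np.sin(th) + vth_c * np.cos(th)
    return ux, uy


def _mode_vorticity_grid(spec: SyntheticSpec, n: int):
    m = eigenmode(n, spec.well.R, StabilityParams())
    x = np.arange(0.0, spec.domain_size, spec.grid_spacing)
    X, Y = np.meshgrid(x - spec.well.center[0], x - spec.well.center[1], indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    th = np.arctan2(Y, X)
    w = np.interp(r, m.r, m.omega, left=m.omega[0], right=0.0)
    w[r > spec.well.R] = 0.0
    return w * np.exp(1j * n * th)


def _sq_core(ph, wf):
    """Smoothed square wave on phase ph in [0, 1): +1 on (0, 0.5), -1 on
    (0.5, 1), with tanh transitions of relative width wf."""
    up = np.tanh(ph / wf) * np.tanh((0.5 - ph) / wf)
    dn = np.tanh((ph - 0.5) / wf) * np.tanh((1.0 - ph) / wf)
    return up - dn


def _amplitudes(spec: SyntheticSpec, t: np.ndarray):
    """Per-frame complex amplitudes (C, A1, A2) for each state."""
    nt = len(t)
    C = np.zeros(nt)
    A1 = np.zeros(nt, complex)
    A2 = np.zeros(nt, complex)
    amp = spec.amplitude * spec.sign
    if spec.state == "stable_vortex":
        C[:] = amp
    elif spec.state == "reversing":
        C[:] = amp * _sq_core(np.mod(t / spec.reversal_period, 1.0), 0.05)
        A1[:] = 0.55 * spec.amplitude * np.sqrt(np.maximum(1 - (C / spec.amplitude) ** 2, 0.0))
    elif spec.state == "four_vortex":
        # four-vortex harmonic dominant on average, pulsating in antiphase
        # with the weaker two-vortex harmonic (the confined-state structure)
        ph = 2.0 * np.pi * t / spec.reversal_period
        A1[:] = 0.45 * spec.amplitude * np.sqrt(0.55 + 0.45 * np.cos(ph))
        A2[:] = 0.90 * spec.amplitude * np.sqrt(0.55 - 0.45 * np.cos(ph))
    return C, A1, A2


def generate(spec: SyntheticSpec) -> list[FlowField]:
    """Build the frame sequence for one synthetic well."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 0.5 * spec.frame_interval, spec.frame_interval)
    x = np.arange(0.0, spec.domain_size, spec.grid_spacing)
    shape = (len(x), len(x))

    if spec.state in ("random", "turbulent"):
        frames = _generate_disordered(spec, t, x, rng)
    else:
        C, A1, A2 = _amplitudes(spec, t)
        grids_v = {n: _mode_velocity_grids(spec, n) for n in (0, 1, 2)}
        grids_w = {n: _mode_vorticity_grid(spec, n) for n in (0, 1, 2)}
        frames = []
        for i, ti in enumerate(t):
            vx = np.zeros(shape); vy = np.zeros(shape); w = np.zeros(shape)
            for n, A in ((0, C[i]), (1, A1[i]), (2, A2[i])):
                fac = 1.0 if n == 0 else 2.0
                ux, uy = grids_v[n]
                vx += fac * np.real(A * ux)
                vy += fac * np.real(A * uy)
                w += fac * np.real(A * grids_w[n])
            frames.append(FlowField(time=float(ti), vorticity=w, vx=vx, vy=vy,
                                    dx=spec.grid_spacing))

    # measurement model: additive noise, then Gaussian smoothing
    sigma_px = spec.smoothing_sigma / spec.grid_spacing
    for f in frames:
        if spec.noise_sigma > 0:
            f.vx = f.vx + rng.normal(0.0, spec.noise_sigma, shape)
            f.vy = f.vy + rng.normal(0.0, spec.noise_sigma, shape)
        if sigma_px > 0:
            f.vx = gaussian_filter(f.vx, sigma_px)
            f.vy = gaussian_filter(f.vy, sigma_px)
        if spec.noise_sigma > 0 or sigma_px > 0:
            # keep the stored vorticity consistent with the degraded velocity
            f.vorticity = _curl(f.vx, f.vy, spec.grid_spacing)
    return frames


def _curl(vx, vy, dx):
    dvy_dx = np.gradient(vy, dx, axis=0)
    dvx_dy = np.gradient(vx, dx, axis=1)
    return dvy_dx - dvx_dy


def _generate_disordered(spec: SyntheticSpec, t, x, rng):
    """Random (weak filtered noise) and turbulent (drifting |k| ~ 1 ring) states."""
    X, Y = np.meshgrid(x, x, indexing="ij")
    cx, cy = spec.well.center
    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    envelope = 0.5 * (1.0 - np.tanh((r - spec.well.R) / max(spec.well.kernel_width, 1e-6)))
    frames = []
    if spec.state == "random":
        scale = 0.02 * spec.amplitude
        for ti in t:
            vx = gaussian_filter(rng.standard_normal(X.shape), 2.0) * scale
            vy = gaussian_filter(rng.standard_normal(X.shape), 2.0) * scale
            vx *= envelope; vy *= envelope
            frames.append(FlowField(float(ti), _curl(vx, vy, spec.grid_spacing),
                                    vx, vy, spec.grid_spacing))
        return frames
    # turbulent: superposition of |k| ~ 1 plane waves with diffusing phases
    n_modes = 24
    angles = rng.uniform(0, 2 * np.pi, n_modes)
    kmag = rng.normal(1.0, 0.1, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    amps = (0.4 * spec.amplitude / np.sqrt(n_modes)) * (1 + 0.3 * rng.standard_normal(n_modes))
    drift = rng.normal(0.0, 0.8, n_modes)  # phase random-walk rate
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    dt = spec.frame_interval
    for ti in t:
        phases = phases + drift * np.sqrt(dt) * rng.standard_normal(n_modes) + 0.5 * dt
        psi = np.zeros_like(X)
        for a_m, km, d, ph in zip(amps, kmag, dirs, phases):
            psi += a_m * np.sin(km * (d[0] * X + d[1] * Y) + ph)
        vx = np.gradient(psi, spec.grid_spacing, axis=1) * envelope
        vy = -np.gradient(psi, spec.grid_spacing, axis=0) * envelope
        frames.append(FlowField(float(ti), _curl(vx, vy, spec.grid_spacing),
                                vx, vy, spec.grid_spacing))
    return frames


def well_array(specs: list[SyntheticSpec]) -> tuple[list[FlowField], dict]:
    """Composite frames containing several independently generated wells.

    All specs must share grid spacing, frame interval, duration and
    domain size; each well's pattern is added on the common grid.
    Returns ``(frames, manifest)`` with ``manifest[well_id] = spec``.
    Overlapping wells raise ``ValueError``.
    """
    if not specs:
        raise ValueError("no specs")
    s0 = specs[0]
    for s in specs[1:]:
        if (s.domain_size, s.grid_spacing, s.frame_interval, s.duration) != \
           (s0.domain_size, s0.grid_spacing, s0.frame_interval, s0.duration):
            raise ValueError("specs must share grid and timing")
    for i, s in enumerate(specs):
        for s2 in specs[i + 1:]:
            d = np.hypot(s.well.center[0] - s2.well.center[0],
                         s.well.center[1] - s2.well.center[1])
            if d < s.well.R + s2.well.R:
                raise ValueError("wells overlap")
    base = None
    manifest = {}
    for wid, s in enumerate(specs):
        manifest[wid] = s
        fr = generate(s)
        if base is None:
            base = fr
        else:
            for f, g in zip(base, fr):
                f.vx = f.vx + g.vx
                f.vy = f.vy + g.vy
                f.vorticity = f.vorticity + g.vorticity
    return base, manifest
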