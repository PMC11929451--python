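"""Three-mode amplitude equations for a confined active vortex.

The vorticity field in a disc of radius ``R`` is approximated by the three
lowest azimuthal eigenmodes of the linear problem,

    omega = C(t) w0(r) + [A1(t) e^{i theta} w1(r)
                          + A2(t) e^{2 i theta} w2(r) + c.c.] ,

with energy-normalized profiles ``w_n`` from
:mod:`vortexwell.linear_stability`.  Substituting into the full nonlinear
vorticity equation and projecting each azimuthal harmonic onto its mode
with the kinetic-energy inner product (equivalently, a streamfunction
weight: ``<mode, N> = int psi_n^* N dA``, the boundary terms vanishing
under the wall conditions) yields amplitude equations of the form

    dC/dt  = lambda0 C - c1 C^3 - c2 C|A1|^2 - c3 C|A2|^2 - 2 Re(c4 A2 A1*^2)
    dA1/dt = lambda1 A1 - b1 A1|A1|^2 - b2 A1 C^2 - b3 A1|A2|^2
             - b4 C A2 A1* + delta1 A1 C + gamma1 A2 A1*
    dA2/dt = lambda2 A2 - a1 A2|A2|^2 - a2 A2 C^2 - a3 A2|A1|^2
             - a4 C A1^2 + delta2 A2 C + gamma2 A1^2 .

Azimuthal selection rules admit exactly these couplings: the cubic
(|v|^2 v) term produces the cubic monomials, the advective term
(lam v.grad omega) the quadratic ones, so the quadratic couplings scale
linearly with the advection coefficient ``lam``.  In the phase gauge used
here (real radial profiles) the cubic couplings come out real and the
advective couplings purely imaginary; the dynamics is gauge-invariant,
and both structures are asserted at build time together with rotation
equivariance.

Increasing ``R`` at the reference parameters the attractor sequence is:
steady vortex (pure C), a weakly tilted mixed equilibrium, then - through
an infinite-period (SNIC-type) bifurcation near R ~ 5.88 - a limit cycle
on which C reverses sign periodically (vortex reversal), and at larger
radii a pulsation where C is suppressed and |A1|, |A2| oscillate in
antiphase (four-vortex state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .linear_stability import StabilityParams, RadialEigenmode, eigenmode

__all__ = [
    "NormalFormModel", "AmplitudeTrajectory", "BifurcationScan",
    "ReversalThresholdResult", "compute_coefficients", "amplitude_rhs",
    "integrate_amplitudes", "classify_attractor", "sustains_limit_cycle",
    "find_reversal_threshold", "find_lambda_threshold",
]

_COEFF_NAMES = ("c1", "c2", "c3", "c4", "b1", "b2", "b3", "b4",
                "delta1", "gamma1", "a1", "a2", "a3", "a4", "delta2", "gamma2")


@dataclass
class NormalFormModel:
    """Coefficients of the three-mode amplitude equations at one (R, lam, a, b)."""

    R: float
    lam: float
    a: float
    b: float
    lambda0: float
    lambda1: float
    lambda2: float
    c1: complex
    c2: complex
    c3: complex
    c4: complex
    b1: complex
    b2: complex
    b3: complex
    b4: complex
    delta1: complex
    gamma1: complex
    a1: complex
    a2: complex
    a3: complex
    a4: complex
    delta2: complex
    gamma2: complex
    # advective couplings per unit lam, kept for cheap rescaling in scans
    quad_unit: dict = field(default_factory=dict, repr=False)

    def with_lam(self, lam: float) -> "NormalFormModel":
        """Same disc, different advection coefficient (quadratic couplings rescale)."""
        kw = {k: getattr(self, k) for k in _COEFF_NAMES}
        for k in ("delta1", "gamma1", "delta2", "gamma2"):
            kw[k] = self.quad_unit[k] * lam
        return NormalFormModel(
            R=self.R, lam=lam, a=self.a, b=self.b,
            lambda0=self.lambda0, lambda1=self.lambda1, lambda2=self.lambda2,
            **kw, quad_unit=self.quad_unit,
        )

    def pack(self) -> np.ndarray:
        """Flatten to the float vector consumed by the compiled integrator."""
        p = np.empty(26)
        p[0:3] = self.lambda0, self.lambda1, self.lambda2
        for i, k in enumerate(("c1", "c2", "c3")):
            p[3 + i] = np.real(getattr(self, k))
        p[6], p[7] = np.real(self.c4), np.imag(self.c4)
        for i, k in enumerate(("b1", "b2", "b3")):
            p[8 + i] = np.real(getattr(self, k))
        for i, k in enumerate(("b4", "delta1", "gamma1")):
            v = getattr(self, k)
            p[11 + 2 * i], p[12 + 2 * i] = np.real(v), np.imag(v)
        for i, k in enumerate(("a1", "a2", "a3")):
            p[17 + i] = np.real(getattr(self, k))
        for i, k in enumerate(("a4", "delta2", "gamma2")):
            v = getattr(self, k)
            p[20 + 2 * i], p[21 + 2 * i] = np.real(v), np.imag(v)
        return p


@dataclass
class AmplitudeTrajectory:
    """Time series of the real amplitude C and complex amplitudes A1, A2."""

    times: np.ndarray
    C: np.ndarray
    A1: np.ndarray
    A2: np.ndarray


@dataclass
class BifurcationScan:
    """Attractor label (and cycle period where defined) along a control sweep."""

    control: str
    grid: np.ndarray
    attractor: list
    period: list
    direction: str


@dataclass
class ReversalThresholdResult:
    """Outcome of the radius sweep for the reversal (infinite-period) onset."""

    R_cycle_min: float
    R_fixed_point_max: float
    hysteresis_window: tuple[float, float] | None
    down_scan: BifurcationScan
    up_scan: BifurcationScan


# ---------------------------------------------------------------------------
# Galerkin projection

def _polar_fields(modes, r, th, C, A1, A2):
    """Real physical fields and radial derivatives on the (r, theta) grid."""
    sh = (len(r), len(th))
    vr = np.zeros(sh); vth = np.zeros(sh); om = np.zeros(sh)
    vrp = np.zeros(sh); vthp = np.zeros(sh); omp = np.zeros(sh)
    for m, A in zip(modes, (C, A1, A2)):
        e = np.exp(1j * m.n * th)[None, :]
        fac = 1.0 if m.n == 0 else 2.0  # c.c. partner for n >= 1
        cc = np.real(A * e) * fac
        ccI = np.real(1j * A * e) * fac  # v_r profile is i * (real array)
        om += cc * m.omega[:, None]
        omp += cc * m.d_omega[:, None]
        vth += cc * m.v_theta[:, None]
        vthp += cc * m.d_v_theta[:, None]
        vr += ccI * m.v_r_imag[:, None]
        vrp += ccI * m.d_v_r_imag[:, None]
    return vr, vrp, vth, vthp, om, omp


def _nonlinear_projections(modes, C, A1, A2, n_theta=64):
    """Projections of the advective (per unit lam) and cubic (per unit b) terms.

    Returns ``[(adv_0, cub_0), (adv_1, cub_1), (adv_2, cub_2)]`` - the
    harmonic-n component of each nonlinear term projected onto mode n with
    the streamfunction weight, normalized by ``int psi_n w_n r dr`` (the
    mode's kinetic energy).
    """
    r, wq = modes[0].r, modes[0].quad_weights
    th = 2.0 * np.pi * np.arange(n_theta) / n_theta
    vr, vrp, vth, vthp, om, omp = _polar_fields(modes, r, th, C, A1, A2)
    rr = r[:, None]
    kk = np.fft.fftfreq(n_theta, 1.0 / n_theta)

    def dtheta(f):
        return np.real(np.fft.ifft(1j * kk[None, :] * np.fft.fft(f, axis=1), axis=1))

    # advection: -(v.grad omega), per unit lam
    adv = -(vr * omp + vth * dtheta(om) / rr)
    # cubic: -curl(|v|^2 v) = -[q vth / r + d_r(q vth) - (1/r) d_theta(q vr)], per unit b
    q = vr * vr + vth * vth
    qp = 2.0 * (vr * vrp + vth * vthp)
    cub = -(q * vth / rr + qp * vth + q * vthp - dtheta(q * vr) / rr)

    out = []
    for m in modes:
        denom = 2.0 * np.pi * np.sum(wq * r * m.psi * m.omega)
        pair = []
        for N in (adv, cub):
            Nh = np.fft.fft(N, axis=1)[:, m.n] / n_theta
            pair.append(2.0 * np.pi * np.sum(wq * r * Nh * m.psi) / denom)
        out.append(tuple(pair))
    return out


def compute_coefficients(
    R: float, lam: float = 9.0, a: float = 0.5, b: float = 1.6,
    *, n_quad: int = 240, n_theta: int = 64, check: bool = True,
) -> NormalFormModel:
    """Build the amplitude-equation coefficients at radius ``R``.

    Each coefficient is extracted by evaluating the projected nonlinear
    terms at a handful of amplitude tuples chosen so a single monomial is
    isolated at a time (the advective term is quadratic in the field and
    the cubic term cubic, so their monomial families do not mix).

    With ``check=True`` (default) quadrature convergence is verified by
    refinement (relative change < 1e-6 on the leading coefficients),
    rotation equivariance is verified by confirming that azimuthally
    forbidden quadratic projections vanish, and the gauge structure
    (cubic couplings real, advective couplings imaginary) is asserted.
    """
    params = StabilityParams(a=a)
    modes = [eigenmode(n, R, params, n_quad=n_quad) for n in (0, 1, 2)]

    def extract(modes_):
        P = lambda *amps: _nonlinear_projections(modes_, *amps, n_theta=n_theta)
        p100, p010, p001 = P(1, 0, 0), P(0, 1, 0), P(0, 0, 1)
        p110, p101, p011 = P(1, 1, 0), P(1, 0, 1), P(0, 1, 1)
        p111 = P(1, 1, 1)
        ph = np.exp(1j * np.pi / 4)
        p011r = P(0, ph, 1)
        co = {}
        # C equation (cubic part; printed signs are minus)
        co["c1"] = -p100[0][1]
        co["c2"] = -(p110[0][1] - p100[0][1])
        co["c3"] = -(p101[0][1] - p100[0][1])
        co["c4"] = 0.5 * (-p011[0][1] + 1j * (-p011r[0][1]))
        # A1 equation
        co["delta1"] = p110[1][0]
        co["gamma1"] = p011[1][0]
        co["b1"] = -p010[1][1]
        co["b2"] = -(p110[1][1] - p010[1][1])
        co["b3"] = -(p011[1][1] - p010[1][1])
        co["b4"] = -(p111[1][1] + co["b1"] + co["b2"] + co["b3"])
        # A2 equation
        co["delta2"] = p101[2][0]
        co["gamma2"] = p010[2][0]
        co["a1"] = -p001[2][1]
        co["a2"] = -(p101[2][1] - p001[2][1])
        co["a3"] = -(p011[2][1] - p001[2][1])
        co["a4"] = -p110[2][1]
        # azimuthally forbidden quadratic projections onto harmonic 0
        forbidden = max(abs(p100[0][0]), abs(p010[0][0]), abs(p001[0][0]))
        return co, forbidden

    co, forbidden = extract(modes)
    if check:
        if forbidden > 1e-10:
            raise RuntimeError(f"selection-rule violation: forbidden projection {forbidden:.2e}")
        for k in ("c1", "c2", "c3", "b1", "b2", "b3", "a1", "a2", "a3", "c4", "b4", "a4"):
            if abs(np.imag(co[k])) > 1e-8 * max(1.0, abs(co[k])):
                raise RuntimeError(f"cubic coupling {k} not real: {co[k]}")
        for k in ("delta1", "gamma1", "delta2", "gamma2"):
            if abs(np.real(co[k])) > 1e-8 * max(1.0, abs(co[k])):
                raise RuntimeError(f"advective coupling {k} not imaginary: {co[k]}")
        # quadrature refinement
        modes_f = [eigenmode(n, R, params, n_quad=int(n_quad * 1.5)) for n in (0, 1, 2)]
        co_f, _ = extract(modes_f)
        for k in ("c1", "b1", "gamma2"):
            denom = max(abs(co_f[k]), 1e-12)
            if abs(co[k] - co_f[k]) / denom > 1e-6:
                raise RuntimeError(f"quadrature not converged for {k}")

    quad_unit = {k: co[k] for k in ("delta1", "gamma1", "delta2", "gamma2")}
    kw = {}
    for k in _COEFF_NAMES:
        if k in quad_unit:
            kw[k] = co[k] * lam
        else:
            kw[k] = co[k] * b
    return NormalFormModel(
        R=R, lam=lam, a=a, b=b,
        lambda0=modes[0].growth_rate, lambda1=modes[1].growth_rate,
        lambda2=modes[2].growth_rate, **kw, quad_unit=quad_unit,
    )


# ---------------------------------------------------------------------------
# the vector field and its integrators

def amplitude_rhs(model: NormalFormModel, C: float, A1: complex, A2: complex):
    """Right-hand side ``(dC, dA1, dA2)`` of the amplitude equations."""
    m = model
    m1, m2 = abs(A1) ** 2, abs(A2) ** 2
    dC = (m.lambda0 * C - np.real(m.c1) * C**3 - np.real(m.c2) * C * m1
          - np.real(m.c3) * C * m2 - 2.0 * np.real(m.c4 * A2 * np.conj(A1) ** 2))
    dA1 = (m.lambda1 * A1 - m.b1 * A1 * m1 - m.b2 * A1 * C**2 - m.b3 * A1 * m2
           - m.b4 * C * A2 * np.conj(A1) + m.delta1 * A1 * C + m.gamma1 * A2 * np.conj(A1))
    dA2 = (m.lambda2 * A2 - m.a1 * A2 * m2 - m.a2 * A2 * C**2 - m.a3 * A2 * m1
           - m.a4 * C * A1**2 + m.delta2 * A2 * C + m.gamma2 * A1**2)
    return float(np.real(dC)), complex(dA1), complex(dA2)


@njit(cache=True)
def _rhs_packed(y, p):
    c4 = complex(p[6], p[7])
    b4 = complex(p[11], p[12]); d1 = complex(p[13], p[14]); g1 = complex(p[15], p[16])
    a4 = complex(p[20], p[21]); d2 = complex(p[22], p[23]); g2 = complex(p[24], p[25])
    C = y[0]; A1 = complex(y[1], y[2]); A2 = complex(y[3], y[4])
    m1 = abs(A1) ** 2; m2 = abs(A2) ** 2
    dC = (p[0] * C - p[3] * C**3 - p[4] * C * m1 - p[5] * C * m2
          - 2.0 * (c4 * A2 * A1.conjugate() ** 2).real)
    dA1 = (p[1] * A1 - p[8] * A1 * m1 - p[9] * A1 * C * C - p[10] * A1 * m2
           - b4 * C * A2 * A1.conjugate() + d1 * A1 * C + g1 * A2 * A1.conjugate())
    dA2 = (p[2] * A2 - p[17] * A2 * m2 - p[18] * A2 * C * C - p[19] * A2 * m1
           - a4 * C * A1 * A1 + d2 * A2 * C + g2 * A1 * A1)
    out = np.empty(5)
    out[0] = dC; out[1] = dA1.real; out[2] = dA1.imag
    out[3] = dA2.real; out[4] = dA2.imag
    return out


@njit(cache=True)
def _integrate_rk4(y0, p, t_end, dt, save_every):
    n = int(t_end / dt)
    nout = n // save_every + 1
    T = np.empty(nout); Y = np.empty((nout, 5))
    y = y0.copy(); T[0] = 0.0; Y[0] = y
    j = 1
    for i in range(1, n + 1):
        k1 = _rhs_packed(y, p)
        k2 = _rhs_packed(y + 0.5 * dt * k1, p)
        k3 = _rhs_packed(y + 0.5 * dt * k2, p)
        k4 = _rhs_packed(y + dt * k3, p)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if i % save_every == 0:
            T[j] = i * dt; Y[j] = y; j += 1
        if abs(y[0]) > 1e6 or abs(y[1]) > 1e6 or abs(y[3]) > 1e6:
            return T[:j], Y[:j]
    return T[:j], Y[:j]


def _to_traj(T, Y) -> AmplitudeTrajectory:
    return AmplitudeTrajectory(
        times=T, C=Y[:, 0], A1=Y[:, 1] + 1j * Y[:, 2], A2=Y[:, 3] + 1j * Y[:, 4],
    )


def integrate_amplitudes(
    model: NormalFormModel,
    init: tuple[float, complex, complex],
    t_end: float,
    n_out: int = 4000,
    rtol: float = 1e-8,
) -> AmplitudeTrajectory:
    """Adaptive integration (RK45, rtol<=1e-8) on a uniform output grid.

    Raises ``FloatingPointError`` with the divergence time if any
    amplitude exceeds 1e6.
    """
    C0, A10, A20 = init
    y0 = [float(np.real(C0)), np.real(A10), np.imag(A10), np.real(A20), np.imag(A20)]
    p = model.pack()
    sol = solve_ivp(
        lambda t, y: _rhs_packed(np.asarray(y), p), (0.0, t_end), y0,
        t_eval=np.linspace(0.0, t_end, n_out), rtol=rtol, atol=1e-10, method="RK45",
    )
    Y = sol.y.T
    bad = ~np.isfinite(Y).all(axis=1) | (np.max(np.abs(np.where(np.isfinite(Y), Y, np.inf)),
                                                axis=1) > 1e6)
    if bad.any() or not sol.success:
        t_div = sol.t[int(np.argmax(bad))] if bad.any() else sol.t[-1]
        raise FloatingPointError(f"amplitude blow-up at t={t_div:.2f}")
    return _to_traj(sol.t, Y)


def _integrate_fast(model_or_packed, init, t_end=2000.0, dt=0.01, save_every=50):
    p = model_or_packed.pack() if isinstance(model_or_packed, NormalFormModel) else model_or_packed
    y0 = np.asarray(init, dtype=float)
    T, Y = _integrate_rk4(y0, p, t_end, dt, save_every)
    return T, Y


# ---------------------------------------------------------------------------
# attractor classification

def classify_attractor(
    traj: AmplitudeTrajectory, transient_fraction: float = 0.5,
) -> tuple[str, float | None]:
    """Label the post-transient dynamics.

    ``fixed_point``: all amplitude moduli vary by < 1e-5 over the window.
    ``reversing_cycle``: C has >= 2 sign changes at regular intervals
    (coefficient of variation < 0.5); period = 2 x mean interval.
    ``pulsating_cycle``: mean |C| below 10% of mean |A1| while |A1|
    oscillates.  Otherwise ``unclassified``; a window too short for two
    crossings of a slowly reversing state returns ``indeterminate``.
    """
    i0 = int(len(traj.times) * transient_fraction)
    if len(traj.times) - i0 < 8:
        return "indeterminate", None
    t = traj.times[i0:]
    C = traj.C[i0:]
    mA1 = np.abs(traj.A1[i0:]); mA2 = np.abs(traj.A2[i0:])
    mods = np.vstack([np.abs(C), mA1, mA2])
    if np.all(np.ptp(mods, axis=1) < 1e-5):
        return "fixed_point", None
    s = np.sign(C); s[s == 0] = 1.0
    cross = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if len(cross) >= 2:
        iv = np.diff(t[cross])
        if np.std(iv) / max(np.mean(iv), 1e-12) < 0.5:
            return "reversing_cycle", float(2.0 * np.mean(iv))
    if np.mean(np.abs(C)) < 0.1 * np.mean(mA1) and np.ptp(mA1) > 1e-4:
        return "pulsating_cycle", None
    if len(cross) in (0, 1) and np.ptp(np.abs(C)) > 1e-3:
        return "indeterminate", None
    return "unclassified", None


def sustains_limit_cycle(T, Y, transient_fraction=0.5, amp_min=1e-3):
    """Strict limit-cycle existence test used by the threshold scans.

    Requires >= 4 sign changes of C (reversing) or >= 4 alternations of
    |A1| vs |A2| dominance (pulsating) after the transient, with a
    non-negligible oscillation amplitude.  Returns ``'reversing'``,
    ``'pulsating'`` or ``None``.
    """
    i0 = int(len(T) * transient_fraction)
    C = Y[i0:, 0]
    A1 = np.abs(Y[i0:, 1] + 1j * Y[i0:, 2])
    A2 = np.abs(Y[i0:, 3] + 1j * Y[i0:, 4])
    s = np.sign(C); s[s == 0] = 1.0
    if np.sum(s[:-1] * s[1:] < 0) >= 4 and np.ptp(C) > amp_min:
        return "reversing"
    d = np.sign(A1 - A2); d[d == 0] = 1.0
    if np.sum(d[:-1] * d[1:] < 0) >= 4 and np.ptp(np.maximum(A1, A2)) > amp_min:
        return "pulsating"
    return None


def _reversal_period(T, Y, transient_fraction=0.25):
    i0 = int(len(T) * transient_fraction)
    C = Y[i0:, 0]; t = T[i0:]
    s = np.sign(C); s[s == 0] = 1.0
    cross = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if len(cross) < 2:
        return None
    return float(2.0 * np.mean(np.diff(t[cross])))


def _is_fixed_point(T, Y, p=None, transient_fraction=0.5, tol=1e-5):
    """Stationary over the window AND (if coefficients given) a true
    equilibrium of the vector field — a slow crawl near the ghost of a
    saddle-node can look stationary over any finite window, so the
    residual check is what distinguishes an equilibrium from a stall."""
    i0 = int(len(T) * transient_fraction)
    mods = np.vstack([
        np.abs(Y[i0:, 0]),
        np.abs(Y[i0:, 1] + 1j * Y[i0:, 2]),
        np.abs(Y[i0:, 3] + 1j * Y[i0:, 4]),
    ])
    if not np.all(np.ptp(mods, axis=1) < tol):
        return False
    if p is not None:
        resid = np.max(np.abs(_rhs_packed(Y[-1], p)))
        return bool(resid < 1e-7 * max(1.0, float(np.max(np.abs(Y[-1])))))
    return True


# ---------------------------------------------------------------------------
# bifurcation scans

def _model_table(R_values, a, b, lam=1.0, n_quad=240):
    return {round(float(R), 4): compute_coefficients(R, lam=lam, a=a, b=b,
                                                     n_quad=n_quad, check=False)
            for R in R_values}


def find_reversal_threshold(
    lam: float = 9.0, a: float = 0.5, b: float = 1.6,
    R_window: tuple[float, float] = (5.5, 6.3), dR: float = 0.01,
    t_end: float = 2000.0, n_restarts: int = 5, seed: int = 0,
    n_quad: int = 240,
) -> ReversalThresholdResult:
    """Locate the onset radius of the sign-reversing limit cycle.

    Sweeps the radius window downward with the continued cycle state and
    upward with the continued fixed-point state, adding ``n_restarts``
    independent small-noise initializations at each radius, and returns
    the smallest radius sustaining a reversing cycle, the largest radius
    sustaining a fixed point, and the (possibly empty) overlap.  The
    period on the cycle branch grows as the threshold is approached from
    above (infinite-period scenario).
    """
    rng = np.random.default_rng(seed)
    Rs = np.round(np.arange(R_window[0], R_window[1] + 0.5 * dR, dR), 6)
    table = _model_table(Rs, a, b, n_quad=n_quad)
    packed = {R: table[round(float(R), 4)].with_lam(lam).pack() for R in Rs}

    def restarts(p):
        for _ in range(n_restarts):
            y0 = 1e-2 * rng.standard_normal(5)
            yield _integrate_fast(p, y0, t_end=t_end)

    # downward sweep: follow the cycle
    down_labels, down_periods = [], []
    T, Y = _integrate_fast(packed[Rs[-1]], 1e-2 * rng.standard_normal(5), t_end=2.0 * t_end)
    state = Y[-1]
    for R in Rs[::-1]:
        T, Y = _integrate_fast(packed[R], state, t_end=t_end)
        state = Y[-1]
        lab = sustains_limit_cycle(T, Y, transient_fraction=0.25)
        per = _reversal_period(T, Y) if lab == "reversing" else None
        if lab is None:
            for T2, Y2 in restarts(packed[R]):
                lab2 = sustains_limit_cycle(T2, Y2)
                if lab2 is not None:
                    lab, per = lab2, _reversal_period(T2, Y2, 0.5)
                    state = Y2[-1]
                    break
        down_labels.append(lab); down_periods.append(per)
    down_labels = down_labels[::-1]; down_periods = down_periods[::-1]

    # upward sweep: follow the fixed point.  A small noise floor is
    # re-injected at each step so the sweep abandons equilibria that have
    # gone unstable (the A = 0 subspace is exactly invariant, so a
    # noiseless continuation would ride the unstable pure-vortex branch).
    up_fp = []
    T, Y = _integrate_fast(packed[Rs[0]], 1e-2 * rng.standard_normal(5), t_end=2.0 * t_end)
    state = Y[-1]
    for R in Rs:
        T, Y = _integrate_fast(packed[R], state + 1e-6 * rng.standard_normal(5),
                               t_end=t_end)
        state = Y[-1]
        fp = _is_fixed_point(T, Y, packed[R])
        if not fp:
            for T2, Y2 in restarts(packed[R]):
                if _is_fixed_point(T2, Y2, packed[R]):
                    fp = True
                    state = Y2[-1]
                    break
        up_fp.append(fp)

    cyc_idx = [i for i, l in enumerate(down_labels) if l == "reversing"]
    fp_idx = [i for i, f in enumerate(up_fp) if f]
    if not cyc_idx:
        raise RuntimeError("no reversing cycle found in the radius window")
    if not fp_idx:
        raise RuntimeError("no fixed point found in the radius window")
    R_cyc = float(Rs[min(cyc_idx)])
    R_fp = float(Rs[max(fp_idx)])
    hyst = (R_cyc, R_fp) if R_fp >= R_cyc else None
    down = BifurcationScan("R", Rs, down_labels, down_periods, "down")
    up = BifurcationScan("R", Rs, ["fixed_point" if f else "other" for f in up_fp],
                         [None] * len(Rs), "up")
    return ReversalThresholdResult(
        R_cycle_min=R_cyc, R_fixed_point_max=R_fp, hysteresis_window=hyst,
        down_scan=down, up_scan=up,
    )


def find_lambda_threshold(
    a: float = 0.5, b: float = 1.6,
    R_values: tuple[float, ...] = (5.9,),
    lam_window: tuple[float, float] = (3.0, 5.0), dlam: float = 0.05,
    t_end: float = 2000.0, n_restarts: int = 5, seed: int = 0,
    n_quad: int = 240,
) -> float:
    """Smallest advection coefficient sustaining a limit cycle.

    ``R_values`` defaults to a radius inside the reversal window of the
    reference model (a reversing cycle exists there at lam = 9).  The
    coefficients depend on lam only through a linear rescaling of the
    advective couplings, so they are computed once per radius; lam is
    swept downward with the continued cycle state plus seeded restarts,
    and the smallest lam for which any cycle (reversing or pulsating) is
    sustained is returned.
    """
    rng = np.random.default_rng(seed)
    table = _model_table(R_values, a, b, n_quad=n_quad)
    lams = np.round(np.arange(lam_window[1], lam_window[0] - 0.5 * dlam, -dlam), 6)
    smallest = None
    for R in R_values:
        base = table[round(float(R), 4)]
        T, Y = _integrate_fast(base.with_lam(9.0).pack(),
                               1e-2 * rng.standard_normal(5), t_end=2.0 * t_end)
        state = Y[-1]
        for lam in lams:
            p = base.with_lam(float(lam)).pack()
            T, Y = _integrate_fast(p, state, t_end=t_end)
            lab = sustains_limit_cycle(T, Y, transient_fraction=0.25)
            if lab is None:
                for _ in range(n_restarts):
                    T2, Y2 = _integrate_fast(p, 1e-2 * rng.standard_normal(5), t_end=t_end)
                    if sustains_limit_cycle(T2, Y2) is not None:
                        lab = "restart"
                        Y = Y2
                        break
            if lab is None:
                break
            state = Y[-1]
            if smallest is None or lam < smallest:
                smallest = float(lam)
    if smallest is None:
        raise RuntimeError("no limit cycle found anywhere in the lambda window")
    return smallest
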