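"""Linear stability of the quiescent state in a circular well.

Linearizing the dimensionless Toner-Tu-Swift-Hohenberg vorticity equation
about ``v = 0`` gives

    d(omega)/dt = a*omega - (1 + laplacian)^2 omega ,

whose azimuthal modes in a disc of radius ``R`` are superpositions of two
Bessel profiles,

    omega_n(r, theta) = [G+ J_n(k+ r) + G- J_n(k- r)] exp(i n theta) ,

with radial wavenumbers ``k_pm = sqrt(1 +/- sqrt(a - lambda_n))``.  The
velocity field is recovered through a streamfunction ``psi`` with
``omega = -laplacian(psi)`` and ``v = (d_y psi, -d_x psi)``; in polar
components ``v_r = (1/r) d_theta psi`` and ``v_theta = -d_r psi``.  The
streamfunction of a mode carries an extra harmonic (origin-regular) term
``h r^|n|``.  Requiring ``omega = v_r = v_theta = 0`` at ``r = R`` yields a
characteristic determinant whose real roots in ``lambda`` are the growth
rates ``lambda_n(R)``.

The sign convention and the kinetic-energy normalization of the eigenmodes
fixed here are relied upon by :mod:`vortexwell.normal_form`, where the same
modes serve as the Galerkin basis of the three-mode amplitude equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize, special

__all__ = [
    "StabilityParams",
    "RadialEigenmode",
    "GrowthRateCurve",
    "NoRootError",
    "dispersion_unbounded",
    "fastest_growing_wavenumber",
    "characteristic_determinant",
    "growth_rate",
    "growth_rate_curve",
    "critical_radius",
    "eigenmode",
]


class NoRootError(RuntimeError):
    """Raised when no real growth rate (or radius crossing) is found in the scan window."""


@dataclass(frozen=True)
class StabilityParams:
    """Parameters of the linear disc eigenproblem.

    Attributes
    ----------
    a : float
        Linear gain of the model (dimensionless), default 0.5.
    n_max : int
        Highest azimuthal index analyzed by convenience routines.
    """

    a: float = 0.5
    n_max: int = 2

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("linear gain a must be positive")
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")


@dataclass
class RadialEigenmode:
    """One azimuthal eigenmode of the linearized equation in a disc.

    The radial profiles are stored on ``r`` (a Gauss-Legendre grid on
    ``(0, R)`` by default).  The profiles of ``omega``, ``psi`` and
    ``v_theta`` are real in the phase convention used here; ``v_r`` is
    ``i`` times the real array ``v_r_imag`` (the radial velocity of an
    ``exp(i n theta)`` mode is in quadrature with the tangential one).
    The mode is normalized so its kinetic energy
    ``int |v|^2 dA = 2 pi int (|v_r|^2 + |v_theta|^2) r dr`` equals 1.
    """

    n: int
    R: float
    growth_rate: float
    k_plus: complex
    k_minus: complex
    G_plus: complex
    G_minus: complex
    h: complex
    energy_norm: float
    r: np.ndarray = field(repr=False)
    quad_weights: np.ndarray = field(repr=False)
    omega: np.ndarray = field(repr=False)
    d_omega: np.ndarray = field(repr=False)
    psi: np.ndarray = field(repr=False)
    d_psi: np.ndarray = field(repr=False)
    v_theta: np.ndarray = field(repr=False)
    d_v_theta: np.ndarray = field(repr=False)
    v_r_imag: np.ndarray = field(repr=False)
    d_v_r_imag: np.ndarray = field(repr=False)

    @property
    def v_r(self) -> np.ndarray:
        """Complex radial-velocity profile (purely imaginary)."""
        return 1j * self.v_r_imag

    def boundary_values(self) -> tuple[float, float, float]:
        """``(omega, v_r, v_theta)`` evaluated at ``r = R`` (should all vanish)."""
        kp2 = float(np.real(self.k_plus**2))
        km2 = float(np.real(self.k_minus**2))
        w, _, psi, dpsi = _profiles_raw(
            self.n, kp2, km2,
            np.array([np.real(self.G_plus), np.real(self.G_minus)]),
            np.real(self.h), np.array([self.R]),
        )
        vth = -dpsi[0]
        vr = abs(self.n) * psi[0] / self.R
        return float(w[0]), float(vr), float(vth)


# ---------------------------------------------------------------------------
# unbounded dispersion relation

def dispersion_unbounded(k: float, a: float = 0.5) -> float:
    """Growth rate ``a - (1 - k^2)^2`` of a plane wave of wavenumber ``k``.

    This is the dispersion relation of the linearized equation on the
    unbounded plane; it is maximized at ``k = 1``, so the characteristic
    vortex size of the pattern is ``2 pi`` in dimensionless units.
    """
    k = np.asarray(k, dtype=float)
    return a - (1.0 - k**2) ** 2


def fastest_growing_wavenumber(a: float = 0.5) -> tuple[float, float]:
    """Return ``(k*, wavelength)`` maximizing :func:`dispersion_unbounded`.

    Located numerically (the analytic answer is ``k* = 1``); the
    wavelength is ``2 pi / k*``.
    """
    res = optimize.minimize_scalar(
        lambda k: -dispersion_unbounded(k, a), bounds=(1e-6, 3.0), method="bounded",
        options={"xatol": 1e-12},
    )
    kstar = float(res.x)
    return kstar, 2.0 * np.pi / kstar


# ---------------------------------------------------------------------------
# Bessel basis, realified
#
# For lambda < a the squared wavenumbers ksq = 1 +/- sqrt(a - lambda) are
# real; ksq may be negative (k purely imaginary), in which case
# J_n(i x) = i^n I_n(x) and the basis is realified by using I_n directly
# (an overall column phase does not move determinant roots).

def _bessel(n: int, ksq: float, r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if ksq >= 0.0:
        return special.jv(n, np.sqrt(ksq) * r)
    return special.iv(n, np.sqrt(-ksq) * r)


def _bessel_dr(n: int, ksq: float, r: np.ndarray) -> np.ndarray:
    """d/dr of the realified radial basis function."""
    r = np.asarray(r, dtype=float)
    if ksq >= 0.0:
        k = np.sqrt(ksq)
        return k * 0.5 * (special.jv(n - 1, k * r) - special.jv(n + 1, k * r))
    k = np.sqrt(-ksq)
    return k * 0.5 * (special.iv(n - 1, k * r) + special.iv(n + 1, k * r))


def _wavenumbers_sq(lam: float, a: float) -> tuple[float, float]:
    s = np.sqrt(a - lam)  # lam < a on the search branch
    return 1.0 + s, 1.0 - s


_DEGENERATE_TOL = 1e-9


def _boundary_matrix(n: int, lam: float, R: float, a: float) -> np.ndarray:
    """Boundary-condition matrix in the coefficients (G+, G-[, h]).

    Rows: ``omega(R) = 0``; for ``|n| >= 1`` also ``v_r(R) = 0`` (i.e.
    ``psi(R) = 0``) and ``v_theta(R) = 0`` (``psi'(R) = 0``); for ``n = 0``
    the radial velocity vanishes identically and the homogeneous constant
    drops out of the velocity, leaving the 2x2 system
    ``omega(R) = 0``, ``psi'(R) = 0``.
    """
    kp2, km2 = _wavenumbers_sq(lam, a)
    if abs(kp2 - km2) < _DEGENERATE_TOL or abs(km2) < _DEGENERATE_TOL:
        raise FloatingPointError(
            f"degenerate wavenumbers at lambda={lam} (k+^2={kp2}, k-^2={km2})"
        )
    n = abs(n)
    if n == 0:
        return np.array(
            [
                [_bessel(0, kp2, R), _bessel(0, km2, R)],
                [_bessel_dr(0, kp2, R) / kp2, _bessel_dr(0, km2, R) / km2],
            ]
        )
    return np.array(
        [
            [_bessel(n, kp2, R), _bessel(n, km2, R), 0.0],
            [_bessel(n, kp2, R) / kp2, _bessel(n, km2, R) / km2, R**n],
            [_bessel_dr(n, kp2, R) / kp2, _bessel_dr(n, km2, R) / km2, n * R ** (n - 1)],
        ]
    )


def characteristic_determinant(
    n: int, lam: float, R: float, a: float = 0.5, *, perturb: bool = True
) -> float:
    """Determinant of the boundary-condition matrix at trial growth rate ``lam``.

    Zero crossings in ``lam`` locate the growth rates ``lambda_n(R)``.
    The function is continuous in ``lam`` and ``R`` away from the
    degenerate points ``lam = a`` (``k+ = k-``) and ``lam = a - 1``
    (``k- = 0``); those removable singularities are handled by evaluating
    at a slightly perturbed ``lam`` when ``perturb`` is true.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    try:
        m = _boundary_matrix(n, lam, R, a)
    except FloatingPointError:
        if not perturb:
            raise
        m = _boundary_matrix(n, lam - 1e-7, R, a)
    return float(np.linalg.det(m))


_LAMBDA_SCAN_LO = -5.0
_LAMBDA_SCAN_STEP = 0.01


def growth_rate(n: int, R: float, params: StabilityParams | None = None) -> float:
    """Leading real growth rate ``lambda_n(R)`` of azimuthal mode ``n``.

    The characteristic determinant is scanned on
    ``[-5, a)`` with step 0.01 and each sign change refined by Brent's
    method to absolute tolerance 1e-12.  The largest root is returned.

    Raises
    ------
    NoRootError
        If no sign change occurs in the scan window (strongly damped
        small-``R`` modes, or a complex-eigenvalue branch).
    """
    params = params or StabilityParams()
    a = params.a
    lams = np.arange(_LAMBDA_SCAN_LO, a - 1e-6, _LAMBDA_SCAN_STEP)
    vals = np.array([characteristic_determinant(n, l, R, a) for l in lams])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        raise NoRootError(f"no real growth rate for n={n}, R={R} in [{_LAMBDA_SCAN_LO}, {a})")
    roots = [
        optimize.brentq(
            lambda l: characteristic_determinant(n, l, R, a),
            lams[i], lams[i + 1], xtol=1e-12,
        )
        for i in idx
    ]
    return float(max(roots))


@dataclass
class GrowthRateCurve:
    """Leading growth rate of one azimuthal mode on a grid of radii."""

    n: int
    R_grid: np.ndarray
    lambda_values: np.ndarray


def growth_rate_curve(
    n: int, R_min: float, R_max: float, dR: float = 0.01,
    params: StabilityParams | None = None,
) -> GrowthRateCurve:
    """Tabulate ``lambda_n(R)`` on ``[R_min, R_max]``; radii with no real root give NaN."""
    Rs = np.arange(R_min, R_max + 0.5 * dR, dR)
    vals = np.empty_like(Rs)
    for i, R in enumerate(Rs):
        try:
            vals[i] = growth_rate(n, R, params)
        except NoRootError:
            vals[i] = np.nan
    return GrowthRateCurve(n=n, R_grid=Rs, lambda_values=vals)


def critical_radius(
    n: int, params: StabilityParams | None = None,
    R_window: tuple[float, float] = (0.5, 12.0), dR: float = 0.01,
) -> float:
    """Smallest radius at which ``lambda_n`` crosses zero, to 1e-8 in ``R``.

    Scans the window with step ``dR`` for a sign change of the leading
    growth rate (treating radii with no real root as stable) and refines
    by bisection.
    """
    params = params or StabilityParams()

    def lam_of(R: float) -> float:
        try:
            return growth_rate(n, R, params)
        except NoRootError:
            return -np.inf

    prev_R, prev = None, None
    for R in np.arange(R_window[0], R_window[1] + 0.5 * dR, dR):
        val = lam_of(R)
        if prev is not None and prev < 0.0 <= val:
            lo, hi = prev_R, R
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if lam_of(mid) < 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-8:
                    break
            return 0.5 * (lo + hi)
        prev_R, prev = R, val
    raise NoRootError(f"lambda_{n} does not cross zero for R in {R_window}")


# ---------------------------------------------------------------------------
# eigenmodes

def _profiles_raw(n, kp2, km2, G, h, r):
    """Unnormalized profiles (omega, d_omega, psi, d_psi) of a mode."""
    n = abs(n)
    Gp, Gm = G
    w = Gp * _bessel(n, kp2, r) + Gm * _bessel(n, km2, r)
    dw = Gp * _bessel_dr(n, kp2, r) + Gm * _bessel_dr(n, km2, r)
    psi = Gp * _bessel(n, kp2, r) / kp2 + Gm * _bessel(n, km2, r) / km2
    dpsi = Gp * _bessel_dr(n, kp2, r) / kp2 + Gm * _bessel_dr(n, km2, r) / km2
    if n > 0:
        psi = psi + h * r**n
        dpsi = dpsi + h * n * r ** (n - 1)
    return w, dw, psi, dpsi


def eigenmode(
    n: int, R: float, params: StabilityParams | None = None, *, n_quad: int = 240,
) -> RadialEigenmode:
    """Energy-normalized eigenmode of azimuthal index ``n`` at radius ``R``.

    The null space of the boundary matrix at ``lambda_n(R)`` gives the
    Bessel coefficients; the overall phase (sign, in the realified basis)
    is fixed by making ``v_theta`` positive at its largest interior
    extremum, and the amplitude by unit kinetic energy.  Radial profiles
    and their radial derivatives are tabulated on an ``n_quad``-point
    Gauss-Legendre grid, which downstream Galerkin quadratures reuse.

    Raises
    ------
    np.linalg.LinAlgError
        If the boundary matrix is rank-deficient beyond a 1-D null space.
    """
    params = params or StabilityParams()
    a = params.a
    lam = growth_rate(n, R, params)
    kp2, km2 = _wavenumbers_sq(lam, a)
    m = _boundary_matrix(n, lam, R, a)
    u, s, vt = np.linalg.svd(m)
    if m.shape[0] > 1 and s[-2] < 1e-8 * s[0]:
        raise np.linalg.LinAlgError(
            f"boundary matrix at n={n}, R={R} has a degenerate (>1D) null space"
        )
    null = vt[-1]
    G = null[:2]
    h = null[2] if abs(n) >= 1 else 0.0

    x, wq = leggauss(n_quad)
    r = 0.5 * R * (x + 1.0)
    wq = 0.5 * R * wq

    w, dw, psi, dpsi = _profiles_raw(n, kp2, km2, G, h, r)
    nn = abs(n)
    v_theta = -dpsi
    v_r_imag = nn * psi / r
    energy = 2.0 * np.pi * np.sum(wq * r * (v_r_imag**2 + v_theta**2))
    scale = 1.0 / np.sqrt(energy)
    # orientation: v_theta > 0 at its largest extremum
    if v_theta[np.argmax(np.abs(v_theta))] < 0:
        scale = -scale

    w, dw, psi, dpsi = (arr * scale for arr in (w, dw, psi, dpsi))
    v_theta = -dpsi
    v_r_imag = nn * psi / r
    # psi'' from the defining relation -lap(psi) = omega
    d2psi = -w - dpsi / r + nn**2 * psi / r**2
    d_v_theta = -d2psi
    d_v_r_imag = nn * (dpsi / r - psi / r**2)

    return RadialEigenmode(
        n=n, R=R, growth_rate=lam,
        k_plus=complex(np.sqrt(complex(kp2))), k_minus=complex(np.sqrt(complex(km2))),
        G_plus=complex(G[0] * scale), G_minus=complex(G[1] * scale),
        h=complex(h * scale), energy_norm=1.0,
        r=r, quad_weights=wq,
        omega=w, d_omega=dw, psi=psi, d_psi=dpsi,
        v_theta=v_theta, d_v_theta=d_v_theta,
        v_r_imag=v_r_imag, d_v_r_imag=d_v_r_imag,
    )
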