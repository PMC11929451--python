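"""Term-library regression of the governing vorticity equation.

Given a time series of flow fields on a periodic grid, the vorticity
tendency ``d(omega)/dt`` (centered finite differences in time) is
regressed onto a library of candidate field operators evaluated
spectrally.  Two fixed libraries are provided:

``ttshe``
    ``{omega, lap(omega), lap^2(omega), v.grad(omega), curl(|v|^2 v)}`` -
    the vorticity form of the Toner-Tu-Swift-Hohenberg model, whose true
    coefficients are ``(a - 1, -2, -1, -lam, -b)``.

``nikolaevskiy``
    ``{lap(omega), lap^2(omega), lap^3(omega), v.grad(omega)}`` - the
    Nikolaevskiy alternative, which carries a sixth-order operator but no
    linear (omega) term and no cubic nonlinearity.

Ordinary least squares on standardized columns gives the coefficient
estimates with standard errors; the relative residual of each library on
identical rows ranks the models.  Rows are restricted to well interiors
(damping mask K < 0.1) so the penalized wall region does not enter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .fields import FlowField

__all__ = ["TermLibrary", "RegressionResult", "build_design", "fit",
           "compare_models", "recover_ttshe_parameters"]

_LIBRARIES = {
    "ttshe": ("omega", "lap_omega", "lap2_omega", "advection", "cubic_curl"),
    "nikolaevskiy": ("lap_omega", "lap2_omega", "lap3_omega", "advection"),
}


@dataclass(frozen=True)
class TermLibrary:
    """A named, fixed set of candidate terms."""

    model_name: str

    def __post_init__(self):
        if self.model_name not in _LIBRARIES:
            raise ValueError(f"unknown library {self.model_name!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return _LIBRARIES[self.model_name]


@dataclass
class RegressionResult:
    model_name: str
    coefficients: dict
    standard_errors: dict
    residual_norm: float


def _term_fields(frame: FlowField, L: float):
    """Evaluate all candidate operators spectrally on one frame."""
    w = frame.vorticity
    N = w.shape[0]
    kx = 2 * np.pi * sfft.fftfreq(N, L / N)[:, None]
    ky = 2 * np.pi * sfft.rfftfreq(N, L / N)[None, :]
    k2 = kx**2 + ky**2
    wh = sfft.rfft2(w)
    lap = sfft.irfft2(-k2 * wh, s=w.shape)
    lap2 = sfft.irfft2(k2**2 * wh, s=w.shape)
    lap3 = sfft.irfft2(-(k2**3) * wh, s=w.shape)
    wx = sfft.irfft2(1j * kx * wh, s=w.shape)
    wy = sfft.irfft2(1j * ky * wh, s=w.shape)
    adv = frame.vx * wx + frame.vy * wy
    q = frame.vx**2 + frame.vy**2
    fxh = sfft.rfft2(q * frame.vx)
    fyh = sfft.rfft2(q * frame.vy)
    cubic = sfft.irfft2(1j * kx * fyh - 1j * ky * fxh, s=w.shape)
    return {
        "omega": w, "lap_omega": lap, "lap2_omega": lap2, "lap3_omega": lap3,
        "advection": adv, "cubic_curl": cubic,
    }


def build_design(
    frames: list[FlowField], library: TermLibrary,
    damping_mask: np.ndarray | None = None, mask_threshold: float = 0.1,
    standardize: bool = True,
):
    """Design matrix and target vector for one library.

    The target is the centered time difference of the vorticity at
    interior frames; rows are grid nodes where the damping mask is below
    ``mask_threshold`` (all nodes when no mask is given).  Columns are
    standardized to unit RMS with the scalings returned for
    back-transformation.

    Returns ``(design, target, scales)``.
    """
    if len(frames) < 3:
        raise ValueError("need at least 3 consecutive frames")
    dts = np.diff([f.time for f in frames])
    if np.ptp(dts) > 1e-9 * dts[0]:
        raise ValueError("frames must be uniformly spaced in time")
    dt = float(dts[0])
    L = frames[0].dx * frames[0].vorticity.shape[0]
    keep = (np.ones_like(frames[0].vorticity, bool) if damping_mask is None
            else damping_mask < mask_threshold)

    rows_X, rows_y = [], []
    for i in range(1, len(frames) - 1):
        target = (frames[i + 1].vorticity - frames[i - 1].vorticity) / (2.0 * dt)
        tf = _term_fields(frames[i], L)
        rows_y.append(target[keep])
        rows_X.append(np.stack([tf[t][keep] for t in library.terms], axis=-1))
    X = np.concatenate(rows_X, axis=0)
    y = np.concatenate(rows_y, axis=0)
    if standardize:
        scales = np.sqrt(np.mean(X**2, axis=0))
        if np.any(scales == 0):
            bad = [library.terms[i] for i in np.nonzero(scales == 0)[0]]
            raise ValueError(f"zero-norm columns: {bad}")
        X = X / scales
    else:
        scales = np.ones(X.shape[1])
    return X, y, scales


def fit(design: np.ndarray, target: np.ndarray, library: TermLibrary,
        scales: np.ndarray | None = None) -> RegressionResult:
    """Ordinary least squares with standard errors from the residual covariance."""
    scales = scales if scales is not None else np.ones(design.shape[1])
    n, p = design.shape
    beta, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < p:
        g = design.T @ design
        corr = np.abs(g) / np.sqrt(np.outer(np.diag(g), np.diag(g)))
        pairs = [(library.terms[i], library.terms[j])
                 for i in range(p) for j in range(i + 1, p) if corr[i, j] > 1 - 1e-10]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {pairs}")
    resid = target - design @ beta
    sigma2 = float(resid @ resid) / max(n - p, 1)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    rel = float(np.linalg.norm(resid) / max(np.linalg.norm(target), 1e-30))
    coeff = {t: float(b / s) for t, b, s in zip(library.terms, beta, scales)}
    errs = {t: float(e / s) for t, e, s in zip(library.terms, se, scales)}
    return RegressionResult(
        model_name=library.model_name, coefficients=coeff,
        standard_errors=errs, residual_norm=min(rel, 1.0),
    )


def compare_models(
    frames: list[FlowField],
    model_names: tuple[str, ...] = ("ttshe", "nikolaevskiy"),
    damping_mask: np.ndarray | None = None,
    indistinguishable_margin: float = 0.01,
):
    """Fit each library on identical rows and rank by relative residual.

    Returns ``(ranked_results, flag)`` where ``flag`` is
    ``"indistinguishable"`` when the two best relative residuals differ
    by less than ``indistinguishable_margin`` (on the 0..1 residual
    scale), else ``None``.
    """
    if not frames:
        raise ValueError("empty field sequence")
    results = []
    for name in model_names:
        lib = TermLibrary(name)
        X, y, sc = build_design(frames, lib, damping_mask)
        results.append(fit(X, y, lib, sc))
    results.sort(key=lambda r: r.residual_norm)
    flag = None
    if len(results) >= 2:
        r0, r1 = results[0].residual_norm, results[1].residual_norm
        if abs(r1 - r0) < indistinguishable_margin:
            flag = "indistinguishable"
    return results, flag


def recover_ttshe_parameters(result: RegressionResult) -> dict:
    """Physical parameters (lam, a, b) from fitted ``ttshe`` library coefficients.

    Model: ``d_t omega = (a-1) omega - 2 lap(omega) - lap^2(omega)
    - lam (v.grad omega) - b curl(|v|^2 v)``.
    """
    if result.model_name != "ttshe":
        raise ValueError("parameter recovery applies to the ttshe library")
    c = result.coefficients
    return {
        "lam": -c["advection"],
        "a": c["omega"] + 1.0,
        "b": -c["cubic_curl"],
        "lap_coeff": c["lap_omega"],      # expected -2
        "lap2_coeff": c["lap2_omega"],    # expected -1
    }
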