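"""Voxelwise nonlinear least-squares DKI fitting (the conventional baseline).

Each voxel's signal series is fitted to S0*exp(-b*D + b^2*D^2*K/6) by
Levenberg-Marquardt, initialised from a log-domain quadratic fit of
ln(S_j/S_0) in b (whose linear and quadratic coefficients give D and
D^2*K/6).  The fit is unconstrained by default — in noisy data K (and in
extreme cases D) may come out negative, which is deliberate: clamping
would hide the baseline's characteristic error behaviour.  An optional
clamp forces K >= 0 and D > 0.

On noise-free data the model class contains the truth, so the fit is an
exact-recovery oracle (used as such by the test-suite and the phantom
round trip).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dki import AcquisitionScheme, D_SCALE

__all__ = ["LSFFit", "lsf_fit_voxel", "lsf_fit_volume"]

# exponent clip keeps the model evaluable for wild LM trial steps
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class LSFFit:
    """One voxel's fitted (S0, D, K) with a convergence flag.

    D is in mm^2/s.  ``converged`` is False when the optimiser failed and
    the log-domain initialiser was returned instead.
    """

    S0: float
    D: float
    K: float
    converged: bool


def _model(b: np.ndarray, s0: float, d_scaled: float, k: float) -> np.ndarray:
    d = d_scaled / D_SCALE
    expo = np.clip(-b * d + b * b * d * d * k / 6.0, -_EXP_CLIP, _EXP_CLIP)
    return s0 * np.exp(expo)


def _log_init(signals: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Quadratic fit of ln(S_j/S_0) in b: coefficients give -D and D^2*K/6."""
    s0 = signals[0]
    ratio = np.clip(signals[1:] / s0, 1e-12, None)
    y = np.log(ratio)
    bb = b[1:]
    design = np.stack([bb, bb * bb], axis=1)
    (c1, c2), *_ = np.linalg.lstsq(design, y, rcond=None)
    d = -c1
    if d <= 0:
        d = 1e-5 / D_SCALE  # degenerate: fall back to a tiny positive D
        k = 0.0
    else:
        k = 6.0 * c2 / (d * d)
    return float(s0), float(d), float(k)


def lsf_fit_voxel(
    signals: np.ndarray, scheme: AcquisitionScheme, clamp: bool = False
) -> LSFFit:
    """Fit one voxel's series of N+1 signals by nonlinear least squares."""
    signals = np.asarray(signals, dtype=float)
    b = scheme.b
    if signals.shape != b.shape:
        raise ValueError(
            f"expected {b.size} signals (one per b-value), got {signals.shape}"
        )
    if np.all(signals == 0):
        return LSFFit(0.0, 0.0, 0.0, converged=False)
    if signals[0] <= 0:
        raise ValueError("baseline (b=0) signal must be positive")
    s0_0, d_0, k_0 = _log_init(signals, b)
    # fit in scaled units (S0 ~ 1e2-1e3, D*1e3 ~ 1, K ~ 1) for conditioning
    x0 = np.array([s0_0, d_0 * D_SCALE, k_0])

    def residuals(x):
        return _model(b, *x) - signals

    try:
        res = least_squares(
            residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=400,
        )
        ok = bool(res.success)
        s0, d_scaled, k = res.x
    except Exception:
        ok = False
        s0, d_scaled, k = x0
    if not ok:
        s0, d_scaled, k = x0  # report the initialiser with a warning flag
    d = d_scaled / D_SCALE
    if clamp:
        d = max(d, 1e-12)
        k = max(k, 0.0)
    return LSFFit(float(s0), float(d), float(k), converged=ok)


def lsf_fit_volume(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    clamp: bool = False,
    b0_eps: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Apply :func:`lsf_fit_voxel` over a 4D volume.

    Background voxels (baseline at or below the epsilon guard, default
    1e-6 x volume max) are skipped and zero-filled.  Returns
    ``(S0 map, D map, K map, converged mask)``.
    """
    if dwi.ndim != 4:
        raise ValueError("expected a 4D volume (x, y, z, b)")
    if dwi.shape[3] != len(scheme.bvalues):
        raise ValueError("volume frame count does not match the scheme")
    dwi = np.asarray(dwi, dtype=float)
    if b0_eps is None:
        b0_eps = 1e-6 * float(np.max(dwi)) if dwi.size else 0.0
    shape = dwi.shape[:3]
    s0_map = np.zeros(shape)
    d_map = np.zeros(shape)
    k_map = np.zeros(shape)
    conv = np.zeros(shape, dtype=bool)
    fg = np.nonzero(dwi[..., 0] > b0_eps)
    for i, j, k in zip(*fg):
        fit = lsf_fit_voxel(dwi[i, j, k], scheme, clamp=clamp)
        s0_map[i, j, k] = fit.S0
        d_map[i, j, k] = fit.D
        k_map[i, j, k] = fit.K
        conv[i, j, k] = fit.converged
    return s0_map, d_map, k_map, conv
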