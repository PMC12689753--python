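"""Classical least-squares T2/S0 estimation (LSF) by variable projection.

For a mono-exponential train x_i = S0 * exp(-TE_i/T2) + noise, the optimal
complex amplitude for a fixed T2 is available in closed form

    S0*(T2) = sum_i w_i x_i / sum_i w_i^2,   w_i = exp(-TE_i/T2),

which reduces the fit to a 1-D search over T2 (log-spaced grid scan +
golden-section refinement).  Fitting is complex-valued: with complex
Gaussian noise this is unbiased, whereas magnitude fitting is Rician-biased.
A magnitude variant is available behind a flag for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .sigmodel import EchoSchedule, MultiContrastImage, ParameterMaps

__all__ = ["FitOptions", "lsf_fit_pixel", "lsf_fit_image"]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class FitOptions:
    """T2 search bounds (ms), grid size and refinement tolerance (ms)."""

    t2_bounds: Tuple[float, float] = (1.0, 3000.0)
    grid_size: int = 256
    tol: float = 1e-3
    magnitude: bool = False  # fit |x| instead of the complex signal

    def __post_init__(self) -> None:
        lo, hi = self.t2_bounds
        if not 0 < lo < hi:
            raise ValueError("need 0 < t2_min < t2_max")
        if self.grid_size < 4:
            raise ValueError("grid too small")


def _score(signals: np.ndarray, tes: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Variable-projection score |sum w x|^2 / sum w^2 per (pixel, T2)."""
    w = np.exp(-tes[None, :] / t2[:, None])  # (G, P)
    num = np.abs(signals @ w.T) ** 2  # (N, G)
    den = (w * w).sum(axis=1)  # (G,)
    return num / den


def _score_at(signals: np.ndarray, tes: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Score with a per-pixel T2 vector (N,) -> (N,)."""
    w = np.exp(-tes[None, :] / t2[:, None])  # (N, P)
    num = np.abs((w * signals).sum(axis=1)) ** 2
    den = (w * w).sum(axis=1)
    return num / den


def _fit_batch(
    signals: np.ndarray, tes: np.ndarray, opts: FitOptions
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized variable-projection fit of (N, P) complex signals.

    Returns (t2, s0 complex, residual, clamped flag).
    """
    n = signals.shape[0]
    lo, hi = opts.t2_bounds
    grid = np.geomspace(lo, hi, opts.grid_size)
    score = _score(signals, tes, grid)  # (N, G)
    best = np.argmax(score, axis=1)
    # golden-section refinement in log-T2 between the grid neighbors
    lidx = np.maximum(best - 1, 0)
    ridx = np.minimum(best + 1, opts.grid_size - 1)
    a = np.log(grid[lidx])
    b = np.log(grid[ridx])
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = _score_at(signals, tes, np.exp(c))
    fd = _score_at(signals, tes, np.exp(d))
    for _ in range(200):  # invphi^200 << any tol; loop exits on width early
        width = np.exp(b) - np.exp(a)
        if np.all(width < opts.tol):
            break
        take_left = fc > fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc = _score_at(signals, tes, np.exp(c))
        fd = _score_at(signals, tes, np.exp(d))
    t2 = np.exp((a + b) / 2.0)
    clamped = (best == 0) | (best == opts.grid_size - 1)
    t2 = np.where(clamped & (best == 0), lo, t2)
    t2 = np.where(clamped & (best == opts.grid_size - 1), hi, t2)
    w = np.exp(-tes[None, :] / t2[:, None])
    s0 = (w * signals).sum(axis=1) / (w * w).sum(axis=1)
    resid = (np.abs(signals - s0[:, None] * w) ** 2).sum(axis=1)
    # degenerate all-zero signals
    zero = np.all(signals == 0, axis=1)
    t2 = np.where(zero, lo, t2)
    s0 = np.where(zero, 0.0, s0)
    resid = np.where(zero, 0.0, resid)
    clamped = clamped | zero
    return t2, s0, resid, clamped


def lsf_fit_pixel(
    signal: np.ndarray, schedule: EchoSchedule, opts: FitOptions = FitOptions()
) -> Tuple[float, float, float, float, bool]:
    """Fit one echo train; returns (t2, s0_re, s0_im, residual, degenerate)."""
    signal = np.asarray(signal, dtype=complex)
    if signal.ndim != 1 or signal.size != schedule.n_echoes:
        raise ValueError("signal length must match the schedule")
    if signal.size < 2:
        raise ValueError("need at least two echoes")
    sig = np.abs(signal).astype(complex) if opts.magnitude else signal
    t2, s0, resid, flag = _fit_batch(sig[None], schedule.tes, opts)
    return float(t2[0]), float(s0[0].real), float(s0[0].imag), float(resid[0]), bool(flag[0])


def lsf_fit_image(
    x: MultiContrastImage,
    opts: FitOptions = FitOptions(),
    foreground: Optional[np.ndarray] = None,
) -> ParameterMaps:
    """Pixel-wise LSF over a foreground mask; background pixels are zero."""
    h, w = x.shape
    if foreground is None:
        foreground = np.ones((h, w), dtype=bool)
    foreground = np.asarray(foreground, dtype=bool)
    sig = x.data.reshape(x.n_echoes, -1).T[foreground.ravel()]  # (N, P)
    if opts.magnitude:
        sig = np.abs(sig).astype(complex)
    t2 = np.zeros(h * w)
    s0 = np.zeros(h * w, dtype=complex)
    if sig.shape[0]:
        t2_f, s0_f, _, _ = _fit_batch(sig, x.schedule.tes, opts)
        t2[foreground.ravel()] = t2_f
        s0[foreground.ravel()] = s0_f
    return ParameterMaps(
        t2=t2.reshape(h, w),
        s0_re=s0.real.reshape(h, w),
        s0_im=s0.imag.reshape(h, w),
    )
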