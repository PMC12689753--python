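"""Multi-contrast Fourier encoding E_Omega and the data-consistency step.

The encoding operator stacks, per echo, an orthonormal centered 2-D DFT
followed by a binary phase-encode line mask:

    E_Omega = [M_{Omega_1} F, ..., M_{Omega_P} F]^T

Unitary scaling and centered (fftshifted) k-space are used throughout so
Parseval and adjoint identities hold exactly and the noise variance is
transform-invariant.  The functions here are written against
``autograd.numpy`` so the learned modules can differentiate through them;
they behave identically on plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import autograd.numpy as anp
import numpy as np

from .sigmodel import EchoSchedule, MultiContrastImage

__all__ = [
    "SamplingMaskSet",
    "KSpaceSet",
    "fft2c",
    "ifft2c",
    "make_mask_set",
    "encode",
    "adjoint",
    "zero_fill",
    "data_consistency",
]


def fft2c(x):
    """Orthonormal centered 2-D FFT over the last two axes."""
    return anp.fft.fftshift(
        anp.fft.fft2(anp.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(k):
    """Inverse of :func:`fft2c`."""
    return anp.fft.fftshift(
        anp.fft.ifft2(anp.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def default_center_lines(h: int) -> int:
    """Fully sampled low-frequency calibration block: max(2, 4% of H)."""
    return max(2, int(round(0.04 * h)))


@dataclass
class SamplingMaskSet:
    """One binary phase-encode mask per echo, Omega = {Omega_1..Omega_P}.

    Masks have shape (P, H, W), are constant along the frequency-encode
    (column) axis and sample exactly round(H/af) lines per echo, always
    including ``center_lines`` central lines.
    """

    masks: np.ndarray
    af: float
    center_lines: int
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3:
            raise ValueError("expected (P, H, W) masks")
        if not np.all((m == 0) | (m == 1)):
            raise ValueError("masks must be binary")
        if np.any(m != m[:, :, :1]):
            raise ValueError("masks must be constant along the readout axis")
        self.masks = m.astype(np.float32)

    @property
    def n_echoes(self) -> int:
        return self.masks.shape[0]

    def lines_per_echo(self) -> np.ndarray:
        return self.masks[:, :, 0].sum(axis=1).astype(int)


def _center_indices(h: int, n: int) -> np.ndarray:
    c = h // 2  # DC line after fftshift
    lo = c - (n - 1) // 2
    return np.arange(lo, lo + n)


def make_mask_set(
    h: int,
    w: int,
    p: int,
    af: float,
    center_lines: Optional[int] = None,
    seed: int = 0,
) -> SamplingMaskSet:
    """Gaussian variable-density Cartesian line masks, drawn per echo.

    Per echo, an independent draw keeps a fully sampled central block of
    ``center_lines`` phase-encode lines plus ``round(h/af) - center_lines``
    outer lines drawn without replacement with probability proportional to a
    Gaussian density in |k_y| (sigma = h/4).  Echoes use independent draws
    (temporally incoherent sampling), reproducible from ``seed``.
    """
    if af < 1:
        raise ValueError("acceleration factor must be >= 1")
    if center_lines is None:
        center_lines = default_center_lines(h)
    n_lines = int(round(h / af))
    if n_lines < center_lines:
        raise ValueError(
            f"round(h/af) = {n_lines} is smaller than center_lines = {center_lines}"
        )
    rng = np.random.default_rng(seed)
    center = _center_indices(h, center_lines)
    ky = np.arange(h) - h // 2
    density = np.exp(-0.5 * (ky / (h / 4.0)) ** 2)
    density[center] = 0.0
    masks = np.zeros((p, h, w), dtype=np.float32)
    for i in range(p):
        lines = center
        n_extra = n_lines - center_lines
        if n_extra > 0:
            prob = density / density.sum()
            extra = rng.choice(h, size=n_extra, replace=False, p=prob)
            lines = np.concatenate([center, extra])
        masks[i, lines, :] = 1.0
    return SamplingMaskSet(masks=masks, af=af, center_lines=center_lines, seed=seed)


def full_mask_set(h: int, w: int, p: int) -> SamplingMaskSet:
    return SamplingMaskSet(
        masks=np.ones((p, h, w), dtype=np.float32), af=1.0, center_lines=h, seed=0
    )


@dataclass
class KSpaceSet:
    """P complex k-space grids; exactly zero off the sampling set if masked."""

    data: np.ndarray
    schedule: EchoSchedule
    masks: Optional[SamplingMaskSet] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(complex)
        if self.data.ndim != 3:
            raise ValueError("expected (P, H, W) k-space data")
        if self.data.shape[0] != self.schedule.n_echoes:
            raise ValueError("echo count does not match schedule")
        if self.masks is not None:
            if self.masks.masks.shape != self.data.shape:
                raise ValueError("mask shape does not match data")
            if np.any(self.data[self.masks.masks == 0] != 0):
                raise ValueError("data must vanish at unsampled points")


def encode(
    x: MultiContrastImage, masks: Optional[SamplingMaskSet] = None
) -> KSpaceSet:
    """Forward encoding: per-echo unitary centered FFT, then mask."""
    k = fft2c(x.data)
    if masks is not None:
        if masks.masks.shape != x.data.shape:
            raise ValueError("mask shape does not match image")
        k = k * masks.masks
    return KSpaceSet(data=k, schedule=x.schedule, masks=masks)


def adjoint(y: KSpaceSet) -> MultiContrastImage:
    """Adjoint encoding E^H: mask, then inverse unitary centered FFT."""
    k = y.data
    if y.masks is not None:
        k = k * y.masks.masks
    return MultiContrastImage(data=ifft2c(k), schedule=y.schedule)


def zero_fill(y: KSpaceSet) -> MultiContrastImage:
    """Zero-filled reconstruction x_zf = E_Omega^H y_Omega (alias of adjoint)."""
    return adjoint(y)


def dc_arrays(k_est, y, mask, nu=np.inf):
    """Closed-form data consistency on raw arrays (autograd-differentiable).

    Off Omega the estimate passes through; on Omega it is replaced by
    (k_est + nu*y) / (1 + nu), which for nu = inf is the measured value.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    if np.isinf(nu):
        blended = y
    else:
        blended = (k_est + nu * y) / (1.0 + nu)
    return k_est * (1.0 - mask) + blended * mask


def data_consistency(
    k_est: KSpaceSet, y: KSpaceSet, masks: SamplingMaskSet, nu: float = np.inf
) -> KSpaceSet:
    """Data-consistency step on :class:`KSpaceSet` containers."""
    if k_est.data.shape != y.data.shape:
        raise ValueError("k-space shapes disagree")
    out = dc_arrays(k_est.data, y.data, masks.masks, nu)
    return KSpaceSet(data=out, schedule=k_est.schedule, masks=None)
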