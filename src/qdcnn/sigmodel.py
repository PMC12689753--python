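"""Mono-exponential multi-echo spin-echo (MSME) signal model.

The signal of a spin-echo train at echo time TE decays as

    S(S0, T2, TE) = S0 * exp(-TE / T2)

with a complex amplitude ``S0`` proportional to proton density (saturated by
the T1/TR recovery factor) and the transverse relaxation time ``T2`` in ms.
Parameter maps are the triple (T2, Re{S0}, Im{S0}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EchoSchedule",
    "ParameterMaps",
    "MultiContrastImage",
    "synthesize_signal",
    "s0_from_pd",
    "complex_to_channels",
    "channels_to_complex",
]


@dataclass(frozen=True)
class EchoSchedule:
    """Echo times (ms, strictly increasing) and the repetition time (ms)."""

    tes: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        tes = np.asarray(self.tes, dtype=float)
        object.__setattr__(self, "tes", tes)
        if tes.ndim != 1 or tes.size < 2:
            raise ValueError("need at least two echo times")
        if np.any(tes <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.tr <= tes[-1]:
            raise ValueError("TR must exceed the last echo time")

    @property
    def n_echoes(self) -> int:
        return int(self.tes.size)

    def subset(self, indices: np.ndarray) -> "EchoSchedule":
        return EchoSchedule(tes=self.tes[np.asarray(indices)], tr=self.tr)


def default_schedule() -> EchoSchedule:
    """16-echo schedule, TE = 10, 20, ..., 160 ms at TR = 7000 ms."""
    return EchoSchedule(tes=np.arange(10.0, 161.0, 10.0), tr=7000.0)


@dataclass
class ParameterMaps:
    """Per-pixel T2 (ms) and the real/imaginary parts of S0 (a.u.)."""

    t2: np.ndarray
    s0_re: np.ndarray
    s0_im: np.ndarray

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        self.s0_re = np.asarray(self.s0_re, dtype=float)
        self.s0_im = np.asarray(self.s0_im, dtype=float)
        if not (self.t2.shape == self.s0_re.shape == self.s0_im.shape):
            raise ValueError("t2/s0_re/s0_im shapes differ")
        if np.any(self.t2 < 0):
            raise ValueError("T2 must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.t2.shape

    @property
    def s0(self) -> np.ndarray:
        return self.s0_re + 1j * self.s0_im

    def stack(self) -> np.ndarray:
        """(3, H, W) array ordered (T2, Re{S0}, Im{S0})."""
        return np.stack([self.t2, self.s0_re, self.s0_im])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "ParameterMaps":
        if arr.shape[0] != 3:
            raise ValueError("expected leading axis of length 3")
        return cls(t2=arr[0], s0_re=arr[1], s0_im=arr[2])


@dataclass
class MultiContrastImage:
    """P complex images sharing one echo schedule; data shape (P, H, W)."""

    data: np.ndarray
    schedule: EchoSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(complex)
        if self.data.ndim != 3:
            raise ValueError("expected (P, H, W) data")
        if self.data.shape[0] != self.schedule.n_echoes:
            raise ValueError("echo count does not match schedule")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite image values")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    def to_channels(self) -> np.ndarray:
        """Real-channel packing (2P, H, W): real parts then imaginary parts."""
        return complex_to_channels(self.data)

    @classmethod
    def from_channels(
        cls, channels: np.ndarray, schedule: EchoSchedule
    ) -> "MultiContrastImage":
        return cls(data=channels_to_complex(channels), schedule=schedule)


def complex_to_channels(data: np.ndarray) -> np.ndarray:
    """Pack complex (..., P, H, W) into real (..., 2P, H, W).

    The only place the two-real-channel convention is defined: the first P
    channels are the real parts (echo order), the last P the imaginary parts.
    """
    return np.concatenate([np.real(data), np.imag(data)], axis=-3)


def channels_to_complex(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`complex_to_channels`."""
    n2 = channels.shape[-3]
    if n2 % 2:
        raise ValueError("channel axis must have even length")
    p = n2 // 2
    re = channels[..., :p, :, :]
    im = channels[..., p:, :, :]
    return re + 1j * im


def synthesize_signal(
    params: ParameterMaps, schedule: EchoSchedule
) -> MultiContrastImage:
    """Evaluate the decay model per pixel for every echo of the schedule.

    Pixels with T2 = 0 must carry S0 = 0 (background) and map to exactly 0.
    """
    t2 = params.t2
    s0 = params.s0
    fg = np.abs(s0) > 0
    if np.any(t2[fg] <= 0):
        raise ValueError("T2 must be positive wherever |S0| > 0")
    safe_t2 = np.where(t2 > 0, t2, np.inf)
    tes = schedule.tes[:, None, None]
    decay = np.exp(-tes / safe_t2[None])
    data = s0[None] * decay
    data[:, ~fg] = 0.0
    return MultiContrastImage(data=data, schedule=schedule)


def s0_from_pd(pd: np.ndarray, t1: np.ndarray, tr: float) -> np.ndarray:
    """S0 = PD * (1 - exp(-TR/T1)); background (PD = 0) stays 0."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    pd = np.asarray(pd, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(pd < 0):
        raise ValueError("PD must be non-negative")
    fg = pd > 0
    if np.any(t1[fg] <= 0):
        raise ValueError("T1 must be positive on foreground")
    safe_t1 = np.where(t1 > 0, t1, np.inf)
    s0 = pd * (1.0 - np.exp(-tr / safe_t1))
    s0[~fg] = 0.0
    return s0
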