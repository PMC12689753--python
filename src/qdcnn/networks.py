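"""Learned modules: the unrolled data-consistent reconstruction network
``f_rec`` and the pixel-wise fully connected mapping network ``f_map``.

``f_rec`` is a deep cascade of convolutional denoisers interleaved with
closed-form data-consistency steps: each cascade applies a residual CNN to
the 2P-real-channel multi-echo image, transforms to k-space, replaces (or
softly blends) the measured coefficients, and transforms back.  ``f_map``
maps each pixel's length-2P echo vector independently through a shared MLP
to (T2, Re{S0}, Im{S0}); the T2 channel passes through a smooth bounded
positivity transform.

All forwards are written against ``autograd.numpy`` so the training module
can differentiate end-to-end; weights are plain nested lists/dicts of
float32 numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive

from .encoding import KSpaceSet, SamplingMaskSet, dc_arrays, fft2c, ifft2c, zero_fill
from .sigmodel import MultiContrastImage, ParameterMaps

__all__ = [
    "ReconNetConfig",
    "MapNetConfig",
    "init_frec_weights",
    "init_fmap_weights",
    "frec_forward",
    "fmap_forward",
    "qdcnn_forward",
    "frec_forward_arrays",
    "fmap_forward_arrays",
    "n_params",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ReconNetConfig:
    """Unrolled reconstruction network: cascades of residual CNN + DC."""

    n_cascades: int = 5
    convs_per_cascade: int = 5
    filters: int = 64
    kernel: int = 3
    dc_weight: float = np.inf  # nu; inf = hard data consistency
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cascades < 0 or self.convs_per_cascade < 1 or self.filters < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def desk(cls, **overrides) -> "ReconNetConfig":
        kw = dict(n_cascades=2, convs_per_cascade=3, filters=16)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class MapNetConfig:
    """Pixel-wise FCNN: 2P inputs -> hidden rectifier layers -> 3 outputs."""

    hidden_layers: int = 4
    hidden_units: int = 128
    t2_min: float = 1.0
    t2_max: float = 3000.0
    normalize_input: bool = False  # divide by first-echo magnitude + re-inject
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_units < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.t2_min < self.t2_max:
            raise ValueError("need 0 < t2_min < t2_max")

    def input_width(self, n_echoes: int) -> int:
        return 2 * n_echoes + (2 if self.normalize_input else 0)


# ------------------------------------------------------------- precision
#
# The pixel-wise MLP runs in float32 (sgemm is ~2.5x dgemm here); the conv
# stack and the FFT/data-consistency path stay float64 — the conv backward
# pass through reverse-mode tensordot is measurably slower in float32 on
# this BLAS, and float64 keeps the hard-DC exactness invariants tight.
# Gradients are cast back to the dtype of the upstream value.


@primitive
def to_f32(x):
    return np.asarray(x, dtype=np.float32)


@primitive
def to_f64(x):
    return np.asarray(x, dtype=np.float64)


defvjp(to_f32, lambda ans, x: lambda g: np.asarray(g, dtype=np.float64))
defvjp(to_f64, lambda ans, x: lambda g: np.asarray(g, dtype=np.float32))


# ---------------------------------------------------------------- weights


def _he_init(rng, fan_in, shape, dtype=np.float64):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def init_frec_weights(cfg: ReconNetConfig, n_echoes: int) -> List[List[tuple]]:
    """Per cascade, a list of (kernel, bias) conv layers, variance-scaled.

    The final conv of each cascade maps back to 2P channels and is
    zero-initialized so an untrained cascade starts as the identity
    (residual connection adds zero).
    """
    rng = np.random.default_rng(cfg.seed)
    c_img = 2 * n_echoes
    k = cfg.kernel
    cascades = []
    for _ in range(cfg.n_cascades):
        layers = []
        chans = [c_img] + [cfg.filters] * (cfg.convs_per_cascade - 1) + [c_img]
        for i in range(cfg.convs_per_cascade):
            cin, cout = chans[i], chans[i + 1]
            fan_in = cin * k * k
            if i == cfg.convs_per_cascade - 1:
                w = np.zeros((cout, cin, k, k))
            else:
                w = _he_init(rng, fan_in, (cout, cin, k, k))
            b = np.zeros(cout)
            layers.append((w, b))
        cascades.append(layers)
    return cascades


def init_fmap_weights(cfg: MapNetConfig, n_echoes: int) -> List[tuple]:
    rng = np.random.default_rng(cfg.seed)
    widths = (
        [cfg.input_width(n_echoes)]
        + [cfg.hidden_units] * cfg.hidden_layers
        + [3]
    )
    layers = []
    for cin, cout in zip(widths[:-1], widths[1:]):
        w = _he_init(rng, cin, (cin, cout), dtype=np.float32)
        b = np.zeros(cout, dtype=np.float32)
        layers.append((w, b))
    return layers


def n_params(weights) -> int:
    """Total scalar parameter count of a nested weight structure."""
    if isinstance(weights, np.ndarray):
        return weights.size
    if isinstance(weights, (list, tuple)):
        return sum(n_params(w) for w in weights)
    if isinstance(weights, dict):
        return sum(n_params(w) for w in weights.values())
    raise TypeError(type(weights))


# ---------------------------------------------------------------- forwards


def conv2d_same(x, w, b):
    """3x3 (or kxk) same-padding conv on (B, C, H, W), autograd-friendly.

    Expressed as a sum of k*k shifted tensordots so the backward pass stays
    in BLAS-backed ops.
    """
    k = w.shape[2]
    pad = k // 2
    h, wd = x.shape[2], x.shape[3]
    xp = anp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), "constant")
    out = None
    for u in range(k):
        for v in range(k):
            t = anp.tensordot(
                xp[:, :, u : u + h, v : v + wd], w[:, :, u, v], axes=([1], [1])
            )  # (B, H, W, Cout)
            out = t if out is None else out + t
    out = out + b
    return anp.transpose(out, (0, 3, 1, 2))


def _relu(x):
    return anp.maximum(x, 0.0)


def _split_channels(x):
    p = x.shape[1] // 2
    return x[:, :p] + 1j * x[:, p:]


def _join_channels(z):
    return anp.concatenate([anp.real(z), anp.imag(z)], axis=1)


def frec_forward_arrays(x_zf, y, mask, weights, cfg: ReconNetConfig):
    """Unrolled reconstruction on raw arrays.

    x_zf: (B, 2P, H, W) real; y: (B, P, H, W) complex; mask: (B, P, H, W).
    Returns (B, 2P, H, W) real.
    """
    x = x_zf
    for layers in weights:
        h = x
        for i, (w, b) in enumerate(layers):
            h = conv2d_same(h, w, b)
            if i < len(layers) - 1:
                h = _relu(h)
        x = x + h  # residual denoiser
        k = fft2c(_split_channels(x))
        k = dc_arrays(k, y, mask, cfg.dc_weight)
        x = _join_channels(ifft2c(k))
    return x


def fmap_forward_arrays(x, weights, cfg: MapNetConfig):
    """Pixel-wise FCNN on (B, 2P, H, W) real channels -> (B, 3, H, W).

    Each pixel's vector (real parts then imaginary parts, echo order) is
    mapped independently; the T2 output channel is
    t2_min + (t2_max - t2_min) * sigmoid(z).
    """
    bsz, c2, h, w = x.shape
    v = anp.reshape(anp.transpose(x, (0, 2, 3, 1)), (bsz * h * w, c2))
    if cfg.normalize_input:
        p = c2 // 2
        z1 = v[:, :1] + 1j * v[:, p : p + 1]
        mag = anp.abs(z1) + 1e-6
        phase = anp.angle(z1)
        v = anp.concatenate([v / mag, mag, phase], axis=1)
    v = to_f32(v)
    for i, (wgt, b) in enumerate(weights):
        v = anp.dot(v, wgt) + b
        if i < len(weights) - 1:
            v = _relu(v)
    v = to_f64(v)
    t2 = cfg.t2_min + (cfg.t2_max - cfg.t2_min) / (1.0 + anp.exp(-v[:, 0]))
    out = anp.concatenate([t2[:, None], v[:, 1:3]], axis=1)
    return anp.transpose(anp.reshape(out, (bsz, h, w, 3)), (0, 3, 1, 2))


# ------------------------------------------------------- container wrappers


def frec_forward(
    x_zf: MultiContrastImage,
    y: KSpaceSet,
    masks: SamplingMaskSet,
    weights,
    cfg: ReconNetConfig,
) -> MultiContrastImage:
    """x_rec = f_rec(E^H y): unrolled denoise + data-consistency cascades."""
    if x_zf.n_echoes != y.schedule.n_echoes:
        raise ValueError("echo counts disagree")
    if weights and weights[0][0][0].shape[1] != 2 * x_zf.n_echoes:
        raise ValueError("weights built for a different echo count")
    xc = x_zf.to_channels()[None].astype(np.float64)
    out = frec_forward_arrays(
        xc, y.data[None], masks.masks[None], weights, cfg
    )
    return MultiContrastImage.from_channels(
        np.asarray(out)[0].astype(float), x_zf.schedule
    )


def fmap_forward(
    x_rec: MultiContrastImage, weights, cfg: MapNetConfig
) -> ParameterMaps:
    """p_rec = f_map(x_rec), applied independently per pixel."""
    expected = cfg.input_width(x_rec.n_echoes)
    if weights[0][0].shape[0] != expected:
        raise ValueError("weights built for a different echo count")
    xc = x_rec.to_channels()[None].astype(np.float64)
    if not np.all(np.isfinite(xc)):
        raise ValueError("non-finite inputs to the mapping network")
    out = np.asarray(fmap_forward_arrays(xc, weights, cfg))[0]
    return ParameterMaps.from_stack(out.astype(float))


def qdcnn_forward(
    y: KSpaceSet,
    masks: SamplingMaskSet,
    weights: Dict[str, list],
    recon_cfg: ReconNetConfig,
    map_cfg: MapNetConfig,
) -> Tuple[MultiContrastImage, ParameterMaps]:
    """Full pipeline: zero-fill -> f_rec -> f_map; returns both stages."""
    x_zf = zero_fill(y)
    x_rec = frec_forward(x_zf, y, masks, weights["frec"], recon_cfg)
    p_rec = fmap_forward(x_rec, weights["fmap"], map_cfg)
    return x_rec, p_rec


# ------------------------------------------------------------- checkpoints


def save_checkpoint(
    path: Path,
    weights: Dict[str, list],
    recon_cfg: Optional[ReconNetConfig] = None,
    map_cfg: Optional[MapNetConfig] = None,
    extra: Optional[dict] = None,
) -> None:
    """Flat .npz checkpoint with the configs embedded as JSON."""
    arrays = {}

    def _flatten(obj, prefix):
        if isinstance(obj, np.ndarray):
            arrays[prefix] = obj
        elif isinstance(obj, (list, tuple)):
            for i, o in enumerate(obj):
                _flatten(o, f"{prefix}.{i}")
        elif isinstance(obj, dict):
            for k, o in obj.items():
                _flatten(o, f"{prefix}.{k}")
        else:
            raise TypeError(type(obj))

    _flatten(weights, "w")
    meta = {
        "recon_cfg": _cfg_dict(recon_cfg),
        "map_cfg": _cfg_dict(map_cfg),
        "extra": extra or {},
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def _cfg_dict(cfg):
    if cfg is None:
        return None
    d = asdict(cfg)
    return {k: (None if isinstance(v, float) and np.isinf(v) else v) for k, v in d.items()}


def load_checkpoint(path: Path):
    """Returns (weights, meta dict)."""
    npz = np.load(path)
    meta = json.loads(bytes(npz["__meta__"]).decode())

    tree: dict = {}
    for key in npz.files:
        if key == "__meta__":
            continue
        parts = key.split(".")[1:]
        node = tree
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = npz[key]

    def _unflatten(node):
        if isinstance(node, np.ndarray):
            return node
        keys = list(node)
        if all(k.isdigit() for k in keys):
            return [
                _unflatten(node[k]) for k in sorted(keys, key=int)
            ]
        return {k: _unflatten(v) for k, v in node.items()}

    return _unflatten(tree), meta
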