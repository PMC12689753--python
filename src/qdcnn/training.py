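"""Training: the three-loss objective, mapping-module pretraining, and the
end-to-end loop with early stopping and per-batch mask refresh.

The total objective is

    L_total = lambda_r * L_r + lambda_p * L_p + lambda_dc * L_dc

with L_r the squared error between ground-truth and reconstructed
multi-contrast images, L_p the squared error between ground-truth and
predicted parameter maps (three channels jointly), and L_dc the squared
error between the measured k-space data and the encoded signal-model
prediction from the estimated maps.  By default each term is the literal
squared L2 norm (per batch element), the convention the default lambda
weights are calibrated for; the relative weighting of the three terms is
then independent of image size.  A mean-over-elements reduction is
available as an option.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad

from .encoding import fft2c, ifft2c, make_mask_set
from .networks import (
    MapNetConfig,
    ReconNetConfig,
    fmap_forward_arrays,
    frec_forward_arrays,
    init_fmap_weights,
    init_frec_weights,
)
from .phantom import CaseRecord
from .sigmodel import EchoSchedule

__all__ = [
    "LossRecord",
    "TrainConfig",
    "PretrainConfig",
    "compute_losses",
    "pretrain_fmap",
    "train_e2e",
    "train_variant",
]

METHODS = ("A", "C", "D")


@dataclass(frozen=True)
class LossRecord:
    """The three loss terms and their lambda-weighted total."""

    l_r: float
    l_p: float
    l_dc: float
    l_total: float

    def __post_init__(self) -> None:
        if min(self.l_r, self.l_p, self.l_dc) < 0:
            raise ValueError("losses must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the end-to-end optimization."""

    lambda_r: float = 1.0
    lambda_p: float = 1e-2
    lambda_dc: float = 1e-6
    lr: float = 1e-4
    patience: int = 10
    batch_size: int = 4
    max_epochs: int = 30
    seed: int = 0
    refresh_masks_per_batch: bool = True
    # "sum" is the literal squared-norm the lambda defaults were calibrated
    # for (the relative loss weights are then resolution-independent);
    # "mean" divides each term by its element count instead.
    reduction: str = "sum"

    def __post_init__(self) -> None:
        if min(self.lambda_r, self.lambda_p, self.lambda_dc) < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Training budget paired with the desk-scale dataset/network."""
        kw = dict(max_epochs=30, batch_size=4)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class PretrainConfig:
    """Supervised dictionary regression for the mapping network.

    Decay curves are drawn with T2 ~ U[10, 2500] ms, |S0| ~ U[0.05, 1] and
    phase ~ U[0, 2pi); ``snr_db = None`` trains on noiseless curves.
    """

    steps: int = 25000
    batch_size: int = 512
    lr: float = 2e-3
    snr_db: Optional[float] = None
    t2_range: Tuple[float, float] = (10.0, 2500.0)
    s0_range: Tuple[float, float] = (0.05, 1.0)
    t2_loss_scale: float = 150.0  # ms; balances the T2 and S0 channels
    seed: int = 0


# ------------------------------------------------------------------ pytree


def tree_map(f, *trees):
    t0 = trees[0]
    if isinstance(t0, np.ndarray) or np.isscalar(t0):
        return f(*trees)
    if isinstance(t0, (list, tuple)):
        return [tree_map(f, *parts) for parts in zip(*trees)]
    if isinstance(t0, dict):
        return {k: tree_map(f, *(t[k] for t in trees)) for k in t0}
    raise TypeError(type(t0))


class Adam:
    """Plain Adam on nested weight structures."""

    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, weights, grads):
        if self.m is None:
            self.m = tree_map(np.zeros_like, weights)
            self.v = tree_map(np.zeros_like, weights)
        self.t += 1
        self.m = tree_map(lambda m, g: self.b1 * m + (1 - self.b1) * g, self.m, grads)
        self.v = tree_map(lambda v, g: self.b2 * v + (1 - self.b2) * g * g, self.v, grads)
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        return tree_map(
            lambda w, m, v: w - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps),
            weights,
            self.m,
            self.v,
        )


# ------------------------------------------------------------------ losses


def _model_signal(p_rec, tes):
    """Differentiable signal model on (B, 3, H, W) maps -> (B, P, H, W)."""
    t2 = p_rec[:, 0]
    s0 = p_rec[:, 1] + 1j * p_rec[:, 2]
    safe_t2 = anp.where(t2 > 0, t2, np.inf)
    decay = anp.exp(-tes[None, :, None, None] / safe_t2[:, None])
    return s0[:, None] * decay


def loss_terms_arrays(x_rec, p_rec, x_gt, p_gt, y, mask, tes, reduction="sum"):
    """(l_r, l_p, l_dc) squared-error terms.

    x_rec/x_gt: (B, 2P, H, W) real channels; p_rec/p_gt: (B, 3, H, W);
    y: (B, P, H, W) complex measured k-space supported on the mask.
    Any of x_rec / p_rec may be None (term reported as 0).

    ``reduction="sum"`` is the literal squared L2 norm (normalized by the
    batch size only, so values are comparable across batch sizes);
    ``"mean"`` averages over all elements of each term instead.
    """
    bsz = y.shape[0]

    def _reduce(sq, n_elem):
        total = anp.sum(sq) / bsz
        return total if reduction == "sum" else total * bsz / n_elem

    l_r = (
        _reduce((x_gt - x_rec) ** 2, x_gt.size) if x_rec is not None else 0.0
    )
    if p_rec is not None:
        l_p = _reduce((p_gt - p_rec) ** 2, p_gt.size)
        k_model = fft2c(_model_signal(p_rec, tes)) * mask
        d = y - k_model
        l_dc = _reduce(anp.real(d * anp.conj(d)), y.size)
    else:
        l_p = 0.0
        l_dc = 0.0
    return l_r, l_p, l_dc


def compute_losses(
    x_rec,
    p_rec,
    x_gt,
    p_gt,
    y,
    masks,
    schedule: EchoSchedule,
    lambdas: Tuple[float, float, float] = (1.0, 1e-2, 1e-6),
    reduction: str = "sum",
) -> LossRecord:
    """Container-level loss evaluation; see :func:`loss_terms_arrays`.

    Accepts the package's domain containers (MultiContrastImage,
    ParameterMaps, KSpaceSet, SamplingMaskSet).
    """
    lr_w, lp_w, ldc_w = lambdas
    if min(lr_w, lp_w, ldc_w) < 0:
        raise ValueError("lambda weights must be non-negative")
    x_rec_ch = x_rec.to_channels()[None] if x_rec is not None else None
    x_gt_ch = x_gt.to_channels()[None]
    p_rec_a = p_rec.stack()[None] if p_rec is not None else None
    p_gt_a = p_gt.stack()[None]
    l_r, l_p, l_dc = loss_terms_arrays(
        x_rec_ch, p_rec_a, x_gt_ch, p_gt_a, y.data[None], masks.masks[None],
        schedule.tes, reduction=reduction,
    )
    l_r, l_p, l_dc = float(l_r), float(l_p), float(l_dc)
    return LossRecord(
        l_r=l_r,
        l_p=l_p,
        l_dc=l_dc,
        l_total=lr_w * l_r + lp_w * l_p + ldc_w * l_dc,
    )


# -------------------------------------------------------------- pretraining


def _sample_dictionary(rng, n, tes, cfg: PretrainConfig):
    t2 = rng.uniform(*cfg.t2_range, size=n)
    mag = rng.uniform(*cfg.s0_range, size=n)
    phase = rng.uniform(0.0, 2 * np.pi, size=n)
    s0 = mag * np.exp(1j * phase)
    curves = s0[:, None] * np.exp(-tes[None, :] / t2[:, None])
    if cfg.snr_db is not None:
        sigma = mag * 10.0 ** (-cfg.snr_db / 20.0)
        noise = (
            rng.standard_normal(curves.shape)
            + 1j * rng.standard_normal(curves.shape)
        ) / np.sqrt(2.0)
        curves = curves + sigma[:, None] * noise
    x = np.concatenate([curves.real, curves.imag], axis=1)  # (N, 2P)
    p = np.stack([t2, s0.real, s0.imag], axis=1)  # (N, 3)
    return x, p


def _fmap_on_vectors(v, weights, cfg: MapNetConfig):
    # route through the image forward with a 1-pixel-high layout
    n, c2 = v.shape
    x = anp.reshape(anp.transpose(v), (1, c2, 1, n))
    out = fmap_forward_arrays(x, weights, cfg)
    return anp.transpose(anp.reshape(out, (3, n)))


def pretrain_fmap(
    map_cfg: MapNetConfig,
    schedule: EchoSchedule,
    cfg: PretrainConfig = PretrainConfig(),
) -> Tuple[list, pd.DataFrame]:
    """Train the mapping FCNN on a synthetic decay-curve dictionary.

    Minimizes the parameter loss L_p (mean squared error over the three
    output channels) with Adam; the learning rate is stepped down twice.
    Returns (weights, history).
    """
    rng = np.random.default_rng(cfg.seed)
    weights = init_fmap_weights(map_cfg, schedule.n_echoes)
    tes = schedule.tes

    scale = np.array([cfg.t2_loss_scale, 1.0, 1.0])

    def loss(w, xb, pb):
        # channel-balanced squared parameter error: without the T2 scaling
        # the ms-magnitude T2 channel starves the O(1) S0 channels
        pred = _fmap_on_vectors(xb, w, map_cfg)
        return anp.mean(((pred - pb) / scale) ** 2)

    lg = value_and_grad(loss)
    opt = Adam(cfg.lr)
    history = []
    for step in range(cfg.steps):
        if step == int(0.6 * cfg.steps) or step == int(0.85 * cfg.steps):
            opt.lr *= 0.3
        xb, pb = _sample_dictionary(rng, cfg.batch_size, tes, cfg)
        val, grads = lg(weights, xb, pb)
        weights = opt.step(weights, grads)
        if step % 200 == 0 or step == cfg.steps - 1:
            history.append({"step": step, "l_p": float(val)})
    return weights, pd.DataFrame(history)


# ------------------------------------------------------------- e2e training


def _stack_slices(cases: Sequence[CaseRecord], split: str):
    xs, ps, ks, us, ms = [], [], [], [], []
    for rec in cases:
        if rec.split != split:
            continue
        for s in range(rec.n_slices):
            xs.append(rec.fs_images[s].to_channels())
            ps.append(rec.gt_maps[s].stack())
            ks.append(rec.fs_kspace_noisy[s].data)
            us.append(rec.us_kspace[s].data)
            ms.append(rec.mask_sets[s].masks)
    if not xs:
        raise ValueError(f"no slices in split {split!r}")
    return (
        np.stack(xs),
        np.stack(ps),
        np.stack(ks),
        np.stack(us),
        np.stack(ms).astype(float),
    )


def _forward_losses(weights, frozen_fmap, x_zf, y, mask, x_gt, p_gt, tes,
                    recon_cfg, map_cfg, method, reduction="sum"):
    x_rec = frec_forward_arrays(x_zf, y, mask, weights["frec"], recon_cfg)
    if method == "C":
        p_rec = None
    elif method == "D":
        p_rec = fmap_forward_arrays(x_rec, frozen_fmap, map_cfg)
    else:
        p_rec = fmap_forward_arrays(x_rec, weights["fmap"], map_cfg)
    return loss_terms_arrays(
        x_rec, p_rec, x_gt, p_gt, y, mask, tes, reduction=reduction
    )


def validation_loss(
    weights, frozen_fmap, val_data, tes, recon_cfg, map_cfg, train_cfg, method
) -> LossRecord:
    """l_total on the validation split with its fixed stored masks."""
    x_gt, p_gt, _, us, mask = val_data
    terms = np.zeros(3)
    n = x_gt.shape[0]
    bs = max(1, train_cfg.batch_size)
    for i in range(0, n, bs):
        sl = slice(i, min(i + bs, n))
        y = us[sl]
        x_zf = np.concatenate(
            [ifft2c(y).real, ifft2c(y).imag], axis=1
        )
        out = _forward_losses(
            weights, frozen_fmap, x_zf, y, mask[sl], x_gt[sl], p_gt[sl],
            tes, recon_cfg, map_cfg, method, train_cfg.reduction,
        )
        terms += (sl.stop - sl.start) * np.array([float(t) for t in out])
    terms /= n
    l_r, l_p, l_dc = terms
    total = (
        train_cfg.lambda_r * l_r
        + train_cfg.lambda_p * l_p
        + train_cfg.lambda_dc * l_dc
    )
    return LossRecord(l_r=l_r, l_p=l_p, l_dc=l_dc, l_total=total)


def train_e2e(
    cases: Sequence[CaseRecord],
    recon_cfg: ReconNetConfig,
    map_cfg: MapNetConfig,
    train_cfg: TrainConfig,
    fmap_init: Optional[list] = None,
    method: str = "A",
) -> Tuple[Dict[str, list], pd.DataFrame]:
    """Joint Adam minimization of the lambda-weighted three-loss objective.

    Variant A trains f_rec and the (pretrained-initialized) f_map jointly
    with all three losses; C trains f_rec alone on L_r; D trains f_rec with
    all three losses where the maps inside L_p/L_dc come from the frozen
    pretrained f_map.  With ``refresh_masks_per_batch`` a fresh mask set
    (new seed per batch) regenerates the undersampled inputs from the stored
    noisy fully sampled k-space.  Stops when the validation l_total has not
    improved for ``patience`` consecutive epochs; returns the best weights.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    schedule = cases[0].fs_images[0].schedule
    tes = schedule.tes
    train_data = _stack_slices(cases, "train")
    val_data = _stack_slices(cases, "val")
    x_gt, p_gt, fs_noisy, us, masks = train_data
    n, _, h, w = x_gt.shape
    p = schedule.n_echoes

    rng = np.random.default_rng(train_cfg.seed)
    frec_w = init_frec_weights(recon_cfg, p)
    if fmap_init is None:
        fmap_init = init_fmap_weights(map_cfg, p)
    frozen_fmap = copy.deepcopy(fmap_init)
    if method == "C":
        weights = {"frec": frec_w}
    elif method == "D":
        weights = {"frec": frec_w}
    else:
        weights = {"frec": frec_w, "fmap": copy.deepcopy(fmap_init)}

    lam = (train_cfg.lambda_r, train_cfg.lambda_p, train_cfg.lambda_dc)

    def objective(w, x_zf, y, mask, xb, pb):
        l_r, l_p, l_dc = _forward_losses(
            w, frozen_fmap, x_zf, y, mask, xb, pb, tes, recon_cfg, map_cfg,
            method, train_cfg.reduction,
        )
        return lam[0] * l_r + lam[1] * l_p + lam[2] * l_dc

    obj_grad = value_and_grad(objective)
    opt = Adam(train_cfg.lr)
    history = []
    best_val = np.inf
    best_weights = copy.deepcopy(weights)
    stale = 0
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, train_cfg.batch_size):
            idx = order[i : i + train_cfg.batch_size]
            if train_cfg.refresh_masks_per_batch:
                mset = make_mask_set(
                    h, w, p, af=_dataset_af(cases),
                    seed=int(rng.integers(2**31)),
                )
                mask_b = np.broadcast_to(
                    mset.masks.astype(float), (len(idx), p, h, w)
                )
                y = fs_noisy[idx] * mask_b
            else:
                mask_b = masks[idx]
                y = us[idx]
            zf = ifft2c(y)
            x_zf = np.concatenate([zf.real, zf.imag], axis=1)
            val, grads = obj_grad(weights, x_zf, y, mask_b, x_gt[idx], p_gt[idx])
            weights = opt.step(weights, grads)
            epoch_loss += float(val) * len(idx)
        epoch_loss /= n
        vrec = validation_loss(
            weights, frozen_fmap, val_data, tes, recon_cfg, map_cfg,
            train_cfg, method,
        )
        history.append(
            {
                "epoch": epoch,
                "train_l_total": epoch_loss,
                "val_l_r": vrec.l_r,
                "val_l_p": vrec.l_p,
                "val_l_dc": vrec.l_dc,
                "val_l_total": vrec.l_total,
            }
        )
        if vrec.l_total < best_val:
            best_val = vrec.l_total
            best_weights = copy.deepcopy(weights)
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
    if method in ("C", "D"):
        best_weights = {"frec": best_weights["frec"], "fmap": frozen_fmap}
    return best_weights, pd.DataFrame(history)


def _dataset_af(cases: Sequence[CaseRecord]) -> float:
    return cases[0].mask_sets[0].af


def train_variant(
    method_id: str,
    cases: Sequence[CaseRecord],
    recon_cfg: ReconNetConfig,
    map_cfg: MapNetConfig,
    train_cfg: TrainConfig,
    fmap_init: Optional[list] = None,
):
    """Train one of the compared models.

    A: full end-to-end model (all three losses, f_map trained).
    C: reconstruction network alone, image-space loss only (L_r);
       least-squares fitting replaces f_map at inference.
    D: reconstruction network trained with all three losses through the
       frozen pretrained f_map; least-squares fitting at inference.
    """
    if method_id not in METHODS:
        raise ValueError(f"unknown method {method_id!r}")
    cfg = train_cfg
    if method_id == "C":
        cfg = replace(train_cfg, lambda_p=0.0, lambda_dc=0.0)
    return train_e2e(
        cases, recon_cfg, map_cfg, cfg, fmap_init=fmap_init, method=method_id
    )
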