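"""Evaluation metrics: NRMSE over a region and PSNR.

NRMSE(x, y) = ||x - y||_{2,Phi} / ||x||_{2,Phi} with x the ground truth,
reported in percent.  PSNR = 10 log10(L^2 / MSE_Phi) with L the peak ground
truth intensity over Phi by default; a literal sum-of-squares variant (no
division by the pixel count) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .sigmodel import ParameterMaps

__all__ = ["EvalRegion", "nrmse", "psnr", "make_region", "summarize_nrmse"]


@dataclass(frozen=True)
class EvalRegion:
    """Binary evaluation region Phi."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("evaluation region is empty")
        object.__setattr__(self, "mask", m)


def _over(region: Optional[EvalRegion], arr: np.ndarray) -> np.ndarray:
    if region is None:
        return arr.ravel()
    return arr[region.mask]


def nrmse(x_gt: np.ndarray, y_est: np.ndarray, region: Optional[EvalRegion] = None) -> float:
    """Normalized RMSE as a fraction (multiply by 100 to report percent)."""
    x_gt = np.asarray(x_gt)
    y_est = np.asarray(y_est)
    if x_gt.shape != y_est.shape:
        raise ValueError("shapes disagree")
    x = _over(region, x_gt)
    y = _over(region, y_est)
    denom = np.linalg.norm(x)
    if denom == 0:
        raise ValueError("ground truth has zero norm over the region")
    return float(np.linalg.norm(x - y) / denom)


def psnr(
    x_gt: np.ndarray,
    y_est: np.ndarray,
    region: Optional[EvalRegion] = None,
    peak: Optional[float] = None,
    literal_norm: bool = False,
) -> float:
    """Peak signal-to-noise ratio in dB; identical inputs give +inf."""
    x_gt = np.asarray(x_gt)
    y_est = np.asarray(y_est)
    if x_gt.shape != y_est.shape:
        raise ValueError("shapes disagree")
    x = _over(region, x_gt)
    y = _over(region, y_est)
    if peak is None:
        peak = float(np.abs(x).max())
    err = np.abs(x - y) ** 2
    denom = err.sum() if literal_norm else err.mean()
    if denom == 0:
        return np.inf
    return float(10.0 * np.log10(peak**2 / denom))


def make_region(gt_maps: ParameterMaps, threshold: float = 0.05) -> EvalRegion:
    """Foreground region: |S0_gt| > threshold * max |S0_gt|."""
    mag = np.abs(gt_maps.s0)
    mask = mag > threshold * mag.max()
    if not mask.any():
        raise ValueError("empty evaluation region (all-background maps)")
    return EvalRegion(mask=mask)


def summarize_nrmse(rows: List[dict]) -> pd.DataFrame:
    """Aggregate per-slice NRMSE fractions into the tidy results table.

    ``rows`` entries: method, af, p, parameter, nrmse (fraction, per slice).
    Output columns: method, af, p, parameter, mean_nrmse_pct, sd_nrmse_pct,
    n_slices — mean and standard deviation over test slices, in percent.
    """
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["method", "af", "p", "parameter"], as_index=False)
        .agg(
            mean_nrmse_pct=("nrmse", lambda v: 100.0 * np.mean(v)),
            sd_nrmse_pct=("nrmse", lambda v: 100.0 * np.std(v, ddof=1) if len(v) > 1 else 0.0),
            n_slices=("nrmse", "size"),
        )
    )
    return out
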