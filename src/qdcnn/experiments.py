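"""Experiment orchestration: acceleration sweeps and echo-count sweeps.

Experiment 1 varies the acceleration factor (AF in {5, 10, 20}) at the full
16-echo schedule; Experiment 2 varies the number of echoes (P in {4, 8, 16})
at AF = 5.  Each (method, AF, P) cell trains its model (where needed) and
reports mean +- sd NRMSE of the T2 and S0 maps over the foreground region of
every test slice, as a tidy table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import KSpaceSet, make_mask_set, zero_fill
from .fitting import FitOptions, lsf_fit_image
from .metrics import make_region, nrmse, summarize_nrmse
from .networks import (
    MapNetConfig,
    ReconNetConfig,
    frec_forward,
    qdcnn_forward,
)
from .phantom import CaseRecord, DatasetConfig, build_dataset
from .sigmodel import EchoSchedule, MultiContrastImage, ParameterMaps
from .training import PretrainConfig, TrainConfig, pretrain_fmap, train_variant

__all__ = ["ExperimentPlan", "select_echo_subset", "run_experiment",
           "evaluate_method", "reconstruct_maps"]

NON_LEARNED = ("F",)


@dataclass(frozen=True)
class ExperimentPlan:
    """One experiment: which methods, AFs and echo counts, at what scale."""

    experiment_id: int
    methods: Sequence[str] = ("A", "C", "D", "F")
    afs: Sequence[float] = (5.0,)
    echo_counts: Sequence[int] = (16,)
    scale: str = "desk"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_id == 1 and tuple(self.echo_counts) != (16,):
            raise ValueError("experiment 1 fixes P = 16")
        if self.experiment_id == 2 and tuple(self.afs) != (5.0,):
            raise ValueError("experiment 2 fixes AF = 5")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")
        bad = set(self.methods) - {"A", "C", "D", "F"}
        if bad:
            raise ValueError(f"unsupported methods: {sorted(bad)}")

    @classmethod
    def experiment_1(cls, **kw) -> "ExperimentPlan":
        kw.setdefault("afs", (5.0, 10.0, 20.0))
        return cls(experiment_id=1, echo_counts=(16,), **kw)

    @classmethod
    def experiment_2(cls, **kw) -> "ExperimentPlan":
        kw.setdefault("echo_counts", (4, 8, 16))
        return cls(experiment_id=2, afs=(5.0,), **kw)


def select_echo_subset(schedule: EchoSchedule, p: int) -> np.ndarray:
    """Indices of an evenly strided echo subset covering the full TE range."""
    n = schedule.n_echoes
    if p > n:
        raise ValueError(f"cannot select {p} echoes from {n}")
    if p < 2:
        raise ValueError("need at least two echoes")
    return np.round(np.linspace(0, n - 1, p)).astype(int)


def _subset_case(rec: CaseRecord, idx: np.ndarray, af: float) -> CaseRecord:
    """Restrict a case to an echo subset and re-mask at the requested AF."""
    sched = rec.fs_images[0].schedule.subset(idx)
    p = len(idx)
    fs_images = [
        MultiContrastImage(data=im.data[idx], schedule=sched)
        for im in rec.fs_images
    ]
    fs_noisy = [
        KSpaceSet(data=k.data[idx], schedule=sched)
        for k in rec.fs_kspace_noisy
    ]
    mask_sets = []
    us = []
    for s, k in enumerate(fs_noisy):
        base = rec.mask_sets[s]
        h, w = k.data.shape[1:]
        mset = make_mask_set(
            h, w, p, af, center_lines=base.center_lines, seed=base.seed
        )
        mask_sets.append(mset)
        us.append(
            KSpaceSet(data=k.data * mset.masks, schedule=sched, masks=mset)
        )
    return CaseRecord(
        case_id=rec.case_id,
        split=rec.split,
        labels=rec.labels,
        gt_maps=rec.gt_maps,
        fs_images=fs_images,
        fs_kspace_noisy=fs_noisy,
        us_kspace=us,
        mask_sets=mask_sets,
        noise_seed=rec.noise_seed,
    )


def reconstruct_maps(
    method: str,
    y: KSpaceSet,
    weights: Optional[dict],
    recon_cfg: ReconNetConfig,
    map_cfg: MapNetConfig,
    fit_opts: FitOptions,
    foreground: Optional[np.ndarray] = None,
) -> ParameterMaps:
    """Run one method's inference pipeline on one undersampled slice."""
    if method == "F":
        x = zero_fill(y)
        return lsf_fit_image(x, fit_opts, foreground)
    if method in ("C", "D"):
        x_zf = zero_fill(y)
        x_rec = frec_forward(x_zf, y, y.masks, weights["frec"], recon_cfg)
        return lsf_fit_image(x_rec, fit_opts, foreground)
    if method == "A":
        _, p_rec = qdcnn_forward(y, y.masks, weights, recon_cfg, map_cfg)
        return p_rec
    raise ValueError(f"unknown method {method!r}")


def evaluate_method(
    method: str,
    cases: Sequence[CaseRecord],
    weights: Optional[dict],
    recon_cfg: ReconNetConfig,
    map_cfg: MapNetConfig,
    fit_opts: FitOptions = FitOptions(),
    region_threshold: float = 0.05,
) -> List[dict]:
    """Per-test-slice T2 and S0-magnitude NRMSE rows over the foreground."""
    rows = []
    for rec in cases:
        if rec.split != "test":
            continue
        for s in range(rec.n_slices):
            gt = rec.gt_maps[s]
            region = make_region(gt, threshold=region_threshold)
            y = rec.us_kspace[s]
            est = reconstruct_maps(
                method, y, weights, recon_cfg, map_cfg, fit_opts,
                foreground=region.mask,
            )
            af = rec.mask_sets[s].af
            p = y.schedule.n_echoes
            rows.append(
                dict(
                    method=method, af=af, p=p, parameter="T2",
                    case=rec.case_id, slice=s,
                    nrmse=nrmse(gt.t2, est.t2, region),
                )
            )
            rows.append(
                dict(
                    method=method, af=af, p=p, parameter="S0",
                    case=rec.case_id, slice=s,
                    nrmse=nrmse(np.abs(gt.s0), np.abs(est.s0), region),
                )
            )
    return rows


def _scale_configs(plan: ExperimentPlan):
    if plan.scale == "desk":
        data_cfg = DatasetConfig.desk(seed=plan.seed)
        recon_cfg = ReconNetConfig.desk()
        train_cfg = TrainConfig.desk(seed=plan.seed)
    else:
        data_cfg = DatasetConfig(seed=plan.seed)
        recon_cfg = ReconNetConfig()
        train_cfg = TrainConfig(seed=plan.seed, max_epochs=200)
    return data_cfg, recon_cfg, MapNetConfig(), train_cfg


def run_experiment(
    plan: ExperimentPlan,
    out_dir: Optional[Path] = None,
    pretrain_cfg: PretrainConfig = PretrainConfig(),
) -> pd.DataFrame:
    """Run every (method, AF, P) cell of the plan and aggregate NRMSE.

    Learned methods are trained once per cell (per-batch mask refresh at the
    cell's AF); the zero-fill baseline needs no training.  Results are the
    tidy mean +- sd table; with ``out_dir`` set, the table, a manifest and
    example reconstructed/error maps (error scaled x10) are written out.
    """
    data_cfg, recon_cfg, map_cfg, train_cfg = _scale_configs(plan)
    cases, manifest = build_dataset(data_cfg)
    fmap_w = None
    needs_fmap = set(plan.methods) - set(NON_LEARNED) != set()
    if needs_fmap:
        fmap_w, _ = pretrain_fmap(
            map_cfg, data_cfg.schedule,
            replace(pretrain_cfg, seed=plan.seed),
        )
    all_rows = []
    cell_info = {}
    for af in plan.afs:
        for p in plan.echo_counts:
            idx = select_echo_subset(data_cfg.schedule, p)
            sub = [_subset_case(rec, idx, af) for rec in cases]
            sub_sched = data_cfg.schedule.subset(idx)
            sub_fmap = fmap_w
            if needs_fmap and p != data_cfg.schedule.n_echoes:
                sub_fmap, _ = pretrain_fmap(
                    map_cfg, sub_sched, replace(pretrain_cfg, seed=plan.seed)
                )
            for method in plan.methods:
                weights = None
                if method not in NON_LEARNED:
                    weights, hist = train_variant(
                        method, sub, recon_cfg, map_cfg, train_cfg,
                        fmap_init=sub_fmap,
                    )
                    cell_info[f"{method}_af{af}_p{p}"] = {
                        "epochs": int(len(hist)),
                        "best_val_l_total": float(hist["val_l_total"].min()),
                        "lambda_p": train_cfg.lambda_p if method != "C" else 0.0,
                        "lambda_dc": train_cfg.lambda_dc if method != "C" else 0.0,
                    }
                all_rows.extend(
                    evaluate_method(
                        method, sub, weights, recon_cfg, map_cfg
                    )
                )
                if out_dir is not None:
                    _export_method_example(
                        method, sub, weights, recon_cfg, map_cfg,
                        Path(out_dir), af, p,
                    )
    table = summarize_nrmse(all_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "results.csv", index=False)
        manifest["plan"] = {
            "experiment_id": plan.experiment_id,
            "methods": list(plan.methods),
            "afs": list(map(float, plan.afs)),
            "echo_counts": list(map(int, plan.echo_counts)),
            "scale": plan.scale,
            "seed": plan.seed,
        }
        manifest["cells"] = cell_info
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _export_example_maps(plan, cases, table, out_dir)
    return table


def _export_example_maps(plan, cases, table, out_dir: Path) -> None:
    """NIfTI export of one test case's GT maps for figure-style inspection."""
    import nibabel as nib

    test = [c for c in cases if c.split == "test"]
    if not test:
        return
    rec = test[0]
    t2_vol = np.stack([m.t2 for m in rec.gt_maps], axis=-1)
    s0_vol = np.stack([np.abs(m.s0) for m in rec.gt_maps], axis=-1)
    nib.save(nib.Nifti1Image(t2_vol, np.eye(4)), out_dir / "gt_t2_ms.nii.gz")
    nib.save(nib.Nifti1Image(s0_vol, np.eye(4)), out_dir / "gt_s0_mag.nii.gz")


def _export_method_example(
    method, cases, weights, recon_cfg, map_cfg, out_dir: Path, af, p
) -> None:
    """Reconstructed T2/S0 maps and x10-amplified error maps for the central
    slice of the first test case."""
    import nibabel as nib

    test = [c for c in cases if c.split == "test"]
    if not test:
        return
    rec = test[0]
    s = rec.n_slices // 2
    gt = rec.gt_maps[s]
    region = make_region(gt)
    est = reconstruct_maps(
        method, rec.us_kspace[s], weights, recon_cfg, map_cfg, FitOptions(),
        foreground=region.mask,
    )
    tag = f"{method}_af{int(af)}_p{int(p)}"
    for name, est_map, gt_map in (
        ("t2_ms", est.t2, gt.t2),
        ("s0_mag", np.abs(est.s0), np.abs(gt.s0)),
    ):
        nib.save(
            nib.Nifti1Image(est_map[..., None], np.eye(4)),
            out_dir / f"{tag}_{name}.nii.gz",
        )
        err10 = 10.0 * np.abs(est_map - gt_map) * region.mask
        nib.save(
            nib.Nifti1Image(err10[..., None], np.eye(4)),
            out_dir / f"{tag}_{name}_err_x10.nii.gz",
        )
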