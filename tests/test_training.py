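"""Loss algebra, pretraining and end-to-end training mechanics."""

from dataclasses import replace

import numpy as np
import pytest

from qdcnn.encoding import encode, make_mask_set
from qdcnn.networks import MapNetConfig, ReconNetConfig, init_fmap_weights
from qdcnn.phantom import DatasetConfig, build_dataset
from qdcnn.sigmodel import ParameterMaps, synthesize_signal
from qdcnn.training import (
    LossRecord,
    PretrainConfig,
    TrainConfig,
    compute_losses,
    pretrain_fmap,
    train_e2e,
    train_variant,
)


@pytest.fixture(scope="module")
def consistent_problem(schedule16):
    """GT maps, their noiseless images and exactly consistent k-space."""
    rng = np.random.default_rng(11)
    h = w = 16
    maps = ParameterMaps(
        t2=rng.uniform(50, 300, size=(h, w)),
        s0_re=rng.uniform(0.2, 1.0, size=(h, w)),
        s0_im=np.zeros((h, w)),
    )
    img = synthesize_signal(maps, schedule16)
    masks = make_mask_set(h, w, 16, 2.0, seed=3)
    y = encode(img, masks)
    return maps, img, masks, y


class TestLossAlgebra:
    def test_zero_at_exact_consistency(self, consistent_problem, schedule16):
        maps, img, masks, y = consistent_problem
        rec = compute_losses(img, maps, img, maps, y, masks, schedule16)
        assert rec.l_r == rec.l_p == rec.l_dc == 0.0
        assert rec.l_total == 0.0

    def test_default_lambda_total(self):
        """Unit sub-losses weighted by (1, 1e-2, 1e-6) total 1.010001."""
        rec = LossRecord(l_r=1.0, l_p=1.0, l_dc=1.0, l_total=0.0)
        total = 1.0 * rec.l_r + 1e-2 * rec.l_p + 1e-6 * rec.l_dc
        assert total == pytest.approx(1.010001, abs=1e-12)

    def test_lambda_linearity(self, consistent_problem, schedule16):
        maps, img, masks, y = consistent_problem
        rng = np.random.default_rng(5)
        perturbed = ParameterMaps(
            t2=maps.t2 * 1.2,
            s0_re=maps.s0_re + 0.1,
            s0_im=maps.s0_im,
        )
        r1 = compute_losses(
            img, perturbed, img, maps, y, masks, schedule16, (1.0, 1e-2, 1e-6)
        )
        r2 = compute_losses(
            img, perturbed, img, maps, y, masks, schedule16, (1.0, 1e-2, 2e-6)
        )
        # doubling lambda_dc doubles exactly its contribution
        assert r2.l_total - r1.l_total == pytest.approx(1e-6 * r1.l_dc, rel=1e-9)

    def test_ldc_blind_to_off_mask_model_components(
        self, consistent_problem, schedule16
    ):
        """L_dc equals the error restricted to the sampling set: model
        k-space components off the mask never contribute."""
        from qdcnn.encoding import fft2c
        from qdcnn.training import loss_terms_arrays

        maps, img, masks, y = consistent_problem
        rng = np.random.default_rng(5)
        wrong = ParameterMaps(
            t2=maps.t2 * rng.uniform(0.7, 1.3, size=maps.shape),
            s0_re=maps.s0_re + 0.05,
            s0_im=maps.s0_im,
        )
        p = wrong.stack()[None]
        x = img.to_channels()[None]
        ldc = loss_terms_arrays(
            x, p, x, maps.stack()[None], y.data[None], masks.masks[None],
            schedule16.tes,
        )[2]
        k_model = fft2c(synthesize_signal(wrong, schedule16).data)
        d_on = (y.data - k_model) * masks.masks  # off-mask differences removed
        expected = np.sum(np.abs(d_on) ** 2)
        assert float(ldc) == pytest.approx(expected, rel=1e-12)

    def test_negative_lambda_rejected(self, consistent_problem, schedule16):
        maps, img, masks, y = consistent_problem
        with pytest.raises(ValueError):
            compute_losses(
                img, maps, img, maps, y, masks, schedule16, (-1.0, 0.0, 0.0)
            )


class TestPretrainFmap:
    def test_loss_descends_and_is_deterministic(self, schedule16):
        cfg = PretrainConfig(steps=300, batch_size=64, seed=9)
        mcfg = MapNetConfig(hidden_layers=2, hidden_units=32)
        w1, h1 = pretrain_fmap(mcfg, schedule16, cfg)
        w2, h2 = pretrain_fmap(mcfg, schedule16, cfg)
        assert h1["l_p"].iloc[-1] < h1["l_p"].iloc[0]
        np.testing.assert_array_equal(w1[0][0], w2[0][0])
        np.testing.assert_array_equal(w1[-1][1], w2[-1][1])


@pytest.fixture(scope="module")
def micro_dataset():
    cfg = DatasetConfig(
        n_cases=3, n_train=1, n_val=1, n_test=1, n_slices=2,
        h=32, w=32, af=3.0, seed=21,
    )
    cases, _ = build_dataset(cfg)
    return cases


@pytest.fixture(scope="module")
def micro_cfgs():
    return (
        ReconNetConfig(n_cascades=1, convs_per_cascade=2, filters=8),
        MapNetConfig(hidden_layers=2, hidden_units=32),
    )


class TestTrainE2E:
    def test_early_stopping_exact_patience(
        self, micro_dataset, micro_cfgs, monkeypatch
    ):
        """A validation loss that never improves halts training after
        exactly `patience` further epochs."""
        import qdcnn.training as tr

        calls = []

        def rigged(*args, **kwargs):
            calls.append(1)
            return LossRecord(l_r=1.0, l_p=1.0, l_dc=1.0, l_total=1.0)

        monkeypatch.setattr(tr, "validation_loss", rigged)
        rcfg, mcfg = micro_cfgs
        tcfg = TrainConfig(
            patience=10, max_epochs=100, batch_size=2, seed=0,
            refresh_masks_per_batch=False,
        )
        _, history = tr.train_e2e(micro_dataset, rcfg, mcfg, tcfg)
        assert len(history) == 11  # epoch 0 sets best; 10 stale epochs follow

    def test_returned_weights_hit_min_val_loss(self, micro_dataset, micro_cfgs):
        import qdcnn.training as tr

        rcfg, mcfg = micro_cfgs
        tcfg = TrainConfig(
            patience=3, max_epochs=4, batch_size=2, seed=1,
            refresh_masks_per_batch=False,
        )
        weights, history = tr.train_e2e(micro_dataset, rcfg, mcfg, tcfg)
        sched = micro_dataset[0].fs_images[0].schedule
        val_data = tr._stack_slices(micro_dataset, "val")
        rec = tr.validation_loss(
            weights, weights["fmap"], val_data, sched.tes, rcfg, mcfg, tcfg, "A"
        )
        assert rec.l_total == pytest.approx(history["val_l_total"].min(), rel=1e-9)

    def test_variant_c_total_is_lr_only(self, micro_dataset, micro_cfgs):
        rcfg, mcfg = micro_cfgs
        tcfg = TrainConfig(max_epochs=1, batch_size=2, seed=2,
                           refresh_masks_per_batch=False)
        _, hist = train_variant("C", micro_dataset, rcfg, mcfg, tcfg)
        row = hist.iloc[0]
        assert row["val_l_total"] == pytest.approx(row["val_l_r"], rel=1e-12)
        assert row["val_l_p"] == 0.0 and row["val_l_dc"] == 0.0

    def test_variants_diverge_from_same_seed(self, micro_dataset, micro_cfgs):
        # several Adam steps: the very first step is +-lr elementwise and
        # can coincide across variants whose gradients share signs
        rcfg, mcfg = micro_cfgs
        tcfg = TrainConfig(max_epochs=3, batch_size=1, seed=3,
                           refresh_masks_per_batch=False)
        fmap_init = init_fmap_weights(mcfg, 16)
        wa, _ = train_variant("A", micro_dataset, rcfg, mcfg, tcfg, fmap_init)
        wc, _ = train_variant("C", micro_dataset, rcfg, mcfg, tcfg, fmap_init)
        diff = np.abs(
            np.asarray(wa["frec"][0][0][0]) - np.asarray(wc["frec"][0][0][0])
        ).max()
        assert diff > 0

    def test_unknown_method_rejected(self, micro_dataset, micro_cfgs):
        rcfg, mcfg = micro_cfgs
        with pytest.raises(ValueError):
            train_variant("B", micro_dataset, rcfg, mcfg, TrainConfig())

    def test_training_improves_objective(self, micro_dataset, micro_cfgs):
        import qdcnn.training as tr

        rcfg, mcfg = micro_cfgs
        sched = micro_dataset[0].fs_images[0].schedule
        tcfg = TrainConfig(
            max_epochs=5, batch_size=2, seed=4, lr=1e-3,
            refresh_masks_per_batch=False,
        )
        fmap_init, _ = pretrain_fmap(
            mcfg, sched, PretrainConfig(steps=200, batch_size=64, seed=0)
        )
        from qdcnn.networks import init_frec_weights

        val_data = tr._stack_slices(micro_dataset, "val")
        w0 = {
            "frec": init_frec_weights(rcfg, 16),
            "fmap": [list(l) for l in fmap_init],
        }
        before = tr.validation_loss(
            w0, fmap_init, val_data, sched.tes, rcfg, mcfg, tcfg, "A"
        )
        weights, hist = tr.train_e2e(
            micro_dataset, rcfg, mcfg, tcfg, fmap_init=fmap_init
        )
        assert hist["val_l_total"].min() < before.l_total

    def test_loss_invariant_to_slice_order(self, micro_dataset, micro_cfgs, schedule16):
        import qdcnn.training as tr

        rcfg, mcfg = micro_cfgs
        tcfg = TrainConfig(batch_size=2, refresh_masks_per_batch=False)
        fmap_w = init_fmap_weights(mcfg, 16)
        from qdcnn.networks import init_frec_weights

        weights = {"frec": init_frec_weights(rcfg, 16), "fmap": fmap_w}
        val = tr._stack_slices(micro_dataset, "val")
        rec1 = tr.validation_loss(
            weights, fmap_w, val, schedule16.tes, rcfg, mcfg, tcfg, "A"
        )
        reversed_val = tuple(a[::-1].copy() for a in val)
        rec2 = tr.validation_loss(
            weights, fmap_w, reversed_val, schedule16.tes, rcfg, mcfg, tcfg, "A"
        )
        assert rec1.l_total == pytest.approx(rec2.l_total, rel=1e-12)
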