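"""Unrolled reconstruction network and pixel-wise mapping network tests."""

import numpy as np
import pytest

from qdcnn.encoding import encode, make_mask_set, zero_fill
from qdcnn.networks import (
    MapNetConfig,
    ReconNetConfig,
    fmap_forward,
    frec_forward,
    init_fmap_weights,
    init_frec_weights,
    load_checkpoint,
    n_params,
    qdcnn_forward,
    save_checkpoint,
)
from qdcnn.sigmodel import MultiContrastImage, ParameterMaps, synthesize_signal


@pytest.fixture(scope="module")
def small_problem(schedule16):
    rng = np.random.default_rng(0)
    h = w = 24
    maps = ParameterMaps(
        t2=rng.uniform(50, 300, size=(h, w)),
        s0_re=rng.uniform(0.2, 1.0, size=(h, w)),
        s0_im=0.2 * rng.uniform(0.2, 1.0, size=(h, w)),
    )
    img = synthesize_signal(maps, schedule16)
    masks = make_mask_set(h, w, 16, 3.0, seed=5)
    y = encode(img, masks)
    return img, maps, masks, y


class TestFrec:
    def test_empty_unroll_is_identity(self, small_problem):
        img, _, masks, y = small_problem
        x_zf = zero_fill(y)
        out = frec_forward(x_zf, y, masks, [], ReconNetConfig(n_cascades=0))
        np.testing.assert_array_equal(out.data, x_zf.data)

    def test_zero_residual_init_gives_pure_dc(self, small_problem):
        """Freshly initialized cascades leave measured k-space exact (nu=inf)."""
        img, _, masks, y = small_problem
        cfg = ReconNetConfig.desk()
        w = init_frec_weights(cfg, 16)
        x_rec = frec_forward(zero_fill(y), y, masks, w, cfg)
        k = encode(x_rec, None).data
        on = masks.masks == 1
        np.testing.assert_allclose(k[on], y.data[on], atol=1e-12)

    def test_fully_sampled_zero_residual_roundtrip(self, small_problem, schedule16):
        from qdcnn.encoding import full_mask_set

        img, _, _, _ = small_problem
        masks = full_mask_set(24, 24, 16)
        y = encode(img, masks)
        cfg = ReconNetConfig.desk()
        w = init_frec_weights(cfg, 16)
        x_rec = frec_forward(zero_fill(y), y, masks, w, cfg)
        np.testing.assert_allclose(x_rec.data, img.data, atol=1e-8)

    def test_hard_dc_invariant_with_trained_like_weights(self, small_problem):
        """Measured k-space coefficients survive any denoiser output."""
        img, _, masks, y = small_problem
        cfg = ReconNetConfig.desk()
        rng = np.random.default_rng(3)
        w = init_frec_weights(cfg, 16)
        # make the denoiser act nontrivially
        w = [
            [(k + 0.05 * rng.standard_normal(k.shape), b) for k, b in layers]
            for layers in w
        ]
        x_rec = frec_forward(zero_fill(y), y, masks, w, cfg)
        k = encode(x_rec, None).data
        on = masks.masks == 1
        np.testing.assert_allclose(k[on], y.data[on], atol=1e-10)

    def test_echo_count_mismatch_rejected(self, small_problem):
        img, _, masks, y = small_problem
        cfg = ReconNetConfig.desk()
        w = init_frec_weights(cfg, 8)  # wrong echo count
        with pytest.raises(ValueError):
            frec_forward(zero_fill(y), y, masks, w, cfg)


class TestFmap:
    def test_output_shape_and_t2_bounds(self, small_problem):
        img, _, _, _ = small_problem
        cfg = MapNetConfig()
        w = init_fmap_weights(cfg, 16)
        maps = fmap_forward(img, w, cfg)
        assert maps.stack().shape == (3, 24, 24)
        assert np.all(maps.t2 > cfg.t2_min) and np.all(maps.t2 < cfg.t2_max)

    def test_pixelwise_permutation_equivariance(self, small_problem, schedule16):
        img, _, _, _ = small_problem
        cfg = MapNetConfig()
        w = init_fmap_weights(cfg, 16)
        rng = np.random.default_rng(7)
        perm = rng.permutation(24 * 24)
        permuted = MultiContrastImage(
            data=img.data.reshape(16, -1)[:, perm].reshape(16, 24, 24),
            schedule=schedule16,
        )
        a = fmap_forward(img, w, cfg).stack().reshape(3, -1)[:, perm]
        b = fmap_forward(permuted, w, cfg).stack().reshape(3, -1)
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    def test_nonfinite_input_rejected(self, schedule16):
        cfg = MapNetConfig()
        w = init_fmap_weights(cfg, 16)
        data = np.ones((16, 4, 4), complex)
        img = MultiContrastImage(data=data, schedule=schedule16)
        img.data[0, 0, 0] = np.nan  # bypass constructor check
        with pytest.raises(ValueError):
            fmap_forward(img, w, cfg)


class TestComposition:
    def test_deterministic_given_weights(self, small_problem):
        _, _, masks, y = small_problem
        rcfg = ReconNetConfig.desk(seed=1)
        mcfg = MapNetConfig(seed=2)
        weights = {
            "frec": init_frec_weights(rcfg, 16),
            "fmap": init_fmap_weights(mcfg, 16),
        }
        x1, p1 = qdcnn_forward(y, masks, weights, rcfg, mcfg)
        x2, p2 = qdcnn_forward(y, masks, weights, rcfg, mcfg)
        np.testing.assert_array_equal(x1.data, x2.data)
        np.testing.assert_array_equal(p1.stack(), p2.stack())

    def test_gradients_finite_on_random_batch(self, small_problem, schedule16):
        from autograd import grad

        from qdcnn.networks import fmap_forward_arrays, frec_forward_arrays
        from qdcnn.training import loss_terms_arrays, tree_map

        _, _, masks, y = small_problem
        rcfg = ReconNetConfig.desk(n_cascades=1)
        mcfg = MapNetConfig(hidden_layers=2, hidden_units=16)
        weights = {
            "frec": init_frec_weights(rcfg, 16),
            "fmap": init_fmap_weights(mcfg, 16),
        }
        yb = y.data[None]
        mask = masks.masks[None].astype(float)
        from qdcnn.encoding import ifft2c

        zf = ifft2c(yb)
        x_zf = np.concatenate([zf.real, zf.imag], axis=1)
        rng = np.random.default_rng(0)
        x_gt = rng.normal(size=x_zf.shape)
        p_gt = rng.uniform(10, 200, size=(1, 3, 24, 24))

        def total(w):
            xr = frec_forward_arrays(x_zf, yb, mask, w["frec"], rcfg)
            pr = fmap_forward_arrays(xr, w["fmap"], mcfg)
            lr_, lp_, ldc_ = loss_terms_arrays(
                xr, pr, x_gt, p_gt, yb, mask, schedule16.tes
            )
            return lr_ + 1e-2 * lp_ + 1e-6 * ldc_

        g = grad(total)(weights)
        flat = []
        tree_map(lambda a: flat.append(np.asarray(a)), g)
        assert all(np.all(np.isfinite(a)) for a in flat)
        assert any(np.any(a != 0) for a in flat)

    def test_oracle_weights_recover_gt(self, small_problem, schedule16):
        """Identity recon on fully sampled data + analytic inversion == GT."""
        from qdcnn.encoding import full_mask_set
        from qdcnn.fitting import lsf_fit_image

        img, maps, _, _ = small_problem
        masks = full_mask_set(24, 24, 16)
        y = encode(img, masks)
        x_rec = frec_forward(
            zero_fill(y), y, masks, [], ReconNetConfig(n_cascades=0)
        )
        est = lsf_fit_image(x_rec)
        np.testing.assert_allclose(est.t2, maps.t2, rtol=1e-3)


class TestParameterCounts:
    @pytest.mark.parametrize(
        "cfg, expected",
        [
            # per cascade: 32->16 (3x3) + 16->16 + 16->32 convs with biases
            (
                ReconNetConfig(n_cascades=2, convs_per_cascade=3, filters=16),
                2 * ((16 * 32 * 9 + 16) + (16 * 16 * 9 + 16) + (32 * 16 * 9 + 32)),
            ),
            (
                ReconNetConfig(n_cascades=1, convs_per_cascade=2, filters=8),
                (8 * 32 * 9 + 8) + (32 * 8 * 9 + 32),
            ),
        ],
    )
    def test_frec_count_is_function_of_config(self, cfg, expected):
        assert n_params(init_frec_weights(cfg, 16)) == expected

    def test_fmap_count_is_function_of_config(self):
        cfg = MapNetConfig(hidden_layers=4, hidden_units=128)
        expected = (32 * 128 + 128) + 3 * (128 * 128 + 128) + (128 * 3 + 3)
        assert n_params(init_fmap_weights(cfg, 16)) == expected


def test_checkpoint_round_trip(tmp_path):
    rcfg = ReconNetConfig.desk(seed=4)
    mcfg = MapNetConfig(seed=5)
    weights = {
        "frec": init_frec_weights(rcfg, 16),
        "fmap": init_fmap_weights(mcfg, 16),
    }
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, weights, recon_cfg=rcfg, map_cfg=mcfg, extra={"k": 1})
    back, meta = load_checkpoint(path)
    assert meta["extra"]["k"] == 1
    assert meta["map_cfg"]["hidden_units"] == 128
    np.testing.assert_array_equal(back["frec"][0][0][0], weights["frec"][0][0][0])
    np.testing.assert_array_equal(back["fmap"][-1][1], weights["fmap"][-1][1])
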