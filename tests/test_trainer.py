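"""Compression-loop behaviour: losses, reproducibility, convergence."""

import numpy as np
import pytest

from inifield import backbone as bb
from inifield.decoder import ROISpec, decode
from inifield.grid import make_grid, minmax_normalize
from inifield.image import ImageTensor
from inifield.metrics import psnr
from inifield.synth import make_nuclei_volume
from inifield.trainer import (
    CompressionConfig, TrainingDivergedError, compress, evaluate, mse_loss,
)


class TestMseLoss:
    def test_identity_zero(self, rng):
        x = rng.random(50)
        assert mse_loss(x, x) == 0.0

    def test_hand_value(self):
        assert mse_loss([0.0, 0.0], [3.0, 4.0]) == 12.5

    def test_matches_naive_loop(self, rng):
        a, b = rng.random(200), rng.random(200)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert mse_loss(a, b) == pytest.approx(acc / 200, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([], [])


class TestCompress:
    def test_constant_image_reproduced(self):
        img = ImageTensor(np.full((16, 16, 16), 777, dtype=np.uint16), "ZYX")
        cfg = CompressionConfig(target_cr=4, steps=200, seed=0, log_every=100)
        f = compress(img, cfg)
        dec = decode(f, ROISpec.full())
        assert psnr(img.data, dec.data, 65535) > 50

    def test_seeded_byte_identical(self, nuclei_small):
        cfg = CompressionConfig(target_cr=6, steps=60, seed=3, log_every=30)
        a = compress(nuclei_small, cfg)
        b = compress(nuclei_small, cfg)
        assert a.to_bytes() == b.to_bytes()

    def test_loss_improves_over_initialization(self, nuclei_small, trained_file):
        trace = trained_file.loss_trace
        assert trace[-1]["loss"] < trace[0]["loss"]

    def test_achieved_cr_covers_target(self, nuclei_small, trained_file):
        assert nuclei_small.raw_bytes / trained_file.nbytes >= 4.0

    def test_width_capacity_helps_at_fixed_steps(self):
        """Median PSNR over seeds is non-decreasing in model width."""
        img = make_nuclei_volume((8, 16, 16), n_nuclei=1, seed=11)
        norm, params = minmax_normalize(img)
        grid = make_grid(img.shape)
        t = norm.data.ravel().astype(np.float32)[:, None]
        from inifield import optim
        from inifield.trainer import _cosine_lr, lr_scale_policy

        def fit_psnr(width, seed):
            model = bb.init_model(3, 1, width, 7, seed=seed)
            pl = model.param_list()
            cfg = CompressionConfig(target_cr=2)
            st = optim.make_state("adam", pl, lr=1e-3,
                                  lr_scales=lr_scale_policy(model, cfg))
            for step in range(150):
                y, cache = bb.forward_cached(model, grid.coords)
                g = bb.backward(model, cache, (2 / len(t)) * (y - t))
                st["lr"] = _cosine_lr(step, 150, 1e-3, 1e-5)
                pl, st = optim.optimizer_step(pl, g.param_list(), st)
                model.set_params(pl)
            pred = np.clip(bb.forward(model, grid.coords)[:, 0], 0, 100)
            rec = params.src_min + pred / params.scale
            return psnr(img.data, np.rint(rec).reshape(img.shape), 65535)

        meds = []
        for width in (2, 8, 24):
            vals = sorted(fit_psnr(width, s) for s in range(5))
            meds.append(vals[2])
        assert meds[0] <= meds[1] + 0.1 and meds[1] <= meds[2] + 0.1

    def test_linear_model_converges_to_least_squares(self):
        """depth=2 + full-grid batches approach the affine least-squares fit."""
        rng = np.random.default_rng(4)
        data = (rng.random((16, 16)) * 50 + 25).astype(np.float32)
        img = ImageTensor(data, "YX")
        norm, _ = minmax_normalize(img)
        grid = make_grid(img.shape)
        t = norm.data.ravel()[:, None]
        X = np.hstack([grid.coords.astype(np.float64), np.ones((256, 1))])
        beta, *_ = np.linalg.lstsq(X, t, rcond=None)
        cfg = CompressionConfig(target_cr=2, steps=10000, batch_points=256,
                                seed=0, depth=2, log_every=5000)
        f = compress(img, cfg)
        model = f.model()
        w_fit = np.concatenate([model.weights[0][:, 0], model.biases[0]])
        np.testing.assert_allclose(w_fit, beta[:, 0], atol=0.05)

    def test_divergence_aborts_with_diagnostic(self, nuclei_small):
        cfg = CompressionConfig(target_cr=6, steps=50, seed=0,
                                optimizer_id="sgd",
                                optimizer_params={})
        cfg.lr = 1e9  # guaranteed blow-up
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(TrainingDivergedError):
                compress(nuclei_small, cfg)


class TestEvaluate:
    def test_report_fields_and_cr_guarantee(self, nuclei_small, trained_file):
        rep = evaluate(nuclei_small, trained_file)
        assert set(rep) >= {"psnr", "ssim", "mse", "achieved_cr"}
        assert rep["achieved_cr"] >= 4.0
        assert -1 <= rep["ssim"] <= 1

    def test_shape_mismatch_rejected(self, trained_file):
        other = ImageTensor(np.zeros((4, 4), dtype=np.uint16), "YX")
        with pytest.raises(ValueError):
            evaluate(other, trained_file)
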