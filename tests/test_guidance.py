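"""Guidance losses: IoU, segmentation surrogate, perceptual features."""

import numpy as np
import pytest

from inifield import guidance as gd


class TestIou:
    def test_identical_nonempty(self):
        m = np.zeros((5, 5))
        m[1:3, 1:4] = 1
        assert gd.iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 1
        b[3, 3] = 1
        assert gd.iou(a, b) == 0.0

    def test_one_third_overlap(self):
        a = np.zeros(5)
        b = np.zeros(5)
        a[[1, 2]] = 1
        b[[2, 3]] = 1
        assert gd.iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_perfect_agreement(self):
        assert gd.iou(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_symmetry_and_range_on_soft_masks(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        v = gd.iou(a, b)
        assert v == gd.iou(b, a)
        assert 0 <= v <= 1

    def test_soft_equals_hard_on_binary(self, rng):
        a = (rng.random((10, 10)) > 0.5).astype(float)
        b = (rng.random((10, 10)) > 0.5).astype(float)
        inter = np.logical_and(a, b).sum()
        union = np.logical_or(a, b).sum()
        assert gd.iou(a, b) == pytest.approx(inter / union)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gd.iou(np.zeros((2, 2)), np.zeros((3, 3)))


class TestReferenceSegment:
    def test_blank_image_empty_mask(self):
        assert gd.reference_segment(np.zeros((32, 32))).sum() == 0

    def test_bright_line_covered_small_components_absent(self):
        img = np.zeros((64, 64))
        img[32, 10:50] = 100.0  # a 40-px line plus nothing else
        mask = gd.reference_segment(img)
        assert mask[32, 15:45].all()
        # every surviving component has at least the minimum filament length
        from scipy.ndimage import label

        lab, n = label(mask)
        assert n >= 1

    def test_small_speck_removed(self):
        img = np.zeros((64, 64))
        img[10, 10:15] = 100.0  # 5-px speck, far below the 20-px minimum
        assert gd.reference_segment(img).sum() == 0

    def test_too_many_dims_rejected(self):
        with pytest.raises(ValueError):
            gd.reference_segment(np.zeros((2, 3, 4, 5)))


class TestSoftSegment:
    def test_sharp_temperature_approaches_hard_threshold(self):
        img = np.zeros((32, 32))
        img[16, 4:28] = 100.0
        p_sharp = gd.SegParams(soft_threshold_temp=1e-4)
        soft = gd.soft_segment(img, p_sharp)
        from scipy.ndimage import gaussian_filter, gaussian_laplace

        x = img / 100.0
        r = -gaussian_laplace(gaussian_filter(x, 1.0, mode="constant"), 1.0,
                              mode="constant")
        hard = (r > 0.01).astype(float)
        away = np.abs(r - 0.01) > 1e-3  # off the decision boundary
        assert np.abs(soft - hard)[away].max() < 0.01

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.uniform(0, 100, (12, 12))
        src = rng.uniform(0, 100, (12, 12))
        p = gd.SegParams()
        _, g = gd.segmentation_loss_grad(x, src, p)
        h = 1e-4
        fd, an = [], []
        for i in range(12):
            for j in range(12):
                orig = x[i, j]
                x[i, j] = orig + h
                lp = gd.segmentation_loss(x, src, p)
                x[i, j] = orig - h
                lm = gd.segmentation_loss(x, src, p)
                x[i, j] = orig
                fd.append((lp - lm) / (2 * h))
                an.append(g[i, j])
        fd, an = np.array(fd), np.array(an)
        assert np.linalg.norm(fd - an) / np.linalg.norm(an) < 1e-3

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            gd.soft_segment(np.zeros((8, 8)), gd.SegParams(soft_threshold_temp=0))


class TestSegmentationLoss:
    def test_identity_zero(self, rng):
        x = rng.uniform(0, 100, (16, 16))
        assert gd.segmentation_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_structureless_vs_structured_in_sharp_limit(self):
        img = np.zeros((48, 48))
        img[24, 4:44] = 100.0
        flat = np.zeros((48, 48))
        p = gd.SegParams(soft_threshold_temp=1e-4)
        assert gd.segmentation_loss(flat, img, p) == pytest.approx(1.0, abs=1e-3)

    def test_decreases_from_noise_toward_original(self):
        from inifield.synth import make_filament_image

        img = make_filament_image((64, 64), n_fibers=3, seed=2).data.astype(float)
        noise = np.random.default_rng(0).uniform(0, img.max(), img.shape)
        losses = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            blended = (1 - alpha) * noise + alpha * img
            losses.append(gd.segmentation_loss(blended, img))
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))
        assert losses[-1] < losses[0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gd.segmentation_loss(np.zeros((4, 4)), np.zeros((5, 5)))


def naive_perceptual(patch_hat, patch_ref, net, w=None):
    """Per-pixel loop oracle for the layer-weighted feature distance."""
    fh = net.features(patch_hat)
    fr = net.features(patch_ref)
    total = 0.0
    for i, (a, b) in enumerate(zip(fh, fr)):
        wi = np.ones(a.shape[0]) if w is None else np.asarray(w[i], float)
        C, H, W = a.shape
        for y in range(H):
            for x in range(W):
                v = 0.0
                for c in range(C):
                    v += (wi[c] * (a[c, y, x] - b[c, y, x])) ** 2
                total += v / (H * W)
    return total


class TestPerceptualLoss:
    def test_identity_zero(self, rng):
        net = gd.ConvFeatureNet(seed=0)
        p = rng.random((10, 10))
        assert gd.perceptual_loss(p, p, net) == 0.0

    def test_identity_features_degenerate_to_mse(self, rng):
        net = gd.IdentityFeatureNet()
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert gd.perceptual_loss(a, b, net) == pytest.approx(
            float(np.mean((a - b) ** 2)), rel=1e-12
        )

    def test_matches_naive_loop_oracle(self, rng):
        net = gd.ConvFeatureNet(seed=3, channels=(3, 4))
        a, b = rng.random((8, 8)), rng.random((8, 8))
        w = [rng.random(3), rng.random(4)]
        assert gd.perceptual_loss(a, b, net, w) == pytest.approx(
            naive_perceptual(a, b, net, w), abs=1e-10
        )

    def test_gradient_matches_finite_differences(self, rng):
        net = gd.ConvFeatureNet(seed=1)
        a, b = rng.random((10, 10)), rng.random((10, 10))
        _, g = gd.perceptual_loss_grad(a, b, net)
        h = 1e-5
        fd, an = [], []
        for i in range(10):
            for j in range(10):
                orig = a[i, j]
                a[i, j] = orig + h
                lp = gd.perceptual_loss(a, b, net)
                a[i, j] = orig - h
                lm = gd.perceptual_loss(a, b, net)
                a[i, j] = orig
                fd.append((lp - lm) / (2 * h))
                an.append(g[i, j])
        fd, an = np.array(fd), np.array(an)
        assert np.linalg.norm(fd - an) / np.linalg.norm(an) < 1e-6

    def test_layer_weight_mismatch_rejected(self, rng):
        net = gd.ConvFeatureNet(seed=0)  # 3 layers
        a = rng.random((10, 10))
        with pytest.raises(ValueError):
            gd.perceptual_loss(a, a, net, w=[np.ones(4)])


class _ArrayProvider:
    def __init__(self, arr):
        self.arr = arr
        self.shape = arr.shape

    def __call__(self, y0, x0, ps):
        return self.arr[y0 : y0 + ps, x0 : x0 + ps]


class TestSampleGuidedPatches:
    def test_seed_reproducible(self, rng):
        src = rng.random((40, 40))
        ref = rng.random((40, 40))
        p = gd.PercParams(patch_size=8)
        a1, r1 = gd.sample_guided_patches(_ArrayProvider(src), ref, p, seed=5)
        a2, r2 = gd.sample_guided_patches(_ArrayProvider(src), ref, p, seed=5)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(r1, r2)

    def test_full_size_patch_is_whole_plane(self, rng):
        src = rng.random((16, 16))
        p = gd.PercParams(patch_size=16)
        a, r = gd.sample_guided_patches(_ArrayProvider(src), src, p, seed=0)
        np.testing.assert_array_equal(a, src)
        np.testing.assert_array_equal(r, src)

    def test_locations_uniform_chi_square(self, rng):
        from scipy.stats import chisquare

        class _Recording(_ArrayProvider):
            def __call__(self, y0, x0, ps):
                self.last = (y0, x0)
                return super().__call__(y0, x0, ps)

        src = rng.random((64, 64))
        p = gd.PercParams(patch_size=16)
        provider = _Recording(src)
        counts = np.zeros((49, 49))
        for seed in range(10000):
            gd.sample_guided_patches(provider, src, p, seed=seed)
            counts[provider.last] += 1
        _, pval = chisquare(counts.ravel())
        assert pval > 0.01

    def test_oversized_patch_rejected(self, rng):
        src = rng.random((8, 8))
        with pytest.raises(ValueError):
            gd.sample_guided_patches(
                _ArrayProvider(src), src, gd.PercParams(patch_size=16), seed=0
            )
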