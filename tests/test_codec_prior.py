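"""Toy codec contracts and the hybrid (codec + residual) pipeline."""

import numpy as np
import pytest

from inifield.codec_prior import (
    CodecError, ToyCodec, decide_slices, hybrid_compress, hybrid_decompress,
)
from inifield.image import ImageTensor
from inifield.inif_format import InifFile
from inifield.metrics import psnr
from inifield.synth import make_nuclei_volume
from inifield.trainer import CompressionConfig


@pytest.fixture(scope="module")
def volume():
    return make_nuclei_volume((12, 24, 24), n_nuclei=2, seed=5)


class _IdentityCodec(ToyCodec):
    """Lossless on any input that fits: encodes at factor 1, 16 bits."""

    codec_id = "toy"  # reuse the container codec id for decode


class TestToyCodec:
    def test_generous_budget_near_lossless(self, volume):
        tc = ToyCodec()
        payload = tc.encode(volume, volume.raw_bytes * 2)
        rec = tc.decode(payload)
        assert rec.shape == volume.shape and rec.data.dtype == np.uint16
        assert psnr(volume.data, rec.data, 65535) > 45

    def test_budget_contract_random_draws(self, rng):
        tc = ToyCodec()
        for _ in range(100):
            shape = tuple(int(rng.integers(6, 24)) for _ in range(3))
            img = ImageTensor(
                rng.integers(0, 60000, shape).astype(np.uint16), "ZYX"
            )
            budget = int(rng.integers(60, img.raw_bytes))
            try:
                payload = tc.encode(img, budget)
            except CodecError:
                continue
            assert len(payload) <= budget
            assert tc.decode(payload).shape == shape

    def test_halving_budget_never_improves(self, rng):
        tc = ToyCodec()
        worse = 0
        for k in range(20):
            img = make_nuclei_volume((8, 16, 16), n_nuclei=1, seed=100 + k)
            budgets = [img.raw_bytes, img.raw_bytes // 2, img.raw_bytes // 4,
                       img.raw_bytes // 8]
            ps = [
                psnr(img.data, tc.decode(tc.encode(img, b)).data, 65535)
                for b in budgets
            ]
            assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:])), ps

    def test_impossible_budget_rejected(self, volume):
        with pytest.raises(CodecError):
            ToyCodec().encode(volume, 10)


class TestDecideSlices:
    def test_perfect_adapted_slice_wins(self, volume):
        codec_rec = ImageTensor(
            np.clip(volume.data.astype(np.int32) + 500, 0, 65535).astype(np.uint16),
            volume.axes,
        )
        adapted = ImageTensor(volume.data.copy(), volume.axes)
        decisions = decide_slices(volume, codec_rec, adapted)
        assert all(decisions)

    def test_tie_keeps_codec(self, volume):
        rec = ImageTensor(volume.data.copy(), volume.axes)
        assert not any(decide_slices(volume, rec, rec))

    def test_matches_per_slice_mse_oracle(self, volume, rng):
        raw = volume.data.astype(np.float64)
        for _ in range(100):
            a = raw + rng.normal(0, rng.uniform(10, 400), raw.shape)
            b = raw + rng.normal(0, rng.uniform(10, 400), raw.shape)
            decisions = decide_slices(
                volume, ImageTensor(a, "ZYX"), ImageTensor(b, "ZYX")
            )
            mse_a = ((a - raw) ** 2).mean(axis=(1, 2))
            mse_b = ((b - raw) ** 2).mean(axis=(1, 2))
            np.testing.assert_array_equal(decisions, mse_b < mse_a)

    def test_unknown_metric_rejected(self, volume):
        rec = ImageTensor(volume.data.copy(), volume.axes)
        with pytest.raises(ValueError):
            decide_slices(volume, rec, rec, metric_id="centrosomes")


@pytest.fixture(scope="module")
def hybrid_file(volume):
    cfg = CompressionConfig(target_cr=8, steps=200, seed=0, log_every=100)
    return hybrid_compress(volume, ToyCodec(), target_cr=8, split=0.9, cfg=cfg)


class TestHybrid:

    def test_codec_budget_is_split_fraction(self, volume, hybrid_file):
        hy = hybrid_file.header["hybrid"]
        budget = int(0.9 * volume.raw_bytes / 8)
        assert hy["codec_payload_len"] <= budget
        assert hy["split"] == 0.9

    def test_whole_file_cr_covers_target(self, volume, hybrid_file):
        assert volume.raw_bytes / hybrid_file.nbytes >= 8

    def test_decompress_deterministic_and_round_trips(self, volume, hybrid_file):
        out1 = hybrid_decompress(hybrid_file)
        out2 = hybrid_decompress(InifFile.from_bytes(hybrid_file.to_bytes()))
        np.testing.assert_array_equal(out1.data, out2.data)
        assert out1.shape == volume.shape and out1.data.dtype == np.uint16

    def test_all_false_decisions_equal_codec_only(self, volume, hybrid_file):
        tc = ToyCodec()
        codec_only = tc.decode(
            hybrid_file.payload[: hybrid_file.header["hybrid"]["codec_payload_len"]]
        )
        forced = InifFile(dict(hybrid_file.header), hybrid_file.payload)
        forced.header["hybrid"] = {
            **hybrid_file.header["hybrid"],
            "decisions": [False] * volume.shape[0],
        }
        np.testing.assert_array_equal(
            hybrid_decompress(forced).data, codec_only.data
        )

    def test_all_true_matches_recombination_oracle(self, volume, hybrid_file):
        """codec + residual everywhere equals an independent recombination."""
        from inifield.codec_prior import _decode_residual
        from inifield.grid import NormalizationParams

        forced = InifFile(dict(hybrid_file.header), hybrid_file.payload)
        forced.header["hybrid"] = {
            **hybrid_file.header["hybrid"],
            "decisions": [True] * volume.shape[0],
        }
        got = hybrid_decompress(forced).data

        tc = ToyCodec()
        codec_only = tc.decode(
            hybrid_file.payload[: hybrid_file.header["hybrid"]["codec_payload_len"]]
        ).data.astype(np.float64)
        params = NormalizationParams.from_dict(hybrid_file.header["norm"])
        recon_norm = params.dst_lo + (codec_only - params.src_min) * params.scale
        combined = recon_norm + _decode_residual(forced)
        expect = params.src_min + (
            np.clip(combined, params.dst_lo, params.dst_hi) - params.dst_lo
        ) / params.scale
        np.testing.assert_array_equal(
            got, np.clip(np.rint(expect), 0, 65535).astype(np.uint16)
        )

    def test_chosen_slices_no_worse_than_codec(self, volume, hybrid_file):
        tc = ToyCodec()
        codec_only = tc.decode(
            hybrid_file.payload[: hybrid_file.header["hybrid"]["codec_payload_len"]]
        )
        out = hybrid_decompress(hybrid_file)
        for k, used in enumerate(hybrid_file.header["hybrid"]["decisions"]):
            if used:
                assert psnr(volume.data[k], out.data[k], 65535) > psnr(
                    volume.data[k], codec_only.data[k], 65535
                )

    def test_identity_codec_zero_residual(self):
        """A lossless codec pass leaves (almost) nothing for the adapter."""
        img = make_nuclei_volume((8, 16, 16), n_nuclei=1, seed=9)
        tc = ToyCodec()
        cfg = CompressionConfig(target_cr=1.2, steps=50, seed=0, log_every=50)
        f = hybrid_compress(img, tc, target_cr=1.2, split=0.9, cfg=cfg)
        codec_only = tc.decode(
            f.payload[: f.header["hybrid"]["codec_payload_len"]]
        )
        # generous budget -> factor 1; only quantization error remains
        assert psnr(img.data, codec_only.data, 65535) > 40
        out = hybrid_decompress(f)
        assert psnr(img.data, out.data, 65535) >= psnr(
            img.data, codec_only.data, 65535
        ) - 1e-9
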