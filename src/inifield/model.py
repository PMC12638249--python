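"""High-level modelling interface.

:class:`INIFModel` is built from an image (array or :class:`ImageTensor`)
and a target compression ratio; ``fit()`` runs the compression training
and returns an :class:`INIFResults` carrying the serialized unit, the
loss trace, quality metrics and a ``summary()`` table — the same shape of
API as a statistical model fitted to data, which is exactly what the
compressor is: a budgeted sinusoidal regression of intensity on
coordinates.
"""

from __future__ import annotations

import numpy as np

from .decoder import ROISpec, decode, decode_mask
from .guidance import GuidanceConfig
from .image import ImageTensor, default_axes
from .inif_format import InifFile
from .sizing import plan_architecture
from .trainer import CompressionConfig, compress, evaluate


class INIFModel:
    """A per-image implicit neural field compressor.

    Parameters
    ----------
    data : array-like or ImageTensor
        The image to compress (u8/u16/float, up to 5 axes).
    axes : str, optional
        Axis labels among ``T,C,Z,Y,X``; guessed from rank if omitted.
    target_cr : float
        Requested compression ratio; the serialized file is guaranteed to
        be at least this factor smaller than the raw pixel payload.
    guidance : GuidanceConfig, optional
        Segmentation or perceptual guidance term.
    """

    def __init__(self, data, axes=None, target_cr=256.0, guidance=None, **config):
        if isinstance(data, ImageTensor):
            self.image = data
        else:
            data = np.asarray(data)
            self.image = ImageTensor(data, axes or default_axes(data.ndim))
        self.config = CompressionConfig(
            target_cr=float(target_cr), guidance=guidance, **config
        )

    @classmethod
    def from_tiff(cls, path, axes=None, **kw):
        from .image import read_tiff

        return cls(read_tiff(path, axes_hint=axes), **kw)

    def plan(self):
        """The architecture/byte budget the target ratio implies."""
        return plan_architecture(
            self.image.shape, self.image.dtype_code, self.config.target_cr,
            depth=self.config.depth, bytes_per_param=self.config.bytes_per_param,
        )

    def fit(self, steps=None, seed=None, **overrides) -> "INIFResults":
        cfg = CompressionConfig(**{
            **self.config.__dict__,
            **({"steps": steps} if steps is not None else {}),
            **({"seed": seed} if seed is not None else {}),
            **overrides,
        })
        file = compress(self.image, cfg)
        return INIFResults(self, file, cfg)


class INIFResults:
    """The outcome of a compression fit."""

    def __init__(self, model: INIFModel, file: InifFile, config: CompressionConfig):
        self.model = model
        self.file = file
        self.config = config
        self.loss_trace = file.loss_trace
        self._metrics = None

    @property
    def metrics(self) -> dict:
        if self._metrics is None:
            self._metrics = evaluate(self.model.image, self.file)
        return self._metrics

    @property
    def achieved_cr(self) -> float:
        return self.model.image.raw_bytes / self.file.nbytes

    def decode(self, roi: ROISpec | None = None):
        return decode(self.file, roi)

    def decode_mask(self, mask):
        return decode_mask(self.file, mask)

    def save(self, path) -> int:
        return self.file.save(path)

    def summary(self) -> str:
        h = self.file.header
        m = self.metrics
        arch = h["arch"]
        lines = [
            "INIF compression results",
            "=" * 44,
            f"{'axes / shape':<24}{h['axes']} {tuple(h['shape'])}",
            f"{'source dtype':<24}{h['dtype_code']}",
            f"{'architecture':<24}depth {arch['depth']}, width {arch['width']}",
            f"{'trainable parameters':<24}{_param_count(arch)}",
            f"{'target CR':<24}{self.config.target_cr:g}x",
            f"{'achieved CR':<24}{self.achieved_cr:.2f}x",
            f"{'file size':<24}{self.file.nbytes} bytes",
            f"{'PSNR':<24}{m['psnr']:.2f} dB",
            f"{'SSIM':<24}{m['ssim']:.4f}",
            f"{'training steps':<24}{self.config.steps}",
            f"{'final loss':<24}{self.loss_trace[-1]['loss']:.4f}"
            if self.loss_trace else "",
            "=" * 44,
        ]
        return "\n".join(filter(None, lines))


def _param_count(arch) -> int:
    from .backbone import parameter_count_for

    return parameter_count_for(
        arch["in_dim"], arch["out_dim"], arch["width"], arch["depth"]
    )
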