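"""The on-disk INIF container.

Layout::

    magic "NIF1" | uint32 LE header length | UTF-8 JSON header | payload

The header is self-describing: axes, shape, source dtype, normalization
parameters, architecture, seed, optional guidance/hybrid blocks and a
CRC-32 of the payload (fixed-width 8 hex digits so the header length is
known before the payload exists). The payload stores, little-endian, each
weight layer row-major followed by its bias, then the frequency scalars —
float32 by default, float16 behind a format flag.
"""

from __future__ import annotations

import json
import zlib

import numpy as np

from .backbone import SirenModel, layer_dims

MAGIC = b"NIF1"
FORMAT_VERSION = 1
WEIGHT_DTYPES = {"f32": np.dtype("<f4"), "f16": np.dtype("<f2")}


class InifFormatError(ValueError):
    pass


class BadMagicError(InifFormatError):
    pass


class VersionError(InifFormatError):
    pass


class ChecksumError(InifFormatError):
    pass


class TruncatedError(InifFormatError):
    pass


def build_header(metadata: dict) -> bytes:
    """Deterministic compact JSON header."""
    meta = dict(metadata)
    meta.setdefault("format_version", FORMAT_VERSION)
    meta.setdefault("crc32", "00000000")
    return json.dumps(meta, sort_keys=True, separators=(",", ":")).encode("utf-8")


def header_overhead(metadata: dict) -> int:
    """Bytes the container spends on everything except the weight payload."""
    return len(MAGIC) + 4 + len(build_header(metadata))


def serialize_payload(model: SirenModel, weight_dtype: str = "f32") -> bytes:
    dt = WEIGHT_DTYPES[weight_dtype]
    parts = []
    for W, b in zip(model.weights, model.biases):
        parts.append(np.ascontiguousarray(W, dtype=dt).tobytes())
        parts.append(np.ascontiguousarray(b, dtype=dt).tobytes())
    parts.append(np.ascontiguousarray(model.omegas, dtype=dt).tobytes())
    return b"".join(parts)


class InifFile:
    """An in-memory INIF unit: parsed header + raw payload bytes."""

    def __init__(self, header: dict, payload: bytes):
        self.header = header
        self.payload = payload
        self.loss_trace = None  # attached by the trainer, not serialized

    @property
    def nbytes(self) -> int:
        return len(self.to_bytes())

    def to_bytes(self) -> bytes:
        meta = dict(self.header)
        meta["format_version"] = FORMAT_VERSION
        meta["crc32"] = f"{zlib.crc32(self.payload) & 0xFFFFFFFF:08x}"
        hdr = json.dumps(meta, sort_keys=True, separators=(",", ":")).encode()
        return MAGIC + len(hdr).to_bytes(4, "little") + hdr + self.payload

    def save(self, path) -> int:
        blob = self.to_bytes()
        with open(path, "wb") as fh:
            fh.write(blob)
        return len(blob)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "InifFile":
        if len(blob) < 8 or blob[:4] != MAGIC:
            raise BadMagicError("not an INIF file (bad magic)")
        hlen = int.from_bytes(blob[4:8], "little")
        if len(blob) < 8 + hlen:
            raise TruncatedError("truncated header")
        header = json.loads(blob[8 : 8 + hlen].decode("utf-8"))
        if header.get("format_version") != FORMAT_VERSION:
            raise VersionError(
                f"unsupported format_version {header.get('format_version')!r}"
            )
        payload = blob[8 + hlen :]
        arch = header["arch"]
        dt = WEIGHT_DTYPES[header.get("weight_dtype", "f32")]
        dims = layer_dims(arch["in_dim"], arch["out_dim"], arch["width"], arch["depth"])
        n_sine = 0 if arch["depth"] == 2 else arch["depth"] - 1
        n_params = sum(fi * fo + fo for fi, fo in dims) + n_sine
        skip = (header.get("hybrid") or {}).get("codec_payload_len", 0)
        if len(payload) - skip < n_params * dt.itemsize:
            raise TruncatedError("truncated payload")
        expect = f"{zlib.crc32(payload) & 0xFFFFFFFF:08x}"
        if header.get("crc32") != expect:
            raise ChecksumError("payload checksum mismatch")
        return cls(header, payload)

    @classmethod
    def load(cls, path) -> "InifFile":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())

    def model(self) -> SirenModel:
        """Rebuild the network (float32 compute precision) from the payload."""
        arch = self.header["arch"]
        dt = WEIGHT_DTYPES[self.header.get("weight_dtype", "f32")]
        dims = layer_dims(arch["in_dim"], arch["out_dim"], arch["width"], arch["depth"])
        skip = (self.header.get("hybrid") or {}).get("codec_payload_len", 0)
        buf = np.frombuffer(self.payload[skip:], dtype=dt)
        weights, biases, off = [], [], 0
        for fi, fo in dims:
            weights.append(
                buf[off : off + fi * fo].reshape(fi, fo).astype(np.float32)
            )
            off += fi * fo
            biases.append(buf[off : off + fo].astype(np.float32))
            off += fo
        n_sine = 0 if arch["depth"] == 2 else arch["depth"] - 1
        omegas = buf[off : off + n_sine].astype(np.float32)
        return SirenModel(
            arch["in_dim"], arch["out_dim"], arch["width"], arch["depth"],
            arch["omega0"], weights, biases, omegas,
        )


def write_inif(model: SirenModel, metadata: dict, path) -> int:
    """Serialize model + metadata; returns total bytes written."""
    wd = metadata.get("weight_dtype", "f32")
    f = InifFile(dict(metadata), serialize_payload(model, wd))
    return f.save(path)


def read_inif(path) -> tuple[SirenModel, dict]:
    f = InifFile.load(path)
    return f.model(), f.header


def make_file(model: SirenModel, metadata: dict) -> InifFile:
    wd = metadata.get("weight_dtype", "f32")
    return InifFile(dict(metadata), serialize_payload(model, wd))
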