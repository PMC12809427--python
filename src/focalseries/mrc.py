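"""Minimal MRC2014 image/stack I/O and the JSON defocus sidecar.

Images and stacks are written as MRC2014 mode-2 (float32) files with the
pixel size in the cell fields; modes 0 (int8), 1 (int16) and 6 (uint16) are
promoted to float on reading.  Arrays are indexed ``[section, row=y, col=x]``.
Complex images are exported as paired real/imaginary files plus amplitude and
phase images on request.  Series metadata (geometry, microscope, provenance)
round-trips through a JSON sidecar rather than MRC extended headers, so it
stays dialect-free and diffable.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .optics import MicroscopeParams, SeriesGeometry
from .synthesize import FocalSeries

__all__ = [
    "read_mrc",
    "write_mrc",
    "write_complex",
    "SeriesMetadata",
    "write_series",
    "read_series",
]

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MrcFormatError(ValueError):
    """Raised for corrupt or unsupported MRC files."""


def write_mrc(data: np.ndarray, pixel: float, path) -> None:
    """Write a 2D image or 3D stack as an MRC2014 mode-2 file."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected 2D or 3D data, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite data")
    if np.iscomplexobj(data):
        raise ValueError("complex data: use write_complex")
    nz, ny, nx = data.shape
    data32 = np.ascontiguousarray(data, dtype="<f4")
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, nx * pixel, ny * pixel, nz * pixel, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(data32.min()), float(data32.max()),
                     float(data32.mean()))
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data32.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data32.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file, returning (stack as float32 (nz, ny, nx), pixel size Å)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MrcFormatError(f"{path}: file shorter than the 1024-byte MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 1 << 20:
        raise MrcFormatError(f"{path}: implausible dimensions {(nx, ny, nz)}")
    if mode not in _MODE_DTYPES:
        raise MrcFormatError(f"{path}: unsupported MRC mode {mode}")
    mx = struct.unpack_from("<i", raw, 28)[0]
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    pixel = cella_x / mx if mx > 0 and cella_x > 0 else 1.0
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    offset = _HEADER_SIZE + max(nsymbt, 0)
    count = nx * ny * nz
    if len(raw) < offset + count * dtype.itemsize:
        raise MrcFormatError(f"{path}: truncated data block")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    return data.reshape(nz, ny, nx).astype(np.float32), float(pixel)


def write_complex(values: np.ndarray, pixel: float, prefix,
                  amplitude_phase: bool = True) -> list[Path]:
    """Write a complex image as _real/_imag (and _amp/_phase) MRC files."""
    prefix = Path(prefix)
    written = []
    parts = {"real": np.real(values), "imag": np.imag(values)}
    if amplitude_phase:
        parts["amp"] = np.abs(values)
        parts["phase"] = np.angle(values)
    for tag, arr in parts.items():
        p = prefix.with_name(prefix.name + f"_{tag}.mrc")
        write_mrc(arr, pixel, p)
        written.append(p)
    return written


@dataclass
class SeriesMetadata:
    """Sidecar metadata sufficient to regenerate or reinterpret a series."""

    pixel: float
    voltage: float
    cs: float
    amp_phase: float
    n_images: int
    focal_step: float
    mid_defocus: float
    astig_dev: float = 0.0
    astig_angle: float = 0.0
    seed: int | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def offsets(self) -> list[float]:
        return SeriesGeometry(self.n_images, self.focal_step, self.mid_defocus).offsets.tolist()

    def to_json(self) -> str:
        d = asdict(self)
        d["focal_offsets"] = self.offsets()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SeriesMetadata":
        d = json.loads(text)
        d.pop("focal_offsets", None)
        return cls(**d)

    @classmethod
    def from_series(cls, series: FocalSeries, seed: int | None = None) -> "SeriesMetadata":
        g, m = series.geometry, series.microscope
        return cls(series.pixel, m.voltage, m.cs, m.amp_phase, g.n_images,
                   g.focal_step, g.mid_defocus, g.astig_dev, g.astig_angle,
                   seed, dict(series.provenance))


def write_series(series: FocalSeries, path, seed: int | None = None) -> None:
    """Write a focal series as MRC stack + JSON sidecar (same stem, .json)."""
    path = Path(path)
    write_mrc(series.stack, series.pixel, path)
    meta = SeriesMetadata.from_series(series, seed)
    path.with_suffix(".json").write_text(meta.to_json())


def read_series(path) -> FocalSeries:
    """Read an MRC stack + JSON sidecar back into a FocalSeries."""
    path = Path(path)
    stack, pixel = read_mrc(path)
    meta = SeriesMetadata.from_json(path.with_suffix(".json").read_text())
    geom = SeriesGeometry(meta.n_images, meta.focal_step, meta.mid_defocus,
                          meta.astig_dev, meta.astig_angle)
    mp = MicroscopeParams(meta.voltage, meta.cs, meta.amp_phase)
    return FocalSeries(stack, meta.pixel or pixel, geom, mp, provenance=meta.provenance)
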