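"""Volumes, masks and flow fields on disk and in memory.

Conventions used throughout the package:

* Axis order is ``(Z, Y, X)`` for 3D data and ``(Y, X)`` for 2D data,
  matching the page-major layout of multi-page TIFF stacks.
* Voxel indices are 0-based and voxel centers sit at integer coordinates.
* ``Volume.scale`` is the physical voxel size per axis (e.g. micrometres).
  Physical/"isotropic" coordinates are index offsets multiplied by the
  scale normalized so the smallest axis scale equals 1 — a displacement of
  one voxel along the finest-sampled axis is one isotropic unit.
* Displacement vectors are stored in voxel units of the finest pyramid
  level, component order matching the axis order.  The flow ``u`` maps
  source coordinates into the target volume, i.e. the brightness-constancy
  residual is ``I_s(x) - I_t(x + u)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Volume",
    "Mask",
    "FlowField",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_label_volume",
    "write_label_volume",
    "read_flow_field",
    "write_flow_field",
]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as the expected format."""


@dataclass
class Volume:
    """A scalar intensity grid with per-axis physical voxel size.

    Parameters
    ----------
    data
        Intensity grid, ``(Z, Y, X)`` or ``(Y, X)``, floating point.
    scale
        Physical size of one voxel along each axis, same length as
        ``data.ndim``; all entries strictly positive.
    dtype_origin
        Tag recording the source bit depth (e.g. ``"uint16"``).
    """

    data: np.ndarray
    scale: tuple[float, ...]
    dtype_origin: str = "float32"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise FormatError(f"expected 2D or 3D data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise FormatError(f"zero-size axis in shape {self.data.shape}")
        self.scale = tuple(float(s) for s in self.scale)
        if len(self.scale) != self.data.ndim:
            raise ValueError(
                f"scale has {len(self.scale)} entries for {self.data.ndim}D data"
            )
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scale entries must be positive, got {self.scale}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def iso_scale(self) -> np.ndarray:
        """Per-axis scale normalized so the smallest entry is 1."""
        s = np.asarray(self.scale, dtype=float)
        return s / s.min()


@dataclass
class Mask:
    """Boolean foreground mask paired with a :class:`Volume` shape."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def fraction_fg(self) -> float:
        return float(self.data.mean())

    def validate_against(self, vol: Volume) -> None:
        if self.data.shape != vol.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match volume {vol.shape}"
            )


@dataclass
class FlowField:
    """Per-voxel displacement field in finest-level voxel units.

    ``vectors`` has shape ``(ndim, *spatial)`` with one component per
    spatial axis in axis order.  Background voxels carry a zero vector and
    ``valid == False``.
    """

    vectors: np.ndarray
    valid: np.ndarray
    scale: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        nd = self.valid.ndim
        if self.vectors.shape != (nd, *self.valid.shape):
            raise ValueError(
                f"vectors shape {self.vectors.shape} incompatible with "
                f"valid grid {self.valid.shape}"
            )
        if not self.scale:
            self.scale = (1.0,) * nd
        bg = ~self.valid
        if np.any(self.vectors[:, bg] != 0):
            raise ValueError("background voxels must carry zero displacement")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.valid.shape

    @property
    def ndim(self) -> int:
        return self.valid.ndim


def read_volume(path: str | Path, scale: tuple[float, ...] | None = None) -> Volume:
    """Read a single- or multi-page grayscale TIFF into a :class:`Volume`.

    Intensities are cast to floating point without rescaling.  ``scale``
    defaults to unit voxels.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error classes vary
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.squeeze(np.asarray(data))
    if data.ndim not in (2, 3):
        raise FormatError(f"{path}: expected 2D/3D grayscale, got shape {data.shape}")
    origin = str(data.dtype)
    if scale is None:
        scale = (1.0,) * data.ndim
    return Volume(data.astype(np.float64), scale, dtype_origin=origin)


def write_volume(vol: Volume, path: str | Path, dtype=np.float32) -> None:
    tifffile.imwrite(Path(path), np.asarray(vol.data, dtype=dtype),
                     photometric="minisblack")


def read_mask(path: str | Path) -> Mask:
    """Read a binary/label TIFF as a mask (nonzero means foreground)."""
    data = tifffile.imread(Path(path))
    return Mask(np.squeeze(np.asarray(data)) != 0)


def read_label_volume(path: str | Path) -> np.ndarray:
    """Read an integer label TIFF; label 0 is background."""
    data = np.squeeze(np.asarray(tifffile.imread(Path(path))))
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: labels must be integer valued")
        data = np.round(data).astype(np.int32)
    if data.min() < 0:
        raise ValueError(f"{path}: negative labels are not allowed")
    return data.astype(np.int32)


def write_label_volume(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("negative labels are not allowed")
    tifffile.imwrite(Path(path), labels.astype(np.int32),
                     photometric="minisblack")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_flow_field(flow: FlowField, path: str | Path) -> None:
    """Write a flow field as a multi-channel float32 TIFF plus JSON sidecar.

    Channel ``c`` of the TIFF is the displacement component along spatial
    axis ``c`` (axis order as in :class:`Volume`).  The validity mask is
    stored as one extra trailing uint-like channel (0/1), and the sidecar
    records the axis order, units and channel layout so the file is
    self-describing.
    """
    path = Path(path)
    nd = flow.ndim
    channels = np.concatenate(
        [flow.vectors.astype(np.float32), flow.valid[None].astype(np.float32)], axis=0
    )
    tifffile.imwrite(path, channels, photometric="minisblack")
    header = {
        "format": "svflow-flow-field",
        "axis_order": "ZYX"[-nd:],
        "units": "voxels (finest pyramid level)",
        "channels": ["u_" + a for a in "ZYX"[-nd:].lower()] + ["valid"],
        "valid_convention": "last channel: 1 foreground / 0 background (zero vector)",
        "scale": list(flow.scale),
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=2))


def read_flow_field(path: str | Path) -> FlowField:
    """Invert :func:`write_flow_field` (lossless at float32)."""
    path = Path(path)
    channels = np.asarray(tifffile.imread(path), dtype=np.float64)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing flow sidecar {side}")
    header = json.loads(side.read_text())
    if header.get("format") != "svflow-flow-field":
        raise FormatError(f"{side}: not a svflow flow header")
    nd = channels.shape[0] - 1
    valid = channels[-1] != 0
    vectors = channels[:-1]
    vectors[:, ~valid] = 0.0
    return FlowField(vectors, valid, scale=tuple(header.get("scale", ())))
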