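"""Core volumetric data model and OME-TIFF I/O.

A :class:`Volume3D` is a 3-D scalar grid indexed ``(z, y, x)`` with a
physical voxel spacing ``(dz, dy, dx)`` in micrometres and a semantic
channel label.  All pipeline stages (registration, birefringence mapping,
colocalization, segmentation) exchange data through this container, so the
axis convention is fixed here once: axis 0 is the optical axis (depth),
axes 1 and 2 are the lateral image axes, indices are 0-based, and regions
of interest are half-open on every axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

__all__ = [
    "CHANNELS",
    "DEFAULT_SPACING",
    "Volume3D",
    "Mask3D",
    "Mask2D",
    "ROI",
    "read_volume",
    "write_volume",
    "mip",
]

#: Recognised semantic channel labels.
CHANNELS = ("ri_vertical", "ri_horizontal", "birefringence", "fluorescence", "mask")

#: Fallback voxel spacing (dz, dy, dx) in µm, taken from the instrument's
#: nominal axial/lateral resolution (0.22 µm axial, 0.11 µm lateral).  Real
#: sampling may differ from optical resolution, so this is always overridable.
DEFAULT_SPACING = (0.22, 0.11, 0.11)

#: Physically plausible refractive-index range for hydrated cellular material.
RI_RANGE = (1.30, 1.45)


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar volume with physical voxel spacing.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``.  Stored as float64 except for the
        ``mask`` channel which may be any integer/bool dtype with values
        in ``{0, 1}``.
    spacing
        Voxel size ``(dz, dy, dx)`` in µm; all components must be positive.
    channel
        One of :data:`CHANNELS`.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = DEFAULT_SPACING
    channel: str = "ri_vertical"

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"not a 3D stack: got {data.ndim} dimension(s)")
        if min(data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.channel in ("ri_vertical", "ri_horizontal"):
            lo, hi = float(np.min(data)), float(np.max(data))
            if lo < RI_RANGE[0] or hi > RI_RANGE[1]:
                raise ValueError(
                    f"RI values [{lo:.4f}, {hi:.4f}] outside plausible range {RI_RANGE}"
                )
        elif self.channel == "birefringence":
            if float(np.min(data)) < 0:
                raise ValueError("birefringence values must be >= 0")
        elif self.channel == "mask":
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray, channel: Optional[str] = None) -> "Volume3D":
        """Return a copy with new data (and optionally a new channel label)."""
        return replace(self, data=data, channel=channel or self.channel)


@dataclass(frozen=True)
class Mask3D:
    """Binary 3-D mask sharing the shape/spacing contract of its source volume."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("Mask3D requires a 3D array")
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            data = data.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing components must be > 0")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def count(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass(frozen=True)
class Mask2D:
    """Binary 2-D mask (e.g. a thresholded maximum-intensity projection)."""

    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("Mask2D requires a 2D array")
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            data = data.astype(bool)
        object.__setattr__(self, "data", data)

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region of interest with half-open, 0-based index ranges."""

    z: Tuple[int, int]
    y: Tuple[int, int]
    x: Tuple[int, int]

    def __post_init__(self):
        for name, (lo, hi) in zip("zyx", (self.z, self.y, self.x)):
            if lo < 0 or hi <= lo:
                raise ValueError(f"ROI {name}-range [{lo}, {hi}) is empty or negative")

    @classmethod
    def full(cls, shape: Tuple[int, int, int]) -> "ROI":
        return cls((0, shape[0]), (0, shape[1]), (0, shape[2]))

    def validate(self, shape: Tuple[int, int, int]) -> None:
        for name, (lo, hi), n in zip("zyx", (self.z, self.y, self.x), shape):
            if hi > n:
                raise ValueError(f"ROI {name}-range [{lo}, {hi}) exceeds extent {n}")

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return (slice(*self.z), slice(*self.y), slice(*self.x))

    def extract(self, data: np.ndarray) -> np.ndarray:
        if data.ndim != 3:
            raise ValueError("ROI.extract expects a 3D array")
        self.validate(data.shape)
        return data[self.slices]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


def read_volume(
    path,
    spacing_override: Optional[Tuple[float, float, float]] = None,
    channel: str = "ri_vertical",
) -> Volume3D:
    """Read a single-channel 3-D stack from a (OME-)TIFF file.

    Spacing is taken from OME ``PhysicalSizeZ/Y/X`` metadata when present,
    else from ``spacing_override``, else :data:`DEFAULT_SPACING`.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        spacing = None
        if tf.is_ome and tf.ome_metadata:
            try:
                meta = tifffile.xml2dict(tf.ome_metadata)
                image = meta["OME"]["Image"]
                if isinstance(image, list):
                    image = image[0]
                px = image["Pixels"]
                sz = px.get("PhysicalSizeZ")
                sy = px.get("PhysicalSizeY")
                sx = px.get("PhysicalSizeX")
                if sz is not None and sy is not None and sx is not None:
                    spacing = (float(sz), float(sy), float(sx))
            except (KeyError, TypeError):
                spacing = None
    data = np.asarray(data)
    if data.ndim == 4 and data.shape[0] == 1:
        data = data[0]
    if data.ndim == 2:
        raise ValueError(f"{path}: not a 3D stack (2D image)")
    if data.ndim != 3:
        raise ValueError(
            f"{path}: not a 3D stack (got {data.ndim} dimensions; "
            "multi-channel stacks require channel selection upstream)"
        )
    if spacing is None:
        spacing = spacing_override if spacing_override is not None else DEFAULT_SPACING
    if any(s <= 0 for s in spacing):
        raise ValueError(f"nonpositive spacing {spacing}")
    return Volume3D(data=np.asarray(data, dtype=np.float64), spacing=tuple(spacing), channel=channel)


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as OME-TIFF with spacing metadata.

    ``read_volume(write_volume(v))`` is the identity on data and spacing.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    dz, dy, dx = volume.spacing
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def mip(volume: Volume3D, axis: str = "z", roi: Optional[ROI] = None) -> np.ndarray:
    """Maximum-intensity projection along one axis, optionally within an ROI.

    Returns the 2-D array of per-pixel maxima over the projected axis.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of 'z', 'y', 'x'; got {axis!r}")
    data = volume.data
    if roi is not None:
        data = roi.extract(data)
        if data.size == 0:
            raise ValueError("empty ROI")
    return np.max(data, axis=_AXIS_INDEX[axis])
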