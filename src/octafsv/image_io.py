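"""Reading/writing en-face OCTA slab images and their acquisition metadata.

Conventions used throughout the package:

* images are square, 8-bit, single-channel rasters; ``pixels[0, 0]`` is the
  top-left corner of the en-face view and coordinates are 0-based
  ``(row, column)``;
* acquisition metadata travels in a sidecar manifest (CSV), never in image
  headers, so plain PNG/TIFF files can be used as fixtures and outputs;
* the physical pixel pitch is ``fov_mm * 1000 / grid_px`` micrometres
  (12 um for the default 6x6 mm, 500x500-pixel macular scan) and the area of
  one pixel is the square of the pitch (144 um^2 at defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "Group",
    "Slab",
    "ScanMeta",
    "EnFaceScan",
    "read_scan",
    "write_scan",
    "write_mask",
    "read_mask",
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
]


class Group(str, Enum):
    """Study group: eyes with active central serous chorioretinopathy vs the
    clinically unaffected fellow eyes."""

    CSCR = "CSCR"
    FELLOW = "fellow"


class Slab(str, Enum):
    """En-face depth window, projected by the device.

    The three windows, measured below the retinal pigment epithelium, are
    inner choriocapillaris (4-20 um), outer choriocapillaris (29-49 um) and
    choroid (64-115 um).  Stored as descriptive metadata only; slab
    segmentation itself happens on the device.
    """

    INNER_CC = "inner_CC"
    OUTER_CC = "outer_CC"
    CHOROID = "choroid"


#: Depth window below the RPE for each slab, in micrometres (descriptive only).
SLAB_DEPTH_UM: dict[Slab, tuple[float, float]] = {
    Slab.INNER_CC: (4.0, 20.0),
    Slab.OUTER_CC: (29.0, 49.0),
    Slab.CHOROID: (64.0, 115.0),
}


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition metadata for one en-face slab image."""

    eye_id: str
    group: Group
    slab: Slab
    repeat_index: int
    fov_mm: float = 6.0
    grid_px: int = 500

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "slab", Slab(self.slab))
        if self.repeat_index not in (1, 2):
            raise ValidationError(
                f"repeat_index must be 1 or 2, got {self.repeat_index!r}"
            )
        if not self.fov_mm > 0:
            raise ValidationError(f"fov_mm must be positive, got {self.fov_mm!r}")
        if not (isinstance(self.grid_px, (int, np.integer)) and self.grid_px > 0):
            raise ValidationError(f"grid_px must be a positive integer, got {self.grid_px!r}")

    @property
    def pixel_pitch_um(self) -> float:
        """Physical side of one pixel in micrometres (12.0 at defaults)."""
        return self.fov_mm * 1000.0 / self.grid_px

    @property
    def pixel_area_um2(self) -> float:
        """Physical area of one pixel in um^2 (144.0 at defaults)."""
        return self.pixel_pitch_um ** 2


@dataclass(frozen=True)
class EnFaceScan:
    """One grayscale en-face slab image plus its acquisition metadata."""

    meta: ScanMeta
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValidationError(f"image must be square 2-D, got shape {px.shape}")
        if px.shape[0] != self.meta.grid_px:
            raise ValidationError(
                f"image shape {px.shape} does not match meta.grid_px={self.meta.grid_px}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError(f"pixels must be integer-typed, got {px.dtype}")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValidationError("pixel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceScan":
        """Return a copy of this scan carrying new pixel data."""
        return replace(self, pixels=pixels)


PathLike = Union[str, Path]


def _collapse_channels(arr: np.ndarray, path: PathLike) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        first = arr[..., 0]
        if all(np.array_equal(arr[..., c], first) for c in range(1, arr.shape[-1])):
            return first
        raise ValidationError(
            f"{path}: multi-channel image with non-identical channels; "
            "expected grayscale content"
        )
    raise ValidationError(f"{path}: unsupported raster dimensionality {arr.ndim}")


def read_scan(image_path: PathLike, meta: ScanMeta) -> EnFaceScan:
    """Read an 8-bit grayscale PNG/TIFF en-face image.

    Multi-channel files whose channels are all identical (gray stored as RGB)
    are collapsed to one channel.  The raster must be square and match
    ``meta.grid_px``.
    """
    arr = iio.imread(image_path)
    arr = _collapse_channels(np.asarray(arr), image_path)
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValidationError(f"{image_path}: expected 8-bit pixel data, got {arr.dtype}")
    return EnFaceScan(meta=meta, pixels=arr)


def write_scan(scan: EnFaceScan, path: PathLike) -> None:
    """Write a scan as an 8-bit grayscale image (format chosen by extension)."""
    iio.imwrite(path, scan.pixels)


def write_mask(mask, path: PathLike) -> None:
    """Persist a binary void mask as an 8-bit image: void = 255, background = 0.

    The round trip through :func:`read_mask` is bit-exact.
    """
    arr = np.where(np.asarray(mask.pixels, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, arr)


def read_mask(path: PathLike) -> np.ndarray:
    """Read a mask image written by :func:`write_mask` back to a boolean array."""
    arr = _collapse_channels(np.asarray(iio.imread(path)), path)
    return arr > 127


MANIFEST_COLUMNS = [
    "eye_id",
    "group",
    "slab",
    "repeat_index",
    "image_path",
    "fov_mm",
    "grid_px",
]


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its schema."""
    df = pd.read_csv(path, dtype={"eye_id": str, "image_path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} is missing columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: PathLike) -> None:
    """Write a cohort manifest CSV in the canonical column order."""
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest frame is missing columns {missing}")
    df.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)


def meta_from_manifest_row(row) -> ScanMeta:
    """Build a :class:`ScanMeta` from one manifest row (mapping-like)."""
    return ScanMeta(
        eye_id=str(row["eye_id"]),
        group=Group(row["group"]),
        slab=Slab(row["slab"]),
        repeat_index=int(row["repeat_index"]),
        fov_mm=float(row["fov_mm"]),
        grid_px=int(row["grid_px"]),
    )
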