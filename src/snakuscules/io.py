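"""Image loading, normalization, and anisotropy resampling."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile

__all__ = ["ImageVolume", "load_volume", "save_volume", "resample_isotropic"]


@dataclass
class ImageVolume:
    """A 2D or 3D scalar intensity grid, normalized to [0, 1].

    ``spacing`` is the physical voxel size per axis (same order as the
    array axes, z first for volumes); ``orig_min``/``orig_max`` record the
    intensity range before normalization.
    """

    data: np.ndarray
    spacing: Optional[Tuple[float, ...]] = None
    orig_min: float = 0.0
    orig_max: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError("only 2D and 3D images are supported")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.data.ndim:
                raise ValueError("spacing must have one entry per axis")
            if any(s <= 0 for s in self.spacing):
                raise ValueError("spacing must be positive")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape


def _normalize(arr: np.ndarray) -> Tuple[np.ndarray, float, float]:
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo), lo, hi
    # degenerate range: constant image maps to all zeros
    return np.zeros_like(arr, dtype=np.float64), lo, hi


def load_volume(
    path,
    spacing: Optional[Sequence[float]] = None,
    rgb_to_gray: bool = False,
) -> ImageVolume:
    """Read a single- or multi-page TIFF (or PNG) as a normalized volume."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    # multi-page stacks are page-first; a trailing axis of 3/4 means color
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and min(arr.shape[:2]) > 4:
        if not rgb_to_gray:
            raise ValueError(
                f"{path} looks like a color image; pass rgb_to_gray=True to "
                "convert to luminance"
            )
        arr = arr[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    data, lo, hi = _normalize(arr.astype(np.float64))
    return ImageVolume(data=data, spacing=spacing, orig_min=lo, orig_max=hi)


def save_volume(path, image, spacing: Optional[Sequence[float]] = None) -> None:
    """Write a float32 (multi-page) TIFF."""
    arr = np.asarray(getattr(image, "data", image), dtype=np.float32)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def resample_isotropic(vol: ImageVolume) -> ImageVolume:
    """Linearly interpolate the axial (first) axis to the lateral spacing.

    Lateral axes are untouched; the new axial size is
    ``round(old_size * spacing_ratio)``.  Requires known spacing.
    """
    if vol.spacing is None:
        raise ValueError("resampling requires voxel spacing")
    if vol.ndim == 2:
        return vol
    sz, sy, sx = vol.spacing
    if not np.isclose(sy, sx):
        raise ValueError("lateral spacings must be equal")
    ratio = sz / sx
    if np.isclose(ratio, 1.0):
        return vol
    nz = vol.shape[0]
    new_nz = int(round(nz * ratio))
    # positions of the new planes in original z-index units
    z_pos = np.arange(new_nz) / ratio
    zi = np.minimum(np.floor(z_pos).astype(int), nz - 1)
    zf = z_pos - zi
    zi1 = np.minimum(zi + 1, nz - 1)
    data = (1.0 - zf)[:, None, None] * vol.data[zi] + zf[:, None, None] * vol.data[zi1]
    return ImageVolume(
        data=data,
        spacing=(sx, sy, sx),
        orig_min=vol.orig_min,
        orig_max=vol.orig_max,
    )
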