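"""Reading, writing and preparing 3-D voxel stacks.

The substrate of every measurement in this package is a :class:`VoxelImage`:
a 3-D scalar grid with isotropic voxel spacing.  Stacks are stored in the
usual multi-page TIFF layout, so ``data`` is indexed ``(z, y, x)`` — plane,
row, column — matching what :func:`tifffile.imread` returns.  Voxels are
centered on integer indices; the physical position of voxel ``(k, j, i)`` is
``(k + 0.5, j + 0.5, i + 0.5) * spacing``.

Binary images use the convention foreground = 255, background = 0, which all
downstream modules rely on.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import tifffile

FOREGROUND = 255
BACKGROUND = 0

__all__ = [
    "FOREGROUND",
    "BACKGROUND",
    "VoxelImage",
    "read_stack",
    "write_stack",
    "isodata_threshold",
    "binarize",
    "block_resample",
    "crop",
]


@dataclass
class VoxelImage:
    """A 3-D image with isotropic voxel spacing.

    Parameters
    ----------
    data
        3-D array indexed ``(z, y, x)``.  Usually ``uint8`` (0–255);
        block-resampled images carry float block means.
    spacing
        Isotropic voxel edge length in physical units (μm for micro-CT
        data; 1.0 means "voxel units").
    """

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D stack, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValueError(f"non-numeric voxel data ({self.data.dtype})")
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Shape ``(nz, ny, nx)`` in voxels."""
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def is_binary(self) -> bool:
        """True when the value set is contained in {0, 255}."""
        return bool(np.isin(np.unique(self.data), (BACKGROUND, FOREGROUND)).all())

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data == FOREGROUND))

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.data.copy(), self.spacing)


def read_stack(path: str | os.PathLike, spacing: float = 1.0) -> VoxelImage:
    """Read a multi-page 8-bit TIFF into a :class:`VoxelImage`.

    Pages become z-planes; a single-page file yields ``nz = 1``.  Mixed page
    sizes or a non-8-bit sample format are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image stack: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"mixed page sizes in {path}: {sorted(shapes)}")
        dtypes = {page.dtype for page in tif.pages}
        if dtypes != {np.dtype(np.uint8)}:
            raise ValueError(
                f"unsupported bit depth in {path}: {sorted(map(str, dtypes))} (8-bit only)"
            )
        data = tif.asarray()
    if data.ndim == 2:
        data = data[np.newaxis]
    return VoxelImage(data, spacing=spacing)


def write_stack(img: VoxelImage, path: str | os.PathLike) -> None:
    """Write a stack as multi-page TIFF (uint8 for 8-bit data, float32 otherwise)."""
    data = img.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)


def isodata_threshold(img: VoxelImage) -> float:
    """IsoData (Ridler–Calvard) automatic threshold.

    Starting from mid-range, iterate ``t <- (mean(values <= t) +
    mean(values > t)) / 2`` to a fixed point.  On integer images the floor
    of the converged value is returned, matching integer-histogram
    implementations; a constant image has no separable classes and raises.
    """
    values = img.data.ravel().astype(np.float64)
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError("constant image: no separable classes for IsoData")
    t = (vmin + vmax) / 2.0
    for _ in range(1000):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = (lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < 1e-9:
            t = t_new
            break
        t = t_new
    if np.issubdtype(img.data.dtype, np.integer):
        return float(math.floor(t))
    return float(t)


def binarize(img: VoxelImage, threshold: float = 128) -> VoxelImage:
    """Threshold to a binary 0/255 image; voxels >= threshold become foreground."""
    out = np.where(img.data >= threshold, FOREGROUND, BACKGROUND).astype(np.uint8)
    return VoxelImage(out, img.spacing)


def _block_sums_and_counts(arr: np.ndarray, factor: int, axis: int):
    n = arr.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(arr, starts, axis=axis)
    counts = np.minimum(starts + factor, n) - starts
    return sums, counts


def block_resample(img: VoxelImage, factor: int) -> VoxelImage:
    """Downsample by averaging ``factor``³ blocks of voxels.

    Trailing partial blocks are averaged over the voxels actually present.
    Spacing is multiplied by ``factor``.  ``factor == 1`` is the identity.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"resample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return img.copy()
    sums = img.data.astype(np.float64)
    count_axes = []
    for axis in range(3):
        sums, counts = _block_sums_and_counts(sums, factor, axis)
        count_axes.append(counts)
    total = (
        count_axes[0][:, None, None]
        * count_axes[1][None, :, None]
        * count_axes[2][None, None, :]
    )
    return VoxelImage(sums / total, img.spacing * factor)


def crop(img: VoxelImage, lo: tuple[int, int, int], hi: tuple[int, int, int]) -> VoxelImage:
    """Rectangular volume-of-interest crop, half-open bounds ``lo <= idx < hi``."""
    lo = tuple(int(v) for v in lo)
    hi = tuple(int(v) for v in hi)
    for a in range(3):
        if not (0 <= lo[a] < hi[a] <= img.data.shape[a]):
            raise ValueError(f"crop bounds {lo}..{hi} outside stack {img.data.shape}")
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return VoxelImage(img.data[sl].copy(), img.spacing)
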