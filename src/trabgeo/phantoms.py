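"""Synthetic binary phantoms with known analytic geometry.

Every measurement in this package is validated against shapes whose surface
area, volume and curvature are known in closed form: the solid sphere,
cylindrical rod and flat plate are the three primitives whose shape-index
values (4, 3 and 0) anchor the scale.  The lattice phantom — orthogonal
plates pierced by rods — produces the concave saddle junctions typical of a
trabecular continuum, and the pseudo-trabecular phantom is a seeded,
low-pass-filtered noise field thresholded to a prescribed bone volume
fraction, standing in for real micro-CT stacks in resorption simulations.

Foreground membership is decided on voxel centers (a voxel is foreground iff
its center satisfies the analytic inequality), so every phantom can be
checked exactly against brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image_io import BACKGROUND, FOREGROUND, VoxelImage

__all__ = [
    "make_sphere",
    "make_cylinder",
    "make_plate",
    "make_lattice",
    "make_pseudo_trabecular",
]


def _as_dims(dims) -> tuple[int, int, int]:
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or min(dims) < 1:
        raise ValueError(f"dims must be three positive integers, got {dims}")
    return dims


def _binary(mask: np.ndarray, spacing: float = 1.0) -> VoxelImage:
    return VoxelImage(np.where(mask, FOREGROUND, BACKGROUND).astype(np.uint8), spacing)


def make_sphere(radius: float, dims=(100, 100, 100), spacing: float = 1.0) -> VoxelImage:
    """Solid ball centered in the stack.

    A voxel is foreground iff its center lies within ``radius`` of the image
    center point.  The ball must fit with a margin of at least 2 voxels to
    every stack face.
    """
    dims = _as_dims(dims)
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if any(radius + 2 > (d - 1) / 2 for d in dims):
        raise ValueError(f"sphere radius {radius} does not fit in {dims} with 2-voxel margin")
    center = (np.array(dims, dtype=float) - 1) / 2
    zz, yy, xx = np.indices(dims, dtype=np.float64)
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return _binary(d2 <= radius**2, spacing)


def _disc_mask(shape2d, center, radius) -> np.ndarray:
    uu, vv = np.indices(shape2d, dtype=np.float64)
    return (uu - center[0]) ** 2 + (vv - center[1]) ** 2 <= radius**2


def make_cylinder(
    radius: float, dims=(128, 64, 64), axis: int = 0, spacing: float = 1.0
) -> VoxelImage:
    """Solid circular cylinder spanning the full stack extent along ``axis``.

    The disc cross-section is centered in the perpendicular plane and must
    leave at least a 1-voxel background margin laterally.
    """
    dims = _as_dims(dims)
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    perp = [a for a in range(3) if a != axis]
    if any(radius + 1 > (dims[a] - 1) / 2 for a in perp):
        raise ValueError(f"cylinder radius {radius} does not fit laterally in {dims}")
    shape2d = (dims[perp[0]], dims[perp[1]])
    center = ((shape2d[0] - 1) / 2, (shape2d[1] - 1) / 2)
    disc = _disc_mask(shape2d, center, radius)
    mask = np.broadcast_to(np.expand_dims(disc, axis), dims).copy()
    return _binary(mask, spacing)


def make_plate(
    thickness: int, dims=(64, 128, 128), normal_axis: int = 0, spacing: float = 1.0
) -> VoxelImage:
    """Slab of ``thickness`` voxels centered along ``normal_axis``, full lateral span."""
    dims = _as_dims(dims)
    thickness = int(thickness)
    if thickness <= 0:
        raise ValueError(f"thickness must be >= 1, got {thickness}")
    if normal_axis not in (0, 1, 2):
        raise ValueError(f"normal_axis must be 0, 1 or 2, got {normal_axis}")
    n = dims[normal_axis]
    if thickness > n:
        raise ValueError(f"thickness {thickness} exceeds stack extent {n}")
    start = (n - thickness) // 2
    mask = np.zeros(dims, dtype=bool)
    sl = [slice(None)] * 3
    sl[normal_axis] = slice(start, start + thickness)
    mask[tuple(sl)] = True
    return _binary(mask, spacing)


def make_lattice(
    rod_radius: float,
    plate_thickness: int,
    cell_spacing: int,
    dims=(96, 96, 96),
    spacing: float = 1.0,
) -> VoxelImage:
    """Regular lattice of plates pierced by orthogonal rods.

    Plates are slabs normal to the z axis and rods run along z on a square
    x–y grid, both repeating every ``cell_spacing`` voxels with element
    centers at ``cell_spacing * (k + 1/2)``.  Where a rod meets a plate the
    surface forms a concave saddle junction, the feature that drives the
    negative component of the structure model index.  ``plate_thickness = 0``
    gives rods only; ``rod_radius = 0`` gives plates only.
    """
    dims = _as_dims(dims)
    cell_spacing = int(cell_spacing)
    if cell_spacing < 1:
        raise ValueError(f"cell_spacing must be >= 1, got {cell_spacing}")
    if rod_radius < 0 or plate_thickness < 0:
        raise ValueError("rod_radius and plate_thickness must be >= 0")
    if rod_radius == 0 and plate_thickness == 0:
        raise ValueError("lattice needs at least one of rods or plates")
    if rod_radius > 0 and cell_spacing < 2 * rod_radius:
        raise ValueError(
            f"cell_spacing {cell_spacing} smaller than rod diameter {2 * rod_radius}"
        )
    if plate_thickness > 0 and cell_spacing < plate_thickness:
        raise ValueError(
            f"cell_spacing {cell_spacing} smaller than plate thickness {plate_thickness}"
        )
    mask = np.zeros(dims, dtype=bool)
    if plate_thickness > 0:
        # plate occupies the first plate_thickness planes of every cell, so any
        # integer thickness is realized exactly
        zz = np.arange(dims[0])
        mask[(zz % cell_spacing) < plate_thickness, :, :] = True
    if rod_radius > 0:
        disc_union = np.zeros((dims[1], dims[2]), dtype=bool)
        centers = np.arange(cell_spacing / 2 - 0.5, max(dims[1], dims[2]), cell_spacing)
        for yc in centers[centers < dims[1]]:
            for xc in centers[centers < dims[2]]:
                disc_union |= _disc_mask((dims[1], dims[2]), (yc, xc), rod_radius)
        mask |= disc_union[np.newaxis, :, :]
    return _binary(mask, spacing)


def make_pseudo_trabecular(
    dims=(160, 160, 160),
    target_bvtv: float = 0.44,
    correlation_length: float = 16.0,
    seed: int = 0,
    spacing: float = 1.0,
) -> VoxelImage:
    """Seeded Gaussian random field thresholded to a target bone volume fraction.

    White noise is low-pass filtered with a Gaussian kernel of standard
    deviation ``correlation_length`` (voxels) and thresholded at the quantile
    that leaves ``target_bvtv`` of the voxels foreground, producing a smooth,
    connected two-phase structure with abundant concave junctions.  The
    defaults emulate the substrate of a resorption simulation: a high volume
    fraction (0.44) and a correlation length of 16 voxels, giving element
    diameters around twice that — thick enough that no element vanishes over
    an 8-step single-voxel erosion series, the regime deliberately chosen
    for erosion experiments on real trabeculae.  Deterministic in ``(dims,
    target_bvtv, correlation_length, seed)``.
    """
    dims = _as_dims(dims)
    if not (0 < target_bvtv < 1):
        raise ValueError(f"target_bvtv must lie in (0, 1), got {target_bvtv}")
    if correlation_length <= 0:
        raise ValueError(f"correlation_length must be > 0, got {correlation_length}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(dims)
    field = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    thr = np.quantile(field, 1.0 - target_bvtv)
    mask = field >= thr
    bvtv = mask.mean()
    if abs(bvtv - target_bvtv) > 0.01:
        raise ValueError(
            f"could not reach BV/TV {target_bvtv} on dims {dims} (got {bvtv:.3f}); "
            "the field is too coarse for these dims"
        )
    return _binary(mask, spacing)
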