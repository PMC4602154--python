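"""Structure model index with its positive/negative decomposition and concave fraction.

The structure model index (SMI) compares the surface-area change of a
structure under an infinitesimal dilation to its volume:

    SMI = 6 * (S'/r) * V / S**2

where ``S`` is the surface area of a triangle mesh fitted to the structure,
``S'`` the total change in area after the mesh is dilated a short distance
``r`` along the vertex normals, and ``V`` the structure volume.  Ideal convex
bodies give 0 (plate), 3 (rod) and 4 (sphere).

On concave surface regions triangles *shrink* during dilation, contributing
negatively to ``S'``.  Expanding the sum over triangles and grouping
per-triangle area changes ``s_i`` by sign yields the decomposition

    SMI = SMI+ + SMI-,

where SMI+ collects the convex (growing) triangles and SMI- the concave
(shrinking) ones.  The concave fraction ``CF = U / S`` is the share of the
original surface area carried by shrinking triangles.  A trabecular
continuum has abundant concave junctions, so SMI- is far from zero on real
bone and drags SMI along with bone volume fraction — the decomposition makes
that contamination measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import FOREGROUND, VoxelImage
from .meshing import (
    TriangleMesh,
    export_mesh,
    marching_cubes,
    mesh_area,
    mesh_volume,
    vertex_normals,
)

__all__ = [
    "TriangleDeltas",
    "SMIResult",
    "dilate_mesh",
    "triangle_deltas",
    "compute_smi",
    "classify_and_color",
    "export_colored_mesh",
    "DEFAULT_DILATION_FRACTION",
]

# dilation distance as a fraction of the voxel spacing: small enough for the
# derivative limit S'/r, large enough to keep the per-triangle area
# differences clear of floating-point cancellation
DEFAULT_DILATION_FRACTION = 0.005

CONVEX, FLAT, CONCAVE = "convex", "flat", "concave"


@dataclass
class TriangleDeltas:
    """Per-triangle area bookkeeping for one mesh dilation.

    ``delta[i] = dilated_area[i] - original_area[i]`` is triangle *i*'s
    contribution to the overall change in surface area; its sign classifies
    the local curvature (positive = convex, negative = concave).
    """

    original_area: np.ndarray
    dilated_area: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.dilated_area - self.original_area

    @property
    def n_faces(self) -> int:
        return len(self.original_area)


@dataclass
class SMIResult:
    """All quantities of one structure-model-index measurement.

    Areas are in squared physical units, ``V`` in cubed physical units,
    ``r`` in physical units; ``smi``, ``smi_plus``, ``smi_minus`` and ``cf``
    are dimensionless.  ``U`` is the original area of the shrinking
    (concave) triangles, so ``cf = U / S``.
    """

    S: float
    S_prime: float
    r: float
    V: float
    smi: float
    smi_plus: float
    smi_minus: float
    U: float
    cf: float
    n_convex: int
    n_flat: int
    n_concave: int

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "S_prime": self.S_prime,
            "r": self.r,
            "V": self.V,
            "smi": self.smi,
            "smi_plus": self.smi_plus,
            "smi_minus": self.smi_minus,
            "U": self.U,
            "cf": self.cf,
            "n_convex": self.n_convex,
            "n_flat": self.n_flat,
            "n_concave": self.n_concave,
        }


def dilate_mesh(mesh: TriangleMesh, r: float) -> TriangleMesh:
    """Translate every vertex a distance ``r`` along its unit vertex normal.

    Connectivity is unchanged; convex regions grow, concave regions shrink.
    """
    if not (r > 0):
        raise ValueError(f"dilation distance must be > 0, got {r}")
    normals = vertex_normals(mesh)
    return TriangleMesh(mesh.vertices + r * normals, mesh.faces.copy())


def triangle_deltas(mesh: TriangleMesh, dilated: TriangleMesh) -> TriangleDeltas:
    """Per-triangle area change between a mesh and its dilated copy."""
    if mesh.n_faces != dilated.n_faces or not np.array_equal(mesh.faces, dilated.faces):
        raise ValueError("original and dilated meshes must share the same face list")
    return TriangleDeltas(mesh.face_areas(), dilated.face_areas())


def _smi_from_deltas(deltas: TriangleDeltas, r: float, V: float) -> SMIResult:
    A = deltas.original_area
    d = deltas.delta
    S = float(A.sum())
    S_prime = float(d.sum())
    scale = 6.0 * V / (r * S**2)
    pos = d > 0
    neg = d < 0
    smi_plus = scale * float(d[pos].sum())
    smi_minus = scale * float(d[neg].sum())
    U = float(A[neg].sum())
    return SMIResult(
        S=S,
        S_prime=S_prime,
        r=r,
        V=V,
        smi=scale * S_prime,
        smi_plus=smi_plus,
        smi_minus=smi_minus,
        U=U,
        cf=U / S,
        n_convex=int(pos.sum()),
        n_flat=int((~pos & ~neg).sum()),
        n_concave=int(neg.sum()),
    )


def compute_smi(
    img: VoxelImage,
    r: float | None = None,
    iso: float = 128.0,
    resample_factor: int = 3,
    smoothing: float = 0.5,
    smoothing_iterations: int = 1,
    boundary: str = "capped",
    volume_mode: str = "voxel",
    return_mesh: bool = False,
):
    """Measure SMI, SMI+, SMI- and concave fraction of a binary stack.

    The stack is meshed (marching cubes at level ``iso`` after block
    resampling, then Laplacian smoothing), the mesh is dilated by ``r``
    (default ``0.005 * spacing``) along its vertex normals, and the
    per-triangle area changes are summed by sign.  ``V`` is the foreground
    voxel count times the voxel volume (``volume_mode="voxel"``, consistent
    with BV/TV) or the mesh-enclosed volume (``volume_mode="mesh"``, closed
    meshes only).

    Returns an :class:`SMIResult`; with ``return_mesh=True`` returns
    ``(result, mesh, deltas)`` so the classified surface can be exported.
    """
    if not img.is_binary():
        raise ValueError("compute_smi expects a binary 0/255 image; threshold first")
    fg = img.foreground_count()
    if fg == 0:
        raise ValueError("empty image: no foreground voxels")
    if r is None:
        r = DEFAULT_DILATION_FRACTION * img.spacing
    mesh = marching_cubes(
        img,
        iso=iso,
        resample_factor=resample_factor,
        smoothing=smoothing,
        smoothing_iterations=smoothing_iterations,
        boundary=boundary,
    )
    if volume_mode == "voxel":
        V = fg * img.voxel_volume
    elif volume_mode == "mesh":
        V = mesh_volume(mesh)
    else:
        raise ValueError(f"volume_mode must be 'voxel' or 'mesh', got {volume_mode}")
    dilated = dilate_mesh(mesh, r)
    deltas = triangle_deltas(mesh, dilated)
    result = _smi_from_deltas(deltas, r, V)
    if return_mesh:
        return result, mesh, deltas
    return result


_YELLOW = np.array([255, 255, 0], dtype=np.float64)
_BLUE = np.array([0, 0, 255], dtype=np.float64)
_WHITE = np.array([255, 255, 255], dtype=np.float64)


def classify_and_color(
    deltas: TriangleDeltas, r: float, epsilon_flat: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Classify triangles by normalized area change and assign display colors.

    The normalized change ``delta / (r * area)`` (units 1/length, an
    approximate mean-curvature scale) is compared against the flat band
    ``epsilon_flat``: above it the face is convex (yellow), below its
    negative concave (blue), inside it flat (white).  Color saturation
    encodes magnitude relative to the strongest face.  The band affects the
    visualization classes only — the concave fraction itself uses the strict
    sign of the area change.
    """
    if not (r > 0):
        raise ValueError("r must be > 0")
    A = deltas.original_area
    rel = np.zeros_like(A)
    ok = A > 0
    rel[ok] = deltas.delta[ok] / (r * A[ok])
    classes = np.full(deltas.n_faces, FLAT, dtype=object)
    classes[rel > epsilon_flat] = CONVEX
    classes[rel < -epsilon_flat] = CONCAVE
    vmax = float(np.abs(rel).max()) if deltas.n_faces else 0.0
    sat = np.abs(rel) / vmax if vmax > 0 else np.zeros_like(rel)
    colors = np.tile(_WHITE, (deltas.n_faces, 1))
    cvx = classes == CONVEX
    ccv = classes == CONCAVE
    colors[cvx] = _WHITE + sat[cvx, None] * (_YELLOW - _WHITE)
    colors[ccv] = _WHITE + sat[ccv, None] * (_BLUE - _WHITE)
    return classes, np.clip(np.round(colors), 0, 255).astype(np.uint8)


def export_colored_mesh(
    mesh: TriangleMesh, colors: np.ndarray, path: str, encoding: str = "binary"
) -> None:
    """Write the mesh as PLY with per-face RGB (curvature-class) colors."""
    colors = np.asarray(colors)
    if mesh.n_faces == 0:
        raise ValueError("refusing to export a mesh with no faces")
    if colors.shape[0] != mesh.n_faces:
        raise ValueError("one color per face required")
    export_mesh(mesh, path, face_colors=colors, encoding=encoding)
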