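"""Printable whole-bone models: cortical shell plus parameterized lattice.

Inputs are two watertight STL surfaces segmented from CT -- the outer
and inner contours of the cortical bone.  The shell (outer minus inner)
is filled between the contours; the cancellous cavity enclosed by the
inner surface is tiled with the hexagonal lattice at the calibrated
t/L; the two solids are unioned.  All Booleans run on a shared voxel
grid (occupancy for the surfaces, signed-distance field for the
struts), and the result is extracted with marching cubes as one
watertight mesh -- exact mesh CSG on segmentation-grade geometry is
fragile, voxel CSG is not.

The lattice's vertical struts are aligned with the volume's z axis,
the cranio-caudal (compression) direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .lattice import (
    LatticeSpec,
    distance_field,
    honeycomb_segments,
    mesh_from_field,
)

__all__ = [
    "CorticalPair",
    "ValidationReport",
    "validate_pair",
    "fill_with_lattice",
    "drain_holes",
    "REMESH_EDGE_MM",
    "DEFAULT_BONE_PITCH",
]

#: target edge length when remeshing segmented surfaces (mm)
REMESH_EDGE_MM = 0.8
#: default voxel pitch for whole-bone Booleans (mm)
DEFAULT_BONE_PITCH = 0.2


@dataclass
class CorticalPair:
    """Outer and inner cortical surfaces of one bone.

    Both must be watertight; the inner surface must lie strictly inside
    the outer one without touching it.
    """

    outer: trimesh.Trimesh
    inner: trimesh.Trimesh


@dataclass
class ValidationReport:
    ok: bool
    checks: dict[str, bool]
    messages: list[str] = field(default_factory=list)


def _remesh(mesh: trimesh.Trimesh, max_edge: float) -> trimesh.Trimesh:
    """Split edges longer than ``max_edge`` (longest-edge subdivision)."""
    verts, faces = trimesh.remesh.subdivide_to_size(
        mesh.vertices, mesh.faces, max_edge=max_edge
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=True)


def validate_pair(
    pair: CorticalPair, remesh_edge_mm: float | None = REMESH_EDGE_MM
) -> ValidationReport:
    """Check watertightness, containment and non-intersection.

    Optionally remeshes both surfaces to the target edge length first
    (as segmentation exports are remeshed before further processing);
    pass ``remesh_edge_mm=None`` to skip.  Containment is verified on
    the inner mesh's vertices against the outer volume; intersection is
    flagged when any outer vertex falls inside the inner volume or any
    inner vertex falls outside the outer one.
    """
    outer, inner = pair.outer, pair.inner
    if remesh_edge_mm is not None:
        outer = _remesh(outer, remesh_edge_mm)
        inner = _remesh(inner, remesh_edge_mm)
        pair.outer, pair.inner = outer, inner
    checks: dict[str, bool] = {}
    msgs: list[str] = []
    checks["outer_watertight"] = bool(outer.is_watertight)
    checks["inner_watertight"] = bool(inner.is_watertight)
    if not checks["outer_watertight"]:
        msgs.append("outer surface is not watertight")
    if not checks["inner_watertight"]:
        msgs.append("inner surface is not watertight")
    if checks["outer_watertight"] and checks["inner_watertight"]:
        pitch = float(max(outer.extents)) / 120.0
        inner_inside = _contains_points(outer, inner.vertices, pitch)
        outer_inside_inner = _contains_points(inner, outer.vertices, pitch)
        checks["containment"] = bool(inner_inside.all())
        checks["no_intersection"] = bool(
            inner_inside.all() and not outer_inside_inner.any()
        )
        if not checks["containment"]:
            n = int((~inner_inside).sum())
            msgs.append(f"{n} inner vertices outside the outer surface")
        if not checks["no_intersection"]:
            msgs.append("surfaces intersect or are swapped")
    else:
        checks["containment"] = False
        checks["no_intersection"] = False
    return ValidationReport(ok=all(checks.values()), checks=checks, messages=msgs)


def _occupancy_on_grid(
    mesh: trimesh.Trimesh, origin: np.ndarray, shape, pitch: float
) -> np.ndarray:
    """Filled-interior occupancy of a watertight mesh on a shared grid.

    The surface is subdivided until every edge is well below the pitch,
    the voxels hit by vertices and face centroids form a closed crust,
    and the interior is flood-filled.  Self-contained (no spatial-index
    dependency) and robust for closed surfaces.
    """
    verts, faces = trimesh.remesh.subdivide_to_size(
        mesh.vertices, mesh.faces, max_edge=0.5 * pitch
    )
    pts = np.vstack((verts, verts[faces].mean(axis=1)))
    idx = np.floor((pts - np.asarray(origin)) / pitch).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    occ = np.zeros(shape, dtype=bool)
    occ[tuple(idx[ok].T)] = True
    return ndimage.binary_fill_holes(occ)


def _contains_points(
    mesh: trimesh.Trimesh, points: np.ndarray, pitch: float
) -> np.ndarray:
    """Point-in-volume test against the voxelized interior of a mesh."""
    lo = mesh.bounds[0] - 2 * pitch
    hi = mesh.bounds[1] + 2 * pitch
    shape = tuple(int(math.ceil(s / pitch)) + 1 for s in hi - lo)
    occ = _occupancy_on_grid(mesh, lo, shape, pitch)
    idx = np.floor((np.atleast_2d(points) - lo) / pitch).astype(int)
    inside = np.zeros(len(idx), dtype=bool)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    inside[ok] = occ[tuple(idx[ok].T)]
    return inside


def fill_with_lattice(
    pair: CorticalPair,
    spec: LatticeSpec,
    pitch: float = DEFAULT_BONE_PITCH,
    return_stats: bool = False,
):
    """Union of the cortical shell and the lattice-filled cavity.

    The lattice is tiled over the inner surface's bounding box, clipped
    to the inner volume by voxel occupancy, and unioned with the shell
    (outer minus inner).  ``t -> 0`` degenerates to the shell alone.
    """
    report = validate_pair(pair, remesh_edge_mm=None)
    if not report.ok:
        raise ValueError("invalid cortical pair: " + "; ".join(report.messages))
    inner_ext = pair.inner.extents
    cell = np.array(
        [2 * spec.L + spec.t, math.sqrt(3) * spec.L + spec.t, spec.L + spec.t]
    )
    if spec.t >= pitch and np.any(inner_ext < cell):
        raise ValueError(
            f"lattice cell {cell} mm does not fit the cavity {inner_ext} mm"
        )
    lo = pair.outer.bounds[0] - 2 * pitch
    hi = pair.outer.bounds[1] + 2 * pitch
    shape = tuple(int(math.ceil(s / pitch)) + 1 for s in hi - lo)

    outer_occ = _occupancy_on_grid(pair.outer, lo, shape, pitch)
    inner_occ = _occupancy_on_grid(pair.inner, lo, shape, pitch)
    shell = outer_occ & ~inner_occ

    if spec.t >= pitch:
        b0, b1 = pair.inner.bounds
        segs, nodes = honeycomb_segments(
            spec.L, b0 - spec.L, b1 + spec.L
        )
        lat = distance_field(segs, spec.t / 2.0, lo, shape, pitch, spheres=nodes)
        lattice_occ = (lat <= 0) & inner_occ
    else:
        lattice_occ = np.zeros(shape, dtype=bool)

    solid = shell | lattice_occ
    fld = np.where(solid, -0.5 * pitch, 0.5 * pitch).astype(np.float32)
    mesh = mesh_from_field(fld, lo, pitch)
    if not mesh.is_watertight:
        raise ValueError("bone model meshing produced a non-watertight surface")
    if return_stats:
        cavity = int(inner_occ.sum())
        stats = {
            "voxel_pitch_mm": pitch,
            "shell_voxels": int(shell.sum()),
            "lattice_voxels": int(lattice_occ.sum()),
            "cavity_voxels": cavity,
            "cavity_solid_fraction": float(lattice_occ.sum() / cavity) if cavity else 0.0,
        }
        return mesh, stats
    return mesh


def drain_holes(
    mesh: trimesh.Trimesh,
    centers: np.ndarray,
    direction,
    diameter_mm: float = 2.0,
    pitch: float = DEFAULT_BONE_PITCH,
) -> trimesh.Trimesh:
    """Cut cylindrical drain channels through a model (off by default in
    the pipeline; physical prints need them to evacuate resin).

    Each channel runs through ``center`` along ``direction`` across the
    whole bounding box.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    lo = mesh.bounds[0] - 2 * pitch
    hi = mesh.bounds[1] + 2 * pitch
    shape = tuple(int(math.ceil(s / pitch)) + 1 for s in hi - lo)
    occ = _occupancy_on_grid(mesh, lo, shape, pitch)
    span = float(np.linalg.norm(hi - lo))
    segs = [
        [np.asarray(c, float) - span * direction, np.asarray(c, float) + span * direction]
        for c in np.atleast_2d(centers)
    ]
    holes = distance_field(np.asarray(segs), diameter_mm / 2.0, lo, shape, pitch)
    solid = occ & ~(holes <= 0)
    fld = np.where(solid, -0.5 * pitch, 0.5 * pitch).astype(np.float32)
    return mesh_from_field(fld, lo, pitch)
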