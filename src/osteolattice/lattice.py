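"""Hexagonal lattice geometry: unit cell, relative density, test specimens.

The lattice consists of regular hexagons (side L, strut diameter t) in
horizontal planes whose corners are connected by vertical struts of
length L between planes (AA stacking).  One dimensionless ratio t/L
fully determines the structure and its relative density; t is fixed by
the printable floor of 0.4 mm.

Meshing strategy: every solid is described by a signed-distance-like
field sampled on a regular voxel grid (struts are capsules/cylinders,
junctions are closed by spheres of diameter t); Boolean union and
intersection are pointwise min/max of the fields, and the surface is
extracted with marching cubes.  This trades exactness for robustness:
the result is always a single closed, watertight triangle mesh.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh
from skimage import measure

__all__ = [
    "LatticeSpec",
    "SpecimenDesign",
    "unit_cell",
    "relative_density",
    "voxel_relative_density",
    "specimen",
    "honeycomb_segments",
    "distance_field",
    "mesh_from_field",
    "export_stl",
    "mesh_report",
    "DENSITY_PREFACTOR",
    "MIN_STRUT_MM",
]

#: minimum strut diameter printable by the SLA process (mm)
MIN_STRUT_MM = 0.4

#: Gibson-Ashby style prefactor of the analytic relative density
#: rho = C * (t/L)^2 for this cell (3 in-plane + 2 vertical circular
#: struts per hexagonal prism cell of volume (3*sqrt(3)/2) L^3).
DENSITY_PREFACTOR = 5.0 * math.pi / (6.0 * math.sqrt(3.0))

#: default voxel pitch (mm) for unit-cell meshing
DEFAULT_CELL_PITCH = 0.05
#: default voxel pitch (mm) for full specimens
DEFAULT_SPECIMEN_PITCH = 0.25


@dataclass(frozen=True)
class LatticeSpec:
    """Strut diameter t (mm) and strut length L (mm); ratio t/L.

    ``t`` defaults to the printable floor of 0.4 mm; a spec may be built
    from a target ratio with :meth:`from_ratio`.
    """

    t: float
    L: float

    def __post_init__(self) -> None:
        if self.t <= 0 or self.L <= 0:
            raise ValueError("t and L must be positive")
        if not (0.0 < self.t_over_L < 1.0):
            raise ValueError("t/L must lie in (0, 1)")

    @property
    def t_over_L(self) -> float:
        return self.t / self.L

    @classmethod
    def from_ratio(cls, t_over_L: float, t: float = MIN_STRUT_MM) -> "LatticeSpec":
        if t_over_L <= 0:
            raise ValueError("t/L must be positive")
        return cls(t=t, L=t / t_over_L)


@dataclass(frozen=True)
class SpecimenDesign:
    """Sizing rules for the cylindrical compression specimen.

    diameter >= spacing_factor * (largest lattice spacing); total
    length = 2 * diameter; lattice fused with end plates.
    """

    plate_thickness_mm: float = 1.0
    spacing_factor: float = 10.0
    aspect_ratio: float = 2.0  # length / diameter


# ---------------------------------------------------------------------------
# Field machinery


def distance_field(
    segments: np.ndarray,
    radius: float,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    pitch: float,
    spheres: np.ndarray | None = None,
) -> np.ndarray:
    """Field of (distance to nearest strut axis) - radius on a voxel grid.

    ``segments`` is (n, 2, 3) in mm; voxel centers sit at
    ``origin + (index + 0.5) * pitch``.  Negative values are inside the
    strut union.  Each segment only updates the voxels of its own
    dilated bounding box, so cost scales with strut volume, not grid
    volume.  Optional ``spheres`` (m, 3) add balls of the same radius
    (junction closure).
    """
    origin = np.asarray(origin, dtype=float)
    field = np.full(shape, np.inf, dtype=np.float32)
    axes = [origin[k] + (np.arange(shape[k]) + 0.5) * pitch for k in range(3)]
    reach = radius + 1.6 * pitch

    def _block(lo_pt, hi_pt):
        i0 = np.floor((lo_pt - reach - origin) / pitch - 0.5).astype(int)
        i1 = np.ceil((hi_pt + reach - origin) / pitch - 0.5).astype(int) + 1
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, shape)
        if np.any(i0 >= i1):
            return None
        return tuple(slice(a, b) for a, b in zip(i0, i1))

    for seg in np.asarray(segments, dtype=float).reshape(-1, 2, 3):
        p0, p1 = seg
        sl = _block(np.minimum(p0, p1), np.maximum(p0, p1))
        if sl is None:
            continue
        x = axes[0][sl[0]][:, None, None]
        y = axes[1][sl[1]][None, :, None]
        z = axes[2][sl[2]][None, None, :]
        d = p1 - p0
        length2 = float(d @ d)
        dx, dy, dz = x - p0[0], y - p0[1], z - p0[2]
        if length2 == 0.0:
            dist2 = dx**2 + dy**2 + dz**2
        else:
            tpar = (dx * d[0] + dy * d[1] + dz * d[2]) / length2
            np.clip(tpar, 0.0, 1.0, out=tpar)
            dist2 = (
                (dx - tpar * d[0]) ** 2
                + (dy - tpar * d[1]) ** 2
                + (dz - tpar * d[2]) ** 2
            )
        np.minimum(field[sl], np.sqrt(dist2, dtype=np.float32), out=field[sl])

    if spheres is not None:
        for c in np.asarray(spheres, dtype=float).reshape(-1, 3):
            sl = _block(c, c)
            if sl is None:
                continue
            x = axes[0][sl[0]][:, None, None]
            y = axes[1][sl[1]][None, :, None]
            z = axes[2][sl[2]][None, None, :]
            dist2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
            np.minimum(field[sl], np.sqrt(dist2, dtype=np.float32), out=field[sl])

    return field - np.float32(radius)


def mesh_from_field(
    field: np.ndarray, origin: np.ndarray, pitch: float
) -> trimesh.Trimesh:
    """Extract the level-0 isosurface of a field as a watertight mesh.

    The field is padded with one positive layer so the surface is always
    closed even when solid touches the grid boundary.
    """
    if not np.any(field <= 0):
        raise ValueError("field has no interior; nothing to mesh")
    pad_val = float(max(pitch, np.max(field[np.isfinite(field)], initial=pitch)))
    padded = np.pad(field, 1, constant_values=pad_val)
    # marching_cubes needs finite values
    padded = np.nan_to_num(padded, posinf=pad_val)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.0, spacing=(pitch, pitch, pitch)
    )
    # padded index j maps to voxel center origin + (j - 0.5) * pitch
    verts = verts + (np.asarray(origin) - 0.5 * pitch)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _grid(bounds_lo, bounds_hi, pitch, margin):
    lo = np.asarray(bounds_lo, dtype=float) - margin
    hi = np.asarray(bounds_hi, dtype=float) + margin
    shape = tuple(int(math.ceil(s / pitch)) + 1 for s in hi - lo)
    return lo, shape


# ---------------------------------------------------------------------------
# Honeycomb topology


def _hex_vertices(L: float, center=(0.0, 0.0)) -> np.ndarray:
    ang = np.deg2rad(np.arange(6) * 60.0)
    return np.column_stack(
        (center[0] + L * np.cos(ang), center[1] + L * np.sin(ang))
    )


def _unit_cell_geometry(spec: LatticeSpec):
    """Segments (12, 2, 3) and node centers of one unit cell at the origin."""
    L = spec.L
    v = _hex_vertices(L)
    segs = []
    for k in range(6):
        a, b = v[k], v[(k + 1) % 6]
        segs.append([[a[0], a[1], 0.0], [b[0], b[1], 0.0]])
    for k in range(6):
        segs.append([[v[k][0], v[k][1], 0.0], [v[k][0], v[k][1], L]])
    nodes = np.vstack(
        [np.column_stack((v, np.zeros(6))), np.column_stack((v, np.full(6, L)))]
    )
    return np.asarray(segs), nodes


def honeycomb_segments(
    L: float,
    bounds_lo,
    bounds_hi,
) -> tuple[np.ndarray, np.ndarray]:
    """All strut segments and node points of the lattice intersecting a box.

    Hexagon centers form a triangular lattice of spacing sqrt(3)*L;
    planes repeat every L in z.  Shared edges and vertices are emitted
    once.
    """
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    dx, dy = 1.5 * L, math.sqrt(3.0) * L
    i_min = int(math.floor((lo[0] - L) / dx)) - 1
    i_max = int(math.ceil((hi[0] + L) / dx)) + 1
    j_min = int(math.floor((lo[1] - L) / dy)) - 1
    j_max = int(math.ceil((hi[1] + L) / dy)) + 1
    m_min = int(math.floor(lo[2] / L)) - 1
    m_max = int(math.ceil(hi[2] / L)) + 1

    def key(p):
        return tuple(np.round(np.asarray(p) / (1e-6 * L)).astype(np.int64))

    edges: dict = {}
    verts: dict = {}
    for i in range(i_min, i_max + 1):
        for j in range(j_min, j_max + 1):
            cx = dx * i
            cy = dy * j + (i % 2) * (dy / 2.0)
            if cx < lo[0] - 2 * L or cx > hi[0] + 2 * L:
                continue
            if cy < lo[1] - 2 * L or cy > hi[1] + 2 * L:
                continue
            hv = _hex_vertices(L, (cx, cy))
            for k in range(6):
                a, b = hv[k], hv[(k + 1) % 6]
                ek = frozenset((key(a), key(b)))
                if ek not in edges:
                    edges[ek] = (a, b)
                for p in (a, b):
                    verts.setdefault(key(p), p)

    segments = []
    nodes = []
    for m in range(m_min, m_max + 1):
        z = m * L
        if z > hi[2] + L or z + L < lo[2] - L:
            continue
        for a, b in edges.values():
            segments.append([[a[0], a[1], z], [b[0], b[1], z]])
        for p in verts.values():
            segments.append([[p[0], p[1], z], [p[0], p[1], z + L]])
            nodes.append([p[0], p[1], z])
    return np.asarray(segments), np.asarray(nodes)


# ---------------------------------------------------------------------------
# Operations


def unit_cell(spec: LatticeSpec, pitch: float = DEFAULT_CELL_PITCH) -> trimesh.Trimesh:
    """Watertight mesh of one unit cell.

    Six struts of diameter t along the edges of a regular hexagon of
    side L in the xy-plane plus six vertical struts of length L rising
    from the corners; junctions closed with spheres of diameter t.
    Bounding box: (2L + t) x (sqrt(3) L + t) x (L + t).
    """
    if spec.t >= spec.L:
        raise ValueError("t >= L: struts merge into a solid block")
    segs, nodes = _unit_cell_geometry(spec)
    r = spec.t / 2.0
    lo, shape = _grid(
        [-spec.L - r, -math.sqrt(3) / 2 * spec.L - r, -r],
        [spec.L + r, math.sqrt(3) / 2 * spec.L + r, spec.L + r],
        pitch,
        margin=pitch,
    )
    field = distance_field(segs, r, lo, shape, pitch, spheres=nodes)
    return mesh_from_field(field, lo, pitch)


@lru_cache(maxsize=32)
def _node_overlap_fraction(t_over_L: float) -> float:
    """Junction overlap volume per node, as a multiple of t^3.

    Five strut stubs meet at every lattice node (three in-plane at 120
    degrees, one vertical up, one vertical down).  The sum of their
    cylinder volumes double-counts the material where they interpenetrate
    near the node; that union deficit is evaluated once by fine local
    voxel counting and cached per ratio.
    """
    t = 1.0
    L = t / t_over_L
    r = t / 2.0
    stub = min(L / 2.0, 4.0 * t)
    dirs = []
    for ang in (0.0, 120.0, 240.0):
        a = math.radians(ang)
        dirs.append(np.array([math.cos(a), math.sin(a), 0.0]))
    dirs.append(np.array([0.0, 0.0, 1.0]))
    dirs.append(np.array([0.0, 0.0, -1.0]))
    segs = np.array([[[0.0, 0.0, 0.0], stub * d] for d in dirs])
    pitch = t / 24.0
    half = stub + 2 * pitch
    lo, shape = _grid([-half] * 3, [half] * 3, pitch, margin=0.0)
    union = distance_field(segs, r, lo, shape, pitch) <= 0
    total = 0
    for seg in segs:
        total += int(np.sum(distance_field(seg[None], r, lo, shape, pitch) <= 0))
    overlap_voxels = total - int(np.sum(union))
    return overlap_voxels * pitch**3 / t**3


def relative_density(spec: LatticeSpec, corrected: bool = True) -> float:
    """Solid volume fraction of the lattice.

    The leading-order estimate counts 3 in-plane and 2 vertical struts
    per hexagonal prism cell:  rho = (5*pi / (6*sqrt(3))) * (t/L)^2.
    With ``corrected=True`` (default) the material double-counted at the
    strut junctions is subtracted (2 nodes per cell), which matters for
    stubbier struts; the corrected value never exceeds the uncorrected
    one.
    """
    ratio = spec.t_over_L
    if not (0.0 < ratio < 0.5):
        raise ValueError("relative density is defined for t/L in (0, 0.5)")
    rho = DENSITY_PREFACTOR * ratio**2
    if corrected:
        # Struts carry spherical junction closures (capsule ends of
        # radius t/2); per cell the 5 struts contribute their cap volume
        # and the 2 nodes give back the material double-counted where
        # the struts interpenetrate.
        r = spec.t / 2.0
        cell_volume = 1.5 * math.sqrt(3.0) * spec.L**3
        caps = 5.0 * (4.0 / 3.0) * math.pi * r**3
        overlap = _node_overlap_fraction(round(ratio, 4)) * spec.t**3
        rho = rho + (caps - 2.0 * overlap) / cell_volume
        rho = min(rho, DENSITY_PREFACTOR * ratio**2)
    return rho


def voxel_relative_density(spec: LatticeSpec, pitch: float | None = None) -> float:
    """Occupancy-counting estimate of the relative density.

    Counts solid voxels over one orthorhombic period of the lattice
    (3L x sqrt(3) L x L, two hexagonal cells), independent of the
    closed-form estimate; used as a numerical cross-check.
    """
    L = spec.L
    if pitch is None:
        pitch = L / 120.0
    box = np.array([3.0 * L, math.sqrt(3.0) * L, L])
    segs, nodes = honeycomb_segments(
        L, [-2 * L, -2 * L, -L], box + [2 * L, 2 * L, L]
    )
    shape = tuple(int(round(b / pitch)) for b in box)
    field = distance_field(
        segs, spec.t / 2.0, np.zeros(3), shape, pitch, spheres=nodes
    )
    return float(np.mean(field <= 0))


def specimen(
    spec: LatticeSpec,
    design: SpecimenDesign = SpecimenDesign(),
    pitch: float = DEFAULT_SPECIMEN_PITCH,
    diameter_mm: float | None = None,
) -> trimesh.Trimesh:
    """Cylindrical compression specimen: clipped lattice fused with plates.

    The diameter defaults to ``spacing_factor`` times the largest
    lattice spacing (the across-corners hexagon diameter 2L); total
    length is ``aspect_ratio * diameter`` including the two end plates.
    Struts crossing the cylinder wall are clipped, as in the physical
    print.
    """
    spacing = 2.0 * spec.L
    d_min = design.spacing_factor * spacing
    if diameter_mm is None:
        diameter_mm = d_min
    elif diameter_mm < d_min:
        raise ValueError(
            f"diameter {diameter_mm} mm violates the {design.spacing_factor}x "
            f"spacing rule (needs >= {d_min} mm)"
        )
    R = diameter_mm / 2.0
    height = design.aspect_ratio * diameter_mm
    tp = design.plate_thickness_mm

    lo, shape = _grid([-R, -R, 0.0], [R, R, height], pitch, margin=pitch)
    x = lo[0] + (np.arange(shape[0]) + 0.5) * pitch
    y = lo[1] + (np.arange(shape[1]) + 0.5) * pitch
    z = lo[2] + (np.arange(shape[2]) + 0.5) * pitch
    radial = (
        np.sqrt(x[:, None] ** 2 + y[None, :] ** 2) - R
    ).astype(np.float32)[:, :, None]
    zb = z[None, None, :].astype(np.float32)

    if spec.t < pitch:
        lattice_field = np.full(shape, np.float32(np.inf))
    else:
        segs, nodes = honeycomb_segments(
            spec.L, [-R - spec.L, -R - spec.L, -spec.L],
            [R + spec.L, R + spec.L, height + spec.L],
        )
        lattice_field = distance_field(
            segs, spec.t / 2.0, lo, shape, pitch, spheres=nodes
        )
    # clip lattice to the cylinder and the specimen height
    lattice_field = np.maximum(lattice_field, radial)
    lattice_field = np.maximum(lattice_field, -zb)
    lattice_field = np.maximum(lattice_field, zb - height)
    # end plates: full discs of thickness tp
    plate_lo = np.maximum(radial, np.maximum(-zb, zb - tp))
    plate_hi = np.maximum(radial, np.maximum((height - tp) - zb, zb - height))
    field = np.minimum(lattice_field, np.minimum(plate_lo, plate_hi))
    mesh = mesh_from_field(field, lo, pitch)
    if not mesh.is_watertight:
        raise ValueError("specimen meshing produced a non-watertight surface")
    return mesh


# ---------------------------------------------------------------------------
# Export


def export_stl(mesh: trimesh.Trimesh, path) -> None:
    """Write a binary STL; refuses non-watertight geometry."""
    if not mesh.is_watertight:
        raise ValueError("refusing to export a non-watertight mesh")
    mesh.export(path)


def mesh_report(mesh: trimesh.Trimesh, spec: LatticeSpec | None = None) -> dict:
    rep = {
        "volume_mm3": float(mesh.volume),
        "watertight": bool(mesh.is_watertight),
        "faces": int(len(mesh.faces)),
        "extents_mm": [float(e) for e in mesh.extents],
    }
    if spec is not None:
        rep["t_mm"] = spec.t
        rep["L_mm"] = spec.L
        rep["t_over_L"] = spec.t_over_L
        rep["relative_density"] = relative_density(spec)
    return rep
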