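"""The 2D interaction surface.

Users correct a 3D segmentation by dragging its 2D contour on an image
slice.  This module extracts those contours (plane-mesh intersection),
lifts a 2D drag into a 3D world displacement, picks the mesh vertex that
the drag constrains, and rasterizes a closed surface back into a binary
mask for Dice evaluation.

Slice axes follow radiological convention on an axis-aligned volume:
sagittal = x (axis 0), coronal = y (axis 1), axial = z (axis 2).  The
in-plane 2D basis of a canonical plane is the two remaining world axes in
(x, y, z) order, so 2D coordinates are plain world mm and drags are
isometric.  Arbitrary (point, normal) planes use a deterministic basis
derived from the normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import InputError, NumericalError
from .image import BinaryMask, ImageGeometry

__all__ = [
    "SlicePlane",
    "Polyline",
    "Contour",
    "extract_contour",
    "lift_drag",
    "pick_vertex",
    "rasterize",
]

_AXIS_OF = {"sagittal": 0, "coronal": 1, "axial": 2}
_NAME_OF = {v: k for k, v in _AXIS_OF.items()}

#: contour segment endpoints are merged when within this distance (mm)
LINK_TOL = 1e-6


@dataclass(frozen=True)
class SlicePlane:
    """An image slice: a canonical axis+index pair, or an arbitrary
    (point, unit normal) plane."""

    axis: str | None = None
    index: int | None = None
    point: tuple[float, float, float] | None = None
    normal: tuple[float, float, float] | None = None

    @classmethod
    def canonical(cls, axis: str, index: int) -> "SlicePlane":
        if axis not in _AXIS_OF:
            raise InputError(f"unknown slice axis {axis!r}")
        return cls(axis=axis, index=int(index))

    @classmethod
    def oblique(cls, point, normal) -> "SlicePlane":
        n = np.asarray(normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise InputError("plane normal must be nonzero")
        n = n / norm
        return cls(point=tuple(np.asarray(point, dtype=float)), normal=tuple(n))

    def frame(self, geometry: ImageGeometry):
        """Return (p0, normal, e1, e2): plane origin, unit normal, and the
        orthonormal in-plane basis used for 2D coordinates."""
        if self.axis is not None:
            a = _AXIS_OF[self.axis]
            if self.index is None or not 0 <= self.index < geometry.shape[a]:
                raise InputError(
                    f"slice index {self.index} outside volume axis "
                    f"{self.axis} (size {geometry.shape[a]})"
                )
            p0 = np.zeros(3)
            p0[a] = geometry.origin[a] + self.index * geometry.spacing[a]
            n = np.zeros(3)
            n[a] = 1.0
            in_plane = [ax for ax in range(3) if ax != a]
            e1 = np.eye(3)[in_plane[0]]
            e2 = np.eye(3)[in_plane[1]]
            return p0, n, e1, e2
        if self.point is None or self.normal is None:
            raise InputError("plane needs either axis+index or point+normal")
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        # deterministic basis: world axis with the smallest |normal component|
        a = int(np.argmin(np.abs(n)))
        e1 = np.cross(np.eye(3)[a], n)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return np.asarray(self.point, dtype=float), n, e1, e2

    def to_dict(self) -> dict:
        if self.axis is not None:
            return {"axis": self.axis, "index": self.index}
        return {"point": list(self.point), "normal": list(self.normal)}

    @classmethod
    def from_dict(cls, d: dict) -> "SlicePlane":
        if "axis" in d:
            return cls.canonical(d["axis"], d["index"])
        return cls.oblique(d["point"], d["normal"])


@dataclass
class Polyline:
    """One connected intersection curve: world points, their 2D in-plane
    coordinates, and the mesh edge (vertex pair) each point was
    interpolated on.  Closed curves store first != last (topological
    closure, no duplicate)."""

    points_world: np.ndarray  # (N, 3)
    points_2d: np.ndarray  # (N, 2)
    edges: np.ndarray  # (N, 2) int, source mesh edge per point
    closed: bool


@dataclass
class Contour:
    """Plane-mesh intersection: zero or more polylines."""

    plane: SlicePlane
    polylines: list[Polyline] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.polylines

    def all_points_world(self) -> np.ndarray:
        if self.is_empty:
            return np.empty((0, 3))
        return np.vstack([p.points_world for p in self.polylines])

    def all_points_2d(self) -> np.ndarray:
        if self.is_empty:
            return np.empty((0, 2))
        return np.vstack([p.points_2d for p in self.polylines])

    def to_dict(self) -> dict:
        return {
            "plane": self.plane.to_dict(),
            "polylines": [
                {
                    "points_world": p.points_world.tolist(),
                    "points_2d": p.points_2d.tolist(),
                    "closed": bool(p.closed),
                }
                for p in self.polylines
            ],
        }


def extract_contour(
    mesh: trimesh.Trimesh, plane: SlicePlane, geometry: ImageGeometry
) -> Contour:
    """Intersect a triangle mesh with a slice plane.

    Marching-triangles: every face with vertices on both sides of the plane
    contributes one segment whose endpoints are linearly interpolated on
    the two sign-crossing edges; segments sharing a mesh edge are linked
    into polylines.  A watertight mesh yields only closed polylines.  A
    plane missing the mesh returns an empty contour.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("mesh has non-finite vertex coordinates")
    p0, n, e1, e2 = plane.frame(geometry)
    d = (v - p0) @ n
    # nudge exact-zero distances so every crossing is transversal
    scale = max(1.0, float(np.abs(d).max(initial=0.0)))
    d = np.where(d == 0.0, 1e-14 * scale, d)

    faces = np.asarray(mesh.faces)
    sd = d[faces]  # (F, 3)
    crossing = ~(np.all(sd > 0, axis=1) | np.all(sd < 0, axis=1))
    if not crossing.any():
        return Contour(plane=plane)

    # for each crossing face, the two edges with a sign change
    seg_edges = []  # per face: pair of edge keys
    edge_points: dict[tuple[int, int], np.ndarray] = {}
    for f in faces[crossing]:
        keys = []
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if d[a] * d[b] < 0:
                key = (int(min(a, b)), int(max(a, b)))
                keys.append(key)
                if key not in edge_points:
                    t = d[key[0]] / (d[key[0]] - d[key[1]])
                    edge_points[key] = v[key[0]] + t * (v[key[1]] - v[key[0]])
        if len(keys) == 2:
            seg_edges.append((keys[0], keys[1]))

    # link segments sharing an edge key into polylines
    adjacency: dict[tuple[int, int], list[int]] = {}
    for si, (ka, kb) in enumerate(seg_edges):
        adjacency.setdefault(ka, []).append(si)
        adjacency.setdefault(kb, []).append(si)

    used = np.zeros(len(seg_edges), dtype=bool)
    polylines = []
    for start in range(len(seg_edges)):
        if used[start]:
            continue
        chain = [seg_edges[start][0], seg_edges[start][1]]
        used[start] = True
        closed = False
        # extend forward from the tail, then (if open) from the head
        for end in (1, 0):
            while True:
                tip = chain[-1] if end == 1 else chain[0]
                nxt = [s for s in adjacency.get(tip, []) if not used[s]]
                if not nxt:
                    break
                si = nxt[0]
                ka, kb = seg_edges[si]
                other = kb if ka == tip else ka
                used[si] = True
                if other == (chain[0] if end == 1 else chain[-1]):
                    closed = True
                    break
                if end == 1:
                    chain.append(other)
                else:
                    chain.insert(0, other)
            if closed:
                break
        pts = np.array([edge_points[k] for k in chain])
        polylines.append(
            Polyline(
                points_world=pts,
                points_2d=np.column_stack([(pts - p0) @ e1, (pts - p0) @ e2]),
                edges=np.array(chain, dtype=int),
                closed=closed,
            )
        )
    return Contour(plane=plane, polylines=polylines)


def lift_drag(
    plane: SlicePlane,
    geometry: ImageGeometry,
    p_start: tuple[float, float],
    p_end: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Map a 2D in-plane drag to (world start point, world displacement).

    The basis is orthonormal, so drag lengths and angles are preserved and
    the displacement lies exactly in the plane.
    """
    p0, _, e1, e2 = plane.frame(geometry)
    a = np.asarray(p_start, dtype=float)
    b = np.asarray(p_end, dtype=float)
    start = p0 + a[0] * e1 + a[1] * e2
    end = p0 + b[0] * e1 + b[1] * e2
    return start, end - start


def pick_vertex(
    mesh: trimesh.Trimesh, contour: Contour, p_start: np.ndarray
) -> int:
    """The mesh vertex constrained by a drag starting at ``p_start`` (world).

    Finds the contour point nearest the cursor, then the mesh vertex
    nearest that contour point; ties break to the lowest vertex index.
    """
    if contour.is_empty:
        raise InputError("no contour under cursor")
    pts = contour.all_points_world()
    p_start = np.asarray(p_start, dtype=float).reshape(3)
    cp = pts[np.argmin(np.linalg.norm(pts - p_start, axis=1))]
    dv = np.linalg.norm(np.asarray(mesh.vertices) - cp, axis=1)
    return int(np.argmin(dv))  # argmin returns the first (lowest) index on ties


def _open_edge_count(mesh: trimesh.Trimesh) -> int:
    edges = np.sort(np.asarray(mesh.edges), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts != 2))


# deterministic sub-voxel ray offsets (fractions of spacing) tried in order
# when a column's crossing parity comes out odd
_RAY_JITTERS = ((3.717e-4, 6.193e-4), (1.871e-3, 9.41e-4), (7.13e-3, 3.97e-3))


def rasterize(mesh: trimesh.Trimesh, geometry: ImageGeometry) -> BinaryMask:
    """Voxelize a closed surface: foreground iff the voxel CENTER is inside.

    Casts one ray per (x, y) voxel column along +z and fills between
    crossing pairs (ray parity).  Rays carry a fixed sub-voxel offset
    relative to voxel centers so edge/vertex hits are avoided
    deterministically; translating mesh and origin together therefore
    yields an identical mask.
    """
    open_edges = _open_edge_count(mesh)
    if open_edges != 0 or not mesh.is_watertight:
        raise InputError(
            f"rasterize requires a watertight mesh ({open_edges} open edges)"
        )
    v = np.asarray(mesh.vertices, dtype=float)
    tri = v[np.asarray(mesh.faces)]  # (F, 3, 3)
    nx, ny, nz = geometry.shape
    zc = geometry.axis_coords(2)
    for jx, jy in _RAY_JITTERS:
        xs = geometry.axis_coords(0) + jx * geometry.spacing[0]
        ys = geometry.axis_coords(1) + jy * geometry.spacing[1]
        flips = np.zeros((nx, ny, nz + 1), dtype=np.int64)
        n_cross = np.zeros((nx, ny), dtype=np.int64)
        ok = _cast_rays(tri, xs, ys, zc, flips, n_cross)
        if ok and not np.any(n_cross % 2):
            inside = np.cumsum(flips[:, :, :-1], axis=2) % 2 == 1
            return BinaryMask(geometry=geometry, data=inside.astype(bool))
    raise NumericalError("rasterization parity failure on all ray offsets")


def _cast_rays(tri, xs, ys, zc, flips, n_cross) -> bool:
    """Accumulate z-ray crossings for every triangle; returns False on a
    degenerate hit (ray through a projected edge) so the caller can retry
    with a different offset."""
    x0, y0 = xs[0], ys[0]
    dx = xs[1] - xs[0] if len(xs) > 1 else 1.0
    dy = ys[1] - ys[0] if len(ys) > 1 else 1.0
    nx, ny = len(xs), len(ys)
    for t in tri:
        (ax, ay, az), (bx, by, bz), (cx, cy, cz) = t
        det = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if det == 0.0:  # projects to a line: never hit by a jittered ray
            continue
        lo_x = max(0, int(np.ceil((min(ax, bx, cx) - x0) / dx)))
        hi_x = min(nx - 1, int(np.floor((max(ax, bx, cx) - x0) / dx)))
        lo_y = max(0, int(np.ceil((min(ay, by, cy) - y0) / dy)))
        hi_y = min(ny - 1, int(np.floor((max(ay, by, cy) - y0) / dy)))
        if lo_x > hi_x or lo_y > hi_y:
            continue
        px = xs[lo_x : hi_x + 1, None]
        py = ys[None, lo_y : hi_y + 1]
        # barycentric coordinates of the ray's (x, y) in the projection
        w1 = ((px - ax) * (cy - ay) - (cx - ax) * (py - ay)) / det
        w2 = ((bx - ax) * (py - ay) - (px - ax) * (by - ay)) / det
        w0 = 1.0 - w1 - w2
        hit = (w0 > 0) & (w1 > 0) & (w2 > 0)
        if not hit.any():
            continue
        grazing = ((w0 == 0) | (w1 == 0) | (w2 == 0)) & (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if grazing.any():
            return False
        z = w0 * az + w1 * bz + w2 * cz
        ii, jj = np.nonzero(hit)
        ks = np.searchsorted(zc, z[ii, jj], side="left")
        np.add.at(flips, (ii + lo_x, jj + lo_y, ks), 1)
        np.add.at(n_cross, (ii + lo_x, jj + lo_y), 1)
    return True
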