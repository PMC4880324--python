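"""Trivariate Bernstein free-form deformation (FFD).

A control lattice spans a parallelepiped ``X0 + s*S + t*T + u*U`` with
``(s, t, u) in [0,1]^3``.  A point embedded at local coordinates (s, t, u)
deforms as the Bernstein-weighted sum of the (l+1)(m+1)(n+1) control
points::

    x_ffd = sum_ijk  B_i^l(s) B_j^m(t) B_k^n(u) (P_ijk + dP_ijk)

where ``B_i^l`` is the Bernstein basis polynomial of degree ``l``.  Moving
control points therefore produces a smooth, globally supported deformation
of every embedded point; points outside the lattice are untouched.  The
lattice can cover the whole shape (global mode) or be re-sized onto a
region of interest (local mode) at the same control-point count, which
refines the deformation resolution at no extra cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import trimesh

from .errors import InputError, NumericalError

__all__ = [
    "ControlGrid",
    "LocalCoords",
    "bernstein_1d",
    "bernstein_weights",
    "fit_global_grid",
    "fit_local_grid",
    "embed",
    "deform",
]

#: slack used when deciding whether a local coordinate lies inside [0, 1];
#: absorbs floating-point jitter for vertices sitting exactly on a lattice face
EMBED_TOL = 1e-9

_AXIS_NAMES = ("x", "y", "z")


@dataclass
class ControlGrid:
    """FFD control lattice over a parallelepiped.

    Attributes
    ----------
    origin : (3,) float array
        World position ``X0`` of the lattice corner (mm).
    axes : (3, 3) float array
        Rows are the edge vectors ``S, T, U`` (mm) spanning the
        parallelepiped; must be linearly independent.
    degrees : (l, m, n)
        Bernstein polynomial degrees per axis; the lattice has
        ``(l+1)(m+1)(n+1)`` control points.
    control_points : (l+1, m+1, n+1, 3) float array
        Undeformed control point positions (world mm).
    displacements : (l+1, m+1, n+1, 3) float array
        Control point displacements ``dP`` (mm); all zero at rest.
    """

    origin: np.ndarray
    axes: np.ndarray
    degrees: tuple[int, int, int]
    control_points: np.ndarray = field(default=None)  # type: ignore[assignment]
    displacements: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        l, m, n = (int(d) for d in self.degrees)
        if min(l, m, n) < 1:
            raise InputError(f"grid degrees must be >= 1, got {self.degrees}")
        self.degrees = (l, m, n)
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise NumericalError("lattice axes S, T, U are linearly dependent")
        if self.control_points is None:
            self.control_points = self._lattice_positions()
        self.control_points = np.asarray(self.control_points, dtype=float)
        shape = (l + 1, m + 1, n + 1, 3)
        if self.control_points.shape != shape:
            raise InputError(
                f"control_points shape {self.control_points.shape} != {shape}"
            )
        if self.displacements is None:
            self.displacements = np.zeros(shape)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != shape:
            raise InputError(
                f"displacements shape {self.displacements.shape} != {shape}"
            )

    def _lattice_positions(self) -> np.ndarray:
        l, m, n = self.degrees
        fi = np.arange(l + 1) / l
        fj = np.arange(m + 1) / m
        fk = np.arange(n + 1) / n
        s, t, u = np.meshgrid(fi, fj, fk, indexing="ij")
        stu = np.stack([s, t, u], axis=-1)
        return self.origin + stu @ self.axes

    @property
    def n_control_points(self) -> int:
        l, m, n = self.degrees
        return (l + 1) * (m + 1) * (n + 1)

    def copy(self) -> "ControlGrid":
        return ControlGrid(
            origin=self.origin.copy(),
            axes=self.axes.copy(),
            degrees=self.degrees,
            control_points=self.control_points.copy(),
            displacements=self.displacements.copy(),
        )

    def same_frame(self, other: "ControlGrid") -> bool:
        return (
            self.degrees == other.degrees
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.axes, other.axes)
        )

    # -- JSON round trip (session reproducibility) --------------------------

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axes": self.axes.tolist(),
            "degrees": list(self.degrees),
            "control_points": self.control_points.reshape(-1, 3).tolist(),
            "displacements": self.displacements.reshape(-1, 3).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControlGrid":
        l, m, n = (int(x) for x in d["degrees"])
        shape = (l + 1, m + 1, n + 1, 3)
        return cls(
            origin=np.array(d["origin"], dtype=float),
            axes=np.array(d["axes"], dtype=float),
            degrees=(l, m, n),
            control_points=np.array(d["control_points"], dtype=float).reshape(shape),
            displacements=np.array(d["displacements"], dtype=float).reshape(shape),
        )


@dataclass
class LocalCoords:
    """Per-vertex lattice coordinates of a mesh embedded in a grid.

    ``stu[v]`` solves ``x_v = X0 + s*S + t*T + u*U``.  ``embedded[v]`` is
    True when all three coordinates lie in [0, 1] (within :data:`EMBED_TOL`);
    in local mode vertices outside the lattice are flagged non-embedded and
    never deformed.
    """

    stu: np.ndarray  # (V, 3)
    embedded: np.ndarray  # (V,) bool
    grid: ControlGrid


def bernstein_1d(degree: int, t: np.ndarray) -> np.ndarray:
    """Bernstein basis row ``B_i^degree(t)`` for i = 0..degree.

    ``t`` may be a scalar or an array; the basis axis is appended last.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("non-finite lattice coordinate")
    i = np.arange(degree + 1)
    coeff = np.array([comb(degree, k) for k in i], dtype=float)
    tt = t[..., None]
    return coeff * tt**i * (1.0 - tt) ** (degree - i)


def bernstein_weights(
    degrees: tuple[int, int, int], coords: tuple[float, float, float]
) -> np.ndarray:
    """Trivariate Bernstein weight tensor over (i, j, k) for one point.

    The weights are the outer product of the three univariate bases and sum
    to one for any (s, t, u) by the binomial theorem.
    """
    l, m, n = degrees
    s, t, u = coords
    ws = bernstein_1d(l, np.float64(s))
    wt = bernstein_1d(m, np.float64(t))
    wu = bernstein_1d(n, np.float64(u))
    return np.einsum("i,j,k->ijk", ws, wt, wu)


def weight_matrix(grid: ControlGrid, stu: np.ndarray) -> np.ndarray:
    """Bernstein weights for many points: (V, (l+1)(m+1)(n+1)), flattened
    in C order over (i, j, k)."""
    l, m, n = grid.degrees
    stu = np.atleast_2d(np.asarray(stu, dtype=float))
    ws = bernstein_1d(l, stu[:, 0])
    wt = bernstein_1d(m, stu[:, 1])
    wu = bernstein_1d(n, stu[:, 2])
    w = np.einsum("vi,vj,vk->vijk", ws, wt, wu)
    return w.reshape(stu.shape[0], -1)


def fit_global_grid(
    mesh: trimesh.Trimesh,
    degrees: tuple[int, int, int] = (5, 5, 5),
    padding: float = 0.05,
) -> ControlGrid:
    """Axis-aligned lattice covering the mesh bounding box.

    ``padding`` expands each side by that fraction of the axis extent, so
    every vertex embeds strictly inside (0, 1) and outward drags have room
    to pull the surface.  Degrees (5,5,5) give the default 216-point grid.
    """
    if len(mesh.vertices) == 0:
        raise InputError("cannot fit a grid to an empty mesh")
    if padding < 0:
        raise InputError("padding must be >= 0")
    v = np.asarray(mesh.vertices, dtype=float)
    lo, hi = v.min(axis=0), v.max(axis=0)
    extent = hi - lo
    for a in range(3):
        if extent[a] <= 0:
            raise InputError(
                f"degenerate mesh: zero extent along {_AXIS_NAMES[a]} axis"
            )
    origin = lo - padding * extent
    axes = np.diag(extent * (1.0 + 2.0 * padding))
    return ControlGrid(origin=origin, axes=axes, degrees=degrees)


def fit_local_grid(
    center: np.ndarray,
    size: tuple[float, float, float],
    degrees: tuple[int, int, int] = (5, 5, 5),
) -> ControlGrid:
    """Axis-aligned lattice of the *same* degrees centered on a region.

    Local mode keeps the control-point count fixed while shrinking the
    lattice spacing, so the deformation resolution increases at no extra
    computational cost and everything outside the box is protected.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    size = np.asarray(size, dtype=float).reshape(3)
    if np.any(size <= 0):
        raise InputError(f"local grid size must be strictly positive, got {size}")
    origin = center - size / 2.0
    return ControlGrid(origin=origin, axes=np.diag(size), degrees=degrees)


def embed(mesh: trimesh.Trimesh, grid: ControlGrid) -> LocalCoords:
    """Local coordinates (s, t, u) of every mesh vertex in the lattice frame.

    Solves ``x = X0 + s*S + t*T + u*U`` exactly by inverting the (non-
    degenerate) frame.  Coordinates within :data:`EMBED_TOL` of the [0, 1]
    faces are snapped onto them so boundary weights stay non-negative.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    try:
        inv = np.linalg.inv(grid.axes)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded in ctor
        raise NumericalError("singular lattice frame") from e
    stu = (v - grid.origin) @ inv
    embedded = np.all((stu >= -EMBED_TOL) & (stu <= 1.0 + EMBED_TOL), axis=1)
    # snap embedded rows onto the faces they graze; raw values kept outside
    stu[embedded] = np.clip(stu[embedded], 0.0, 1.0)
    return LocalCoords(stu=stu, embedded=embedded, grid=grid)


def deform(
    mesh: trimesh.Trimesh, coords: LocalCoords, grid: ControlGrid
) -> trimesh.Trimesh:
    """Forward FFD: map every embedded vertex through the displaced lattice.

    Non-embedded vertices (local mode) are returned bitwise unchanged;
    faces are preserved.  Cost is O(V * (l+1)(m+1)(n+1)).
    """
    if not coords.grid.same_frame(grid):
        raise InputError("LocalCoords were computed against a different grid")
    v = np.asarray(mesh.vertices, dtype=float)
    if coords.stu.shape[0] != v.shape[0]:
        raise InputError(
            f"coords cover {coords.stu.shape[0]} vertices, mesh has {v.shape[0]}"
        )
    out = v.copy()
    emb = coords.embedded
    if emb.any():
        l, m, n = grid.degrees
        stu = coords.stu[emb]
        ws = bernstein_1d(l, stu[:, 0])
        wt = bernstein_1d(m, stu[:, 1])
        wu = bernstein_1d(n, stu[:, 2])
        pts = grid.control_points + grid.displacements
        out[emb] = np.einsum("vi,vj,vk,ijkc->vc", ws, wt, wu, pts, optimize=True)
    return trimesh.Trimesh(vertices=out, faces=mesh.faces.copy(), process=False)
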