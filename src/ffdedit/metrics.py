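"""Segmentation quality metrics and the per-session correction trace.

Dice measures volumetric overlap of binary masks on a shared voxel grid;
the Hausdorff distance measures the worst surface-to-surface error and is
computed mesh-natively (point samples on one surface against the exact
nearest point on the other's triangles).  A voxel-based surface variant is
provided for cross-checks.  The CorrectionTrace mirrors the interaction
counter of an editing session: one record per drag with the Dice reached
after it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import GeometryMismatchError, InputError
from .image import BinaryMask

__all__ = [
    "dice",
    "hausdorff",
    "mask_surface_hausdorff",
    "TraceStep",
    "CorrectionTrace",
]


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|).

    Both masks must live on the identical grid (shape, spacing, origin) —
    a mismatch is an error, never a silent resample.  Two empty masks are
    defined to agree perfectly (1.0).
    """
    if not mask_a.geometry.close_to(mask_b.geometry):
        raise GeometryMismatchError(
            f"mask geometries differ: {mask_a.geometry} vs {mask_b.geometry}"
        )
    a, b = mask_a.data, mask_b.data
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface_points(
    mesh: trimesh.Trimesh, samples: int, seed: int
) -> np.ndarray:
    pts = np.asarray(mesh.vertices, dtype=float)
    extra = samples - len(pts)
    if extra > 0:
        sampled, _ = trimesh.sample.sample_surface(mesh, extra, seed=seed)
        pts = np.vstack([pts, sampled])
    return pts


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its paired triangle (both (N, ...)).

    Vectorized closest-point-on-triangle classification (vertex, edge or
    face region of the barycentric plane).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
        t_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    closest = a + v[:, None] * ab + w[:, None] * ac  # face interior default
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[:, None], b + t_bc[:, None] * (c - b), closest)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + t_ac[:, None] * ac, closest)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + t_ab[:, None] * ab, closest)
    at_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(at_c[:, None], c, closest)
    at_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(at_b[:, None], b, closest)
    at_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(at_a[:, None], a, closest)
    return np.linalg.norm(points - closest, axis=1)


def _directed(points: np.ndarray, target: trimesh.Trimesh) -> float:
    """max over points of the exact distance to the target surface.

    Candidate triangles are pruned with a KD-tree on face centroids: the
    true nearest triangle's centroid lies within (distance to the nearest
    centroid + the largest centroid-to-vertex radius), so searching that
    ball is exact.
    """
    from scipy.spatial import cKDTree

    tri = np.asarray(target.triangles)  # (F, 3, 3)
    centroids = tri.mean(axis=1)
    r_max = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)
    d0, _ = tree.query(points)
    radii = d0 + r_max + 1e-9
    best = np.full(len(points), np.inf)
    groups = tree.query_ball_point(points, radii)
    flat_p = np.concatenate(
        [np.full(len(g), i) for i, g in enumerate(groups)]
    ).astype(int)
    flat_f = np.concatenate([np.asarray(g, dtype=int) for g in groups])
    dists = _point_triangle_distance(points[flat_p], tri[flat_f])
    np.minimum.at(best, flat_p, dists)
    return float(best.max())


def hausdorff(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    samples: int = 2000,
    seed: int = 0,
) -> float:
    """Symmetric Hausdorff distance between two surfaces (mm).

    Each direction samples one surface (all vertices plus face-uniform
    samples up to ``samples``) and measures the exact nearest-point
    distance to the other surface's triangles; deterministic for a given
    seed.
    """
    if len(mesh_a.vertices) == 0 or len(mesh_b.vertices) == 0:
        raise InputError("hausdorff requires two non-empty meshes")
    pa = _surface_points(mesh_a, samples, seed)
    pb = _surface_points(mesh_b, samples, seed + 1)
    return max(_directed(pa, mesh_b), _directed(pb, mesh_a))


def mask_surface_hausdorff(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Voxel-based cross-check: Hausdorff between the surface voxels of two
    masks (centers of foreground voxels with a background face-neighbor)."""
    from scipy.ndimage import binary_erosion
    from scipy.spatial import cKDTree

    if not mask_a.geometry.close_to(mask_b.geometry):
        raise GeometryMismatchError("mask geometries differ")

    def surf(mask: BinaryMask) -> np.ndarray:
        d = mask.data
        shell = d & ~binary_erosion(d)
        idx = np.argwhere(shell)
        return mask.geometry.voxel_to_world(idx)

    sa, sb = surf(mask_a), surf(mask_b)
    if len(sa) == 0 or len(sb) == 0:
        raise InputError("mask has no surface voxels")
    dab = cKDTree(sb).query(sa)[0].max()
    dba = cKDTree(sa).query(sb)[0].max()
    return float(max(dab, dba))


@dataclass
class TraceStep:
    """One applied interaction and the Dice reached after it."""

    record: dict
    dice: float | None = None
    decreased_dice: bool = False


@dataclass
class CorrectionTrace:
    """Ordered record of an editing session.

    ``interactions`` counts drags only (grid-mode switches are free, as in
    an interactive session where the counter tracks corrections).
    """

    steps: list[TraceStep] = field(default_factory=list)
    initial_dice: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def interactions(self) -> int:
        return sum(1 for s in self.steps if s.record.get("kind") == "drag")

    @property
    def final_dice(self) -> float | None:
        for s in reversed(self.steps):
            if s.dice is not None:
                return s.dice
        return self.initial_dice

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "initial_dice": self.initial_dice,
            "interactions": self.interactions,
            "steps": [
                {
                    "record": s.record,
                    "dice": s.dice,
                    "decreased_dice": s.decreased_dice,
                }
                for s in self.steps
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionTrace":
        trace = cls(
            initial_dice=d.get("initial_dice"), metadata=d.get("metadata", {})
        )
        for s in d.get("steps", []):
            trace.steps.append(
                TraceStep(
                    record=s["record"],
                    dice=s.get("dice"),
                    decreased_dice=bool(s.get("decreased_dice", False)),
                )
            )
        return trace

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionTrace":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def records(self) -> list[dict]:
        return [s.record for s in self.steps]


def report(
    case: str,
    initial_dice: float,
    final_dice: float,
    interactions: int,
    hausdorff_mm: float,
) -> dict:
    """Evaluation summary in the shape used by the CLI's JSON/TSV reports."""
    return {
        "case": case,
        "initial_dice": initial_dice,
        "final_dice": final_dice,
        "interactions": interactions,
        "hausdorff_mm": hausdorff_mm,
    }


def report_tsv(rows: list[dict]) -> str:
    cols = ["case", "initial_dice", "final_dice", "interactions", "hausdorff_mm"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"
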