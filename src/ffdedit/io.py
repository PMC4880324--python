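"""File IO, interaction traces, and deterministic replay.

Segmentations enter either as surface meshes (STL/PLY/OFF, world mm) or as
binary label volumes (NIfTI/MetaImage), which are converted to a watertight
mesh by iso-surface extraction at level 0.5 between background (0) and
foreground (>= 1).

An editing session is a list of interaction records — drags and grid-mode
switches — serialized as JSON.  Replaying a trace against the same initial
segmentation routes every record through the identical contour/solver code
path the scripted user ran, so it reproduces the same final mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import contours, ffd, solver
from .errors import InputError
from .image import BinaryMask, ImageGeometry, read_mask
from .metrics import CorrectionTrace, TraceStep, dice

__all__ = [
    "CorrectionConfig",
    "load_mesh",
    "save_mesh",
    "load_segmentation",
    "EditSession",
    "replay",
]

_MESH_EXTS = {".stl", ".ply", ".off"}


@dataclass(frozen=True)
class CorrectionConfig:
    """Knobs of a correction run; embedded in every trace for replay."""

    degrees: tuple[int, int, int] = (5, 5, 5)
    padding: float = 0.05

    def to_dict(self) -> dict:
        return {"degrees": list(self.degrees), "padding": self.padding}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionConfig":
        return cls(
            degrees=tuple(d.get("degrees", (5, 5, 5))),
            padding=float(d.get("padding", 0.05)),
        )


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise InputError(f"unsupported mesh format: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), process=False)
    except Exception as e:
        raise InputError(f"failed to read mesh {path}: {e}") from e
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise InputError(f"{path} contains no triangle mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise InputError(f"unsupported mesh format: {path}")
    mesh.export(str(path))


def load_segmentation(
    path: str | Path, geometry: ImageGeometry | None = None
) -> trimesh.Trimesh:
    """Load an initial segmentation as a surface mesh (world mm).

    Mesh files load directly.  Label volumes are surfaced with marching
    cubes at 0.5; the result is vertex-merged so the surface is watertight.
    """
    path = Path(path)
    if path.suffix.lower() in _MESH_EXTS:
        return load_mesh(path)
    mask = read_mask(path)
    return mask_to_mesh(mask)


def mask_to_mesh(mask: BinaryMask) -> trimesh.Trimesh:
    from skimage.measure import marching_cubes

    if not mask.data.any():
        raise InputError("label volume is empty; cannot extract a surface")
    verts, faces, _, _ = marching_cubes(
        mask.data.astype(np.float32), level=0.5, spacing=mask.geometry.spacing
    )
    verts = verts + np.asarray(mask.geometry.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    return mesh


# ---------------------------------------------------------------------------
# interaction records and replay


def drag_record(plane: contours.SlicePlane, start2d, end2d) -> dict:
    return {
        "kind": "drag",
        "plane": plane.to_dict(),
        "start": [float(x) for x in start2d],
        "end": [float(x) for x in end2d],
    }


def set_local_grid_record(center, size) -> dict:
    return {
        "kind": "set_local_grid",
        "center": [float(x) for x in center],
        "size": [float(x) for x in size],
    }


def set_global_grid_record() -> dict:
    return {"kind": "set_global_grid"}


@dataclass
class EditSession:
    """Mutable state of a correction run: the current mesh and grid mode.

    Each drag is stateless: the current mesh is re-embedded in a fresh
    zero-displacement grid (global fit to the current bounding box, or the
    currently selected local box), the single-vertex inverse solve is run,
    and the displacements are discarded after the deformation.
    """

    mesh: trimesh.Trimesh
    geometry: ImageGeometry
    config: CorrectionConfig = field(default_factory=CorrectionConfig)
    local_box: tuple[np.ndarray, np.ndarray] | None = None  # (center, size)

    def active_grid(self) -> ffd.ControlGrid:
        if self.local_box is not None:
            center, size = self.local_box
            return ffd.fit_local_grid(center, size, degrees=self.config.degrees)
        return ffd.fit_global_grid(
            self.mesh, degrees=self.config.degrees, padding=self.config.padding
        )

    def apply_record(self, record: dict) -> None:
        kind = record.get("kind")
        if kind == "set_global_grid":
            self.local_box = None
            return
        if kind == "set_local_grid":
            self.local_box = (
                np.asarray(record["center"], dtype=float),
                np.asarray(record["size"], dtype=float),
            )
            return
        if kind == "drag":
            plane = contours.SlicePlane.from_dict(record["plane"])
            contour = contours.extract_contour(self.mesh, plane, self.geometry)
            if contour.is_empty:
                raise InputError("drag plane does not intersect the mesh")
            start_w, delta = contours.lift_drag(
                plane, self.geometry, record["start"], record["end"]
            )
            vid = contours.pick_vertex(self.mesh, contour, start_w)
            self.mesh = solver.apply_drag(self.mesh, self.active_grid(), vid, delta)
            return
        raise InputError(f"unknown interaction record kind {kind!r}")


def replay(
    initial_mesh: trimesh.Trimesh,
    geometry: ImageGeometry,
    records: list[dict],
    config: CorrectionConfig | None = None,
    gt_mask: BinaryMask | None = None,
) -> tuple[trimesh.Trimesh, CorrectionTrace]:
    """Apply a list of interaction records in order; deterministic.

    When a ground-truth mask is supplied, each step's Dice is recorded in
    the returned trace (as in a session with the quality bar displayed);
    otherwise the trace carries the records alone.
    """
    config = config or CorrectionConfig()
    session = EditSession(
        mesh=initial_mesh.copy(), geometry=geometry, config=config
    )
    trace = CorrectionTrace(metadata={"config": config.to_dict()})
    last = None
    if gt_mask is not None:
        last = dice(contours.rasterize(session.mesh, geometry), gt_mask)
        trace.initial_dice = last
    for i, record in enumerate(records):
        try:
            session.apply_record(record)
        except InputError as e:
            raise InputError(f"record {i}: {e}") from e
        step = TraceStep(record=record)
        if gt_mask is not None and record.get("kind") == "drag":
            d = dice(contours.rasterize(session.mesh, geometry), gt_mask)
            step.dice = d
            step.decreased_dice = last is not None and d < last
            last = d
        trace.steps.append(step)
    return session.mesh, trace


def save_trace_records(
    records: list[dict], config: CorrectionConfig, path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({"config": config.to_dict(), "records": records}, indent=1)
    )


def load_trace_records(path: str | Path) -> tuple[list[dict], CorrectionConfig]:
    d = json.loads(Path(path).read_text())
    if isinstance(d, list):  # bare record list, default config
        return d, CorrectionConfig()
    return d["records"], CorrectionConfig.from_dict(d.get("config", {}))


def geometry_from_image(path: str | Path) -> ImageGeometry:
    """Read only the voxel geometry of a volume (any supported format)."""
    return read_mask(path).geometry
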