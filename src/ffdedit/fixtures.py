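"""Synthetic phantoms and a scripted user.

Real correction sessions need a medical image, an imperfect automatic
segmentation, and a human; none is available to a test suite.  The
fixtures emulate the regime instead: an ellipsoidal ground-truth "organ"
(subdivided icosphere), an initial segmentation degraded by a controlled
perturbation — a global scale error, a smooth localized bump, or a seeded
random lattice jitter — and a deterministic scripted user that plays the
drag-and-drop correction loop: scan slices, find the largest contour
error, drag it onto the ground-truth contour, repeat until the Dice target
or the interaction cap is reached.

Everything is seeded and reproducible; the emitted trace replays to the
bit-identical final mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import contours, ffd, io, metrics
from .errors import InputError
from .image import BinaryMask, ImageGeometry

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "scripted_user"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic correction case.

    Defaults describe the canonical test phantom: a 20 mm sphere centered
    in a 64^3 volume at isotropic 1 mm spacing, meshed at icosphere
    subdivision 3 (642 vertices).
    """

    geometry: ImageGeometry = field(
        default_factory=lambda: ImageGeometry(
            shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)
        )
    )
    center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    radii: tuple[float, float, float] = (20.0, 20.0, 20.0)
    perturbation: str = "global_scale"  # global_scale | smooth_bump | random_ffd
    magnitude: float = 1.10
    seed: int = 0
    mesh_resolution: int = 3  # icosphere subdivision level

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise InputError(f"radii must be positive, got {self.radii}")
        if self.perturbation not in ("global_scale", "smooth_bump", "random_ffd"):
            raise InputError(f"unknown perturbation {self.perturbation!r}")

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "center": list(self.center),
            "radii": list(self.radii),
            "perturbation": self.perturbation,
            "magnitude": self.magnitude,
            "seed": self.seed,
            "mesh_resolution": self.mesh_resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        return cls(
            geometry=ImageGeometry.from_dict(d["geometry"]),
            center=tuple(d["center"]),
            radii=tuple(d["radii"]),
            perturbation=d["perturbation"],
            magnitude=float(d["magnitude"]),
            seed=int(d["seed"]),
            mesh_resolution=int(d["mesh_resolution"]),
        )


@dataclass
class Fixture:
    spec: FixtureSpec
    gt_mask: BinaryMask
    gt_mesh: trimesh.Trimesh
    initial_mesh: trimesh.Trimesh


def _ellipsoid_mesh(spec: FixtureSpec) -> trimesh.Trimesh:
    unit = trimesh.creation.icosphere(subdivisions=spec.mesh_resolution, radius=1.0)
    v = np.asarray(unit.vertices) * np.asarray(spec.radii) + np.asarray(spec.center)
    return trimesh.Trimesh(vertices=v, faces=unit.faces.copy(), process=False)


def _ellipsoid_mask(spec: FixtureSpec) -> BinaryMask:
    g = spec.geometry
    x = g.axis_coords(0)[:, None, None]
    y = g.axis_coords(1)[None, :, None]
    z = g.axis_coords(2)[None, None, :]
    cx, cy, cz = spec.center
    rx, ry, rz = spec.radii
    inside = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
    return BinaryMask(geometry=g, data=inside)


def _perturb(spec: FixtureSpec, gt_mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    v = np.asarray(gt_mesh.vertices, dtype=float).copy()
    center = np.asarray(spec.center)
    rng = np.random.default_rng(spec.seed)
    if spec.perturbation == "global_scale":
        v = center + (v - center) * spec.magnitude
    elif spec.perturbation == "smooth_bump":
        # cosine-windowed radial bump of height `magnitude` mm at a seeded
        # direction; window half-angle 45 degrees
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radial = v - center
        rad_norm = np.linalg.norm(radial, axis=1, keepdims=True)
        unit = radial / rad_norm
        cosang = unit @ direction
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        width = np.pi / 4
        window = np.where(theta < width, 0.5 * (1 + np.cos(np.pi * theta / width)), 0.0)
        v = v + unit * (spec.magnitude * window)[:, None]
    elif spec.perturbation == "random_ffd":
        mesh = trimesh.Trimesh(vertices=v, faces=gt_mesh.faces, process=False)
        grid = ffd.fit_global_grid(mesh, degrees=(2, 2, 2), padding=0.1)
        grid = grid.copy()
        grid.displacements = rng.normal(
            scale=spec.magnitude, size=grid.displacements.shape
        )
        coords = ffd.embed(mesh, grid)
        v = np.asarray(ffd.deform(mesh, coords, grid).vertices)
    out = trimesh.Trimesh(vertices=v, faces=gt_mesh.faces.copy(), process=False)
    # the phantoms are star-shaped around their center, so any face whose
    # normal turns inward signals a self-folded (self-intersecting) surface
    outward = np.einsum(
        "ij,ij->i", out.face_normals, out.triangles_center - center
    )
    if not out.is_watertight or out.volume <= 0 or np.any(outward < 0):
        raise InputError(
            f"perturbation {spec.perturbation!r} magnitude {spec.magnitude} "
            "produced a degenerate (self-folded) surface"
        )
    return out


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Ground-truth mask + mesh and a perturbed initial mesh; deterministic
    per (spec, seed)."""
    gt_mesh = _ellipsoid_mesh(spec)
    gt_mask = _ellipsoid_mask(spec)
    initial = _perturb(spec, gt_mesh) if spec.magnitude != 0 else gt_mesh.copy()
    return Fixture(spec=spec, gt_mask=gt_mask, gt_mesh=gt_mesh, initial_mesh=initial)


def save_fixture(fix: Fixture, out_dir: str | Path) -> None:
    """Write gt mask (NIfTI), gt/initial meshes (PLY) and the spec (JSON)
    into a case directory."""
    import json

    from .image import write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(fix.gt_mask, out / "gt.nii.gz")
    io.save_mesh(fix.gt_mesh, out / "gt.ply")
    io.save_mesh(fix.initial_mesh, out / "init.ply")
    (out / "spec.json").write_text(json.dumps(fix.spec.to_dict(), indent=1))


def load_fixture(case_dir: str | Path) -> Fixture:
    import json

    from .image import read_mask

    case = Path(case_dir)
    spec = FixtureSpec.from_dict(json.loads((case / "spec.json").read_text()))
    return Fixture(
        spec=spec,
        gt_mask=read_mask(case / "gt.nii.gz"),
        gt_mesh=io.load_mesh(case / "gt.ply"),
        initial_mesh=io.load_mesh(case / "init.ply"),
    )


# ---------------------------------------------------------------------------
# scripted user


def _plane_schedule(
    gt_mesh: trimesh.Trimesh, geometry: ImageGeometry, stride: int
) -> list[contours.SlicePlane]:
    """Axis-interleaved slice visiting order through the ground truth.

    A human scans viewers slice by slice; the automation fixes a
    deterministic order: for each axis, the slices covering the target's
    bounding box at ``stride`` voxels, interleaved axial/coronal/sagittal.
    """
    v = np.asarray(gt_mesh.vertices)
    per_axis = []
    for axis in (2, 1, 0):  # axial, coronal, sagittal
        coords = geometry.axis_coords(axis)
        lo = v[:, axis].min() + geometry.spacing[axis]
        hi = v[:, axis].max() - geometry.spacing[axis]
        idx = [i for i in range(0, geometry.shape[axis], stride) if lo <= coords[i] <= hi]
        # visit from the middle outward so central (largest) contours go first
        idx.sort(key=lambda i: (abs(coords[i] - (lo + hi) / 2), i))
        name = contours._NAME_OF[axis]
        per_axis.append([contours.SlicePlane.canonical(name, i) for i in idx])
    from itertools import zip_longest

    schedule: list[contours.SlicePlane] = []
    for group in zip_longest(*per_axis):
        schedule.extend(p for p in group if p is not None)
    return schedule


def scripted_user(
    initial_mesh: trimesh.Trimesh,
    gt_mask: BinaryMask,
    gt_mesh: trimesh.Trimesh,
    geometry: ImageGeometry,
    policy: str = "global",
    dice_target: float = 0.95,
    max_interactions: int = 150,
    seed: int = 0,
    config: io.CorrectionConfig | None = None,
    slice_stride: int = 4,
    min_drag_mm: float = 0.25,
) -> tuple[trimesh.Trimesh, metrics.CorrectionTrace]:
    """Emulate the correction protocol without a human.

    Loop over a fixed slice schedule; on each slice, extract the current
    and ground-truth contours, locate the current-contour point farthest
    (in-plane) from the ground truth, and drag it onto its nearest
    ground-truth contour point — one drag per slice visit.  The grid is
    global, or (policy="local") re-centered on each drag with extent three
    times the local error per axis, floored at four voxels.  Stops at the
    Dice target or the interaction cap.  Deterministic given the inputs.
    """
    if policy not in ("global", "local"):
        raise InputError(f"unknown policy {policy!r}")
    config = config or io.CorrectionConfig()
    session = io.EditSession(mesh=initial_mesh.copy(), geometry=geometry, config=config)
    trace = metrics.CorrectionTrace(
        metadata={
            "policy": policy,
            "seed": seed,
            "dice_target": dice_target,
            "max_interactions": max_interactions,
            "config": config.to_dict(),
        }
    )
    current_dice = metrics.dice(contours.rasterize(session.mesh, geometry), gt_mask)
    trace.initial_dice = current_dice
    if current_dice >= dice_target:
        return session.mesh, trace

    schedule = _plane_schedule(gt_mesh, geometry, slice_stride)
    spacing = np.asarray(geometry.spacing)
    done = False
    while not done:
        dragged_this_sweep = False
        for plane in schedule:
            cur = contours.extract_contour(session.mesh, plane, geometry)
            gt = contours.extract_contour(gt_mesh, plane, geometry)
            if cur.is_empty or gt.is_empty:
                continue
            cur2d = cur.all_points_2d()
            gt2d = gt.all_points_2d()
            # in-plane error of every current contour point
            d2 = np.linalg.norm(cur2d[:, None, :] - gt2d[None, :, :], axis=2)
            nearest = d2.argmin(axis=1)
            errs = d2[np.arange(len(cur2d)), nearest]
            worst = int(errs.argmax())
            if errs[worst] < min_drag_mm:
                continue
            start2d = cur2d[worst]
            end2d = gt2d[nearest[worst]]
            records = []
            if policy == "local":
                start_w, _ = contours.lift_drag(plane, geometry, start2d, end2d)
                size = np.maximum(3.0 * errs[worst], 4.0 * spacing)
                records.append(io.set_local_grid_record(start_w, size))
            records.append(io.drag_record(plane, start2d, end2d))
            for rec in records:
                session.apply_record(rec)
                step = metrics.TraceStep(record=rec)
                if rec["kind"] == "drag":
                    d = metrics.dice(
                        contours.rasterize(session.mesh, geometry), gt_mask
                    )
                    step.dice = d
                    step.decreased_dice = d < current_dice
                    current_dice = d
                trace.steps.append(step)
            dragged_this_sweep = True
            if (
                current_dice >= dice_target
                or trace.interactions >= max_interactions
            ):
                done = True
                break
        if not dragged_this_sweep:
            break  # converged below the drag threshold everywhere
    return session.mesh, trace
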