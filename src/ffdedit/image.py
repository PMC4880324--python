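"""Image geometry and binary masks.

The method never reads intensities — a volume contributes only its voxel
grid (shape, spacing, origin), which bridges voxel indices, slice planes,
and world-mm mesh coordinates.  Convention: 0-based indices, world position
of voxel (i, j, k) = origin + index * spacing (voxel-center), axis-aligned
orientation only; anything else is rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryMismatchError, InputError

__all__ = ["ImageGeometry", "BinaryMask", "read_mask", "write_mask"]


@dataclass(frozen=True)
class ImageGeometry:
    """Voxel grid: ``shape`` counts, ``spacing`` mm/voxel, world ``origin``
    (mm) of the center of voxel (0, 0, 0)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be strictly positive, got {self.spacing}")
        if any(s <= 0 for s in self.shape):
            raise InputError(f"shape must be strictly positive, got {self.shape}")

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(
            self.spacing
        )

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def close_to(self, other: "ImageGeometry", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGeometry":
        return cls(
            shape=tuple(d["shape"]),
            spacing=tuple(d["spacing"]),
            origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
        )


@dataclass
class BinaryMask:
    """A boolean voxel array tied to its :class:`ImageGeometry`."""

    geometry: ImageGeometry
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.geometry.shape:
            raise GeometryMismatchError(
                f"mask shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.geometry.spacing))


def _check_identity_orientation(direction: np.ndarray, path: str) -> None:
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise InputError(
            f"{path}: only identity (axis-aligned) orientation is supported; "
            f"got direction matrix {direction.tolist()}"
        )


def read_mask(path: str | Path) -> BinaryMask:
    """Load a binary label volume from NIfTI (.nii/.nii.gz) or MetaImage
    (.mha/.mhd).  Foreground is any label >= 1."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        spacing = np.linalg.norm(rot, axis=0)
        _check_identity_orientation(rot / spacing, str(path))
        data = np.asarray(img.dataobj)
        geom = ImageGeometry(
            shape=data.shape, spacing=tuple(spacing), origin=tuple(affine[:3, 3])
        )
        return BinaryMask(geometry=geom, data=data >= 0.5)
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        direction = np.array(img.GetDirection()).reshape(3, 3)
        _check_identity_orientation(direction, str(path))
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        geom = ImageGeometry(
            shape=data.shape,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )
        return BinaryMask(geometry=geom, data=data >= 0.5)
    raise InputError(f"unsupported volume format: {path}")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as NIfTI or MetaImage, per the file extension."""
    path = Path(path)
    name = path.name.lower()
    data = mask.data.astype(np.uint8)
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(mask.geometry.spacing)
        affine[:3, 3] = mask.geometry.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(mask.geometry.spacing)
        img.SetOrigin(mask.geometry.origin)
        sitk.WriteImage(img, str(path))
        return
    raise InputError(f"unsupported volume format: {path}")
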