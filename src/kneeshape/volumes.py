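"""Label/probability volumes and their file formats (NIfTI, MetaImage).

A :class:`LabelVolume` is the segmentation substrate: either a 3D grid of
integer class labels ("label mode") or a 4D grid of per-class probabilities
with the class axis last ("probability mode"). Spacing and origin are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_CLASSES = ("background", "patella", "femur", "tibia")


@dataclass
class LabelVolume:
    data: np.ndarray
    classes: tuple = DEFAULT_CLASSES
    spacing: tuple = (0.7, 0.7, 0.7)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.data.ndim not in (3, 4):
            raise ValueError("volume must be 3D labels or 4D probabilities")
        if self.is_probability:
            if self.data.shape[-1] != len(self.classes):
                raise ValueError("probability class axis does not match classes")
            self.validate_probabilities()
        else:
            bad = np.setdiff1d(np.unique(self.data), np.arange(len(self.classes)))
            if bad.size:
                raise ValueError(f"labels outside class set: {bad.tolist()}")

    @property
    def is_probability(self) -> bool:
        return self.data.ndim == 4

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def validate_probabilities(self, atol: float = 1e-6) -> None:
        p = self.data
        if (p < -atol).any() or (p > 1 + atol).any():
            raise ValueError("probabilities outside [0, 1]")
        s = p.sum(axis=-1)
        if not np.allclose(s, 1.0, atol=atol):
            raise ValueError("per-voxel probabilities do not sum to 1")

    def one_hot(self) -> "LabelVolume":
        """Label mode -> probability mode (one-hot)."""
        if self.is_probability:
            return self
        p = np.eye(len(self.classes), dtype=float)[self.data.astype(int)]
        return LabelVolume(p, self.classes, self.spacing, self.origin)

    def same_grid(self, other: "LabelVolume") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    # ---------------------------------------------------------------- I/O
    def save(self, path) -> None:
        path = Path(path)
        if "".join(path.suffixes).endswith((".nii", ".nii.gz")):
            import nibabel as nib

            affine = np.diag(list(self.spacing) + [1.0])
            affine[:3, 3] = self.origin
            nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))
        elif path.suffix in (".mha", ".mhd"):
            import SimpleITK as sitk

            arr = np.asarray(self.data, dtype=np.float32)
            # SimpleITK expects z-fastest-last ordering; move axes accordingly
            img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0) if arr.ndim == 3 else (2, 1, 0, 3)))
            img.SetSpacing(self.spacing)
            img.SetOrigin(self.origin)
            sitk.WriteImage(img, str(path))
        else:
            raise ValueError(f"unsupported volume format: {path.name}")

    @classmethod
    def load(cls, path, classes=DEFAULT_CLASSES) -> "LabelVolume":
        path = Path(path)
        if "".join(path.suffixes).endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            origin = tuple(float(o) for o in img.affine[:3, 3])
        elif path.suffix in (".mha", ".mhd"):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            arr = sitk.GetArrayFromImage(img)
            data = np.transpose(arr, (2, 1, 0) if arr.ndim == 3 else (2, 1, 0, 3))
            spacing = tuple(img.GetSpacing())[:3]
            origin = tuple(img.GetOrigin())[:3]
        else:
            raise ValueError(f"unsupported volume format: {path.name}")
        if data.ndim == 3 and np.allclose(data, np.round(data)):
            data = data.astype(np.int16)
        return cls(data, classes, spacing, origin)
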