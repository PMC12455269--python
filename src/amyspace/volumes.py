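"""Lightweight in-memory carriers for co-registered 3D/4D imaging data.

All within-subject maps in this package are required to live on identical
grids (registration is assumed to have happened upstream), so a "grid" here
is simply the array shape, the voxel size and the NIfTI affine.  Volumes are
read and written as NIfTI-1 through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ScalarVolume", "MaskVolume", "SeriesVolume"]


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class ScalarVolume:
    """A 3D grid of real values: PET uptake, SUVR, metric or atlas map."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.affine, other.affine)
        )

    def require_same_grid(self, other, what: str = "volume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch with {what}: {self.shape}@{self.voxel_size} vs "
                f"{other.shape}@{other.voxel_size}"
            )

    @classmethod
    def from_nifti(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(data=data, voxel_size=tuple(img.header.get_zooms()[:3]),
                   affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))


@dataclass
class MaskVolume:
    """A 3D membership volume: boolean, or probability of inclusion in [0, 1]."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got shape {arr.shape}")
        if arr.dtype != bool:
            arr = arr.astype(np.float64)
            if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
                raise ValueError("probability mask values must lie in [0, 1]")
        self.data = arr
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_boolean(self) -> bool:
        return self.data.dtype == bool

    def as_bool(self) -> np.ndarray:
        """Boolean membership; probability masks count any positive weight."""
        if self.is_boolean:
            return self.data
        return self.data > 0

    def count(self) -> int:
        return int(np.count_nonzero(self.as_bool()))

    same_grid = ScalarVolume.same_grid
    require_same_grid = ScalarVolume.require_same_grid

    @classmethod
    def from_nifti(cls, path, boolean: bool = False) -> "MaskVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if boolean:
            data = data > 0.5
        return cls(data=data, voxel_size=tuple(img.header.get_zooms()[:3]),
                   affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        out = self.data.astype(np.uint8 if self.is_boolean else np.float64)
        img = nib.Nifti1Image(out, self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))


@dataclass
class SeriesVolume:
    """A 4D grid (3D space x time) with a repetition time in seconds."""

    data: np.ndarray
    tr: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def spatial_grid(self) -> ScalarVolume:
        """A scalar volume on this series' spatial grid (for grid checks)."""
        return ScalarVolume(np.zeros(self.shape[:3]), self.voxel_size, self.affine)

    @classmethod
    def from_nifti(cls, path, tr: float | None = None) -> "SeriesVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(data=np.asanyarray(img.dataobj, dtype=np.float64),
                   tr=tr, voxel_size=tuple(zooms[:3]), affine=np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header.set_zooms(self.voxel_size + (self.tr,))
        nib.save(img, str(path))
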