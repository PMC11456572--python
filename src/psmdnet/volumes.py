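"""Scalar image volumes and NIfTI input/output.

A :class:`ScalarVolume` is the atomic imaging object: a 3-D scalar field
(FA, MD, AD, RD, or an integer label map) together with its voxel geometry.
All volumes in one analysis are assumed to live in a common space, so the
affine is a plain voxel-size scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

MAP_NAMES = ("FA", "MD", "AD", "RD")


@dataclass
class ScalarVolume:
    """A 3-D scalar field with voxel geometry.

    Parameters
    ----------
    data
        3-D array of voxel values (unitless for FA, mm^2/s for
        diffusivities, non-negative integers for label maps).
    voxel_size
        Edge lengths of one voxel in mm, per axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def save(self, path: str) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine)
        nib.save(img, path)

    @classmethod
    def load(cls, path: str) -> "ScalarVolume":
        img = nib.load(path)
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), vs)


def save_vector_field(field: np.ndarray, voxel_size, path: str) -> None:
    """Write an (X, Y, Z, 3) vector field as a 4-D NIfTI."""
    aff = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(field, dtype=np.float64), aff), path)


def load_vector_field(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"expected an (X,Y,Z,3) field, got shape {data.shape}")
    return data, vs
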