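"""Sampling grid shared by all volumetric data structures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3D sampling grid with a voxel-to-world affine.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each spatial axis.
    voxel_size : tuple of float
        Voxel edge length in mm along each axis.
    affine : ndarray, optional
        4x4 voxel-to-world transform.  Defaults to a diagonal scaling by
        ``voxel_size`` (origin at voxel (0, 0, 0)).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None, compare=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        if len(voxel) != 3 or any(v <= 0 for v in voxel):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        if self.affine is None:
            aff = np.diag([*voxel, 1.0])
        else:
            aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be invertible")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid") -> bool:
        """Same shape and affine (within floating tolerance)."""
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-8
        )

    def sigma_voxels(self, fwhm_mm: float) -> tuple[float, float, float]:
        """Gaussian sigma per axis, in voxel units, for a given FWHM in mm."""
        sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return tuple(sigma_mm / v for v in self.voxel_size)


def check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "input") -> None:
    if not a.matches(b):
        raise ValueError(f"{what} grid {b.shape} does not match {a.shape}")
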