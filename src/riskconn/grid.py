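"""Spatial containers: the analysis grid, masks, and 4D BOLD series.

Everything downstream works on a common isotropic grid emulating MNI-152
space at 3 mm. The full MNI bounding box (61 x 73 x 61) is supported, but a
smaller grid with the same voxel size is the default for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# MNI-152 3 mm bounding box and the affine nilearn/FSL emit for it.
MNI_3MM_DIMS = (61, 73, 61)
MNI_3MM_ORIGIN = (-90.0, -126.0, -72.0)


def mni_like_affine(voxel_size: float = 3.0,
                    origin: tuple[float, float, float] = MNI_3MM_ORIGIN) -> np.ndarray:
    """RAS+ affine with isotropic voxels and the given world origin."""
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = origin
    return aff


@dataclass(frozen=True)
class BrainGrid:
    """An isotropic voxel grid with a grid -> world (MNI) affine."""

    dims: tuple[int, int, int]
    voxel_size: float = 3.0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.affine is None:
            # centre the grid on the world origin so coordinates look MNI-ish
            origin = tuple(-self.voxel_size * (d - 1) / 2 for d in self.dims)
            object.__setattr__(self, "affine", mni_like_affine(self.voxel_size, origin))
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size ** 3)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world/MNI mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]

    @classmethod
    def mni_3mm(cls) -> "BrainGrid":
        return cls(dims=MNI_3MM_DIMS, voxel_size=3.0, affine=mni_like_affine())


@dataclass
class BOLDSeries:
    """A masked 4D time series (x, y, z, t) on a :class:`BrainGrid`."""

    data: np.ndarray
    tr: float
    grid: BrainGrid
    mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != tuple(self.grid.dims):
            raise ValueError(
                f"data spatial shape {self.data.shape[:3]} != grid dims {self.grid.dims}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != data spatial shape {self.data.shape[:3]}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr

    def masked_series(self) -> np.ndarray:
        """(n_voxels, t) array of in-mask series, in C order of the mask."""
        return self.data[self.mask]

    def copy_with(self, data: np.ndarray) -> "BOLDSeries":
        return BOLDSeries(data=data, tr=self.tr, grid=self.grid, mask=self.mask.copy())


def make_gray_mask(grid: BrainGrid, target_voxels: int) -> np.ndarray:
    """Synthetic gray-matter mask: an ellipsoid shell with an exact voxel count.

    The outer ellipsoid stands in for the cortical envelope and an inner
    ellipsoid (removed) for deep white matter / ventricles, giving the shell
    topology of a gray-matter mask. The outer radius is bisected until the
    count reaches ``target_voxels``; surplus voxels are trimmed from the
    outermost rim deterministically.
    """
    nx, ny, nz = grid.dims
    if target_voxels < 1:
        raise ValueError("target_voxels must be >= 1")
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    r_out = (x / 0.90) ** 2 + (y / 0.95) ** 2 + (z / 0.85) ** 2
    r_in = (x / 0.55) ** 2 + (y / 0.62) ** 2 + (z / 0.50) ** 2
    shell = r_in > 1.0
    if int(shell.sum()) < target_voxels:
        raise ValueError(
            f"grid too small for {target_voxels} shell voxels (max {int(shell.sum())})")
    lo, hi = 0.0, float(r_out.max()) + 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if int(((r_out <= mid) & shell).sum()) < target_voxels:
            lo = mid
        else:
            hi = mid
    mask = (r_out <= hi) & shell
    n = int(mask.sum())
    if n > target_voxels:
        flat = np.argwhere(mask)
        order = np.argsort(r_out[mask], kind="stable")[:target_voxels]
        mask = np.zeros(grid.dims, dtype=bool)
        mask[tuple(flat[order].T)] = True
    return mask


def box_mask(grid: BrainGrid, margin: int = 0) -> np.ndarray:
    """Rectangular mask covering the grid, optionally inset by ``margin``."""
    mask = np.zeros(grid.dims, dtype=bool)
    sl = tuple(slice(margin, d - margin) for d in grid.dims)
    mask[sl] = True
    return mask
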