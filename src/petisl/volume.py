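"""3-D activity-concentration volumes and geometric primitives.

A :class:`Volume3D` couples a voxel array with a 4x4 affine mapping voxel
indices to world coordinates in millimetres (RAS+ convention, as stored in
NIfTI-1 headers).  All geometric operations in the package — VOI
measurement, sphere rasterization, PSF blurring, grid resampling — go
through this container so that volumes acquired on scanners with different
voxel grids can be addressed in one world frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptySupportError, ValidationError

#: Conversion factor between Gaussian FWHM and standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume3D:
    """A 3-D scalar field (kBq/mL, or SUV after normalisation) on a voxel grid.

    Parameters
    ----------
    data
        Voxel values, shape ``(nx, ny, nz)``.
    affine
        4x4 voxel-index -> world-mm transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    @classmethod
    def from_spacing(
        cls,
        data: np.ndarray,
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "Volume3D":
        """Build a volume with an axis-aligned affine from voxel spacing (mm)."""
        spacing = np.asarray(spacing, dtype=float)
        if np.any(spacing <= 0):
            raise ValidationError("voxel spacing must be > 0 on every axis")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = origin
        return cls(np.asarray(data, dtype=np.float64), affine)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing along each index axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    # -- bookkeeping --------------------------------------------------------

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.affine.copy())

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """A new volume on the same grid holding *data*."""
        return Volume3D(np.asarray(data, dtype=np.float64), self.affine.copy())

    @property
    def total_activity_kbq(self) -> float:
        """Sum of AC x voxel volume over the grid, in kBq (data in kBq/mL)."""
        return float(self.data.sum() * self.voxel_volume_mm3 / 1000.0)


# ---------------------------------------------------------------------------
# geometric helpers


def _voxel_bbox(vol: Volume3D, centre_mm: np.ndarray, radius_mm: float):
    """Voxel-index bounding box (inclusive lo, exclusive hi) of a world sphere."""
    centre_mm = np.asarray(centre_mm, dtype=float)
    corners = centre_mm + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    vox = vol.world_to_voxel(corners)
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 1, np.array(vol.shape))
    return lo, hi


def sphere_mask(vol: Volume3D, centre_mm, radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within a world-space sphere."""
    centre_mm = np.asarray(centre_mm, dtype=float)
    lo, hi = _voxel_bbox(vol, centre_mm, radius_mm)
    mask = np.zeros(vol.shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = vol.voxel_to_world(idx)
    inside = np.sum((world - centre_mm) ** 2, axis=1) <= radius_mm**2
    mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    return mask


def sphere_inside_grid(vol: Volume3D, centre_mm, radius_mm: float) -> bool:
    """True when the world-space sphere lies entirely within the voxel grid.

    Conservative check through the sphere's world axis-aligned bounding box.
    """
    centre_mm = np.asarray(centre_mm, dtype=float)
    corners = centre_mm + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    vox = vol.world_to_voxel(corners)
    upper = np.array(vol.shape) - 0.5
    return bool(np.all(vox >= -0.5) and np.all(vox <= upper))


def blur_volume(vol: Volume3D, fwhm_mm) -> Volume3D:
    """Gaussian PSF blur with reflective boundaries.

    The kernel is normalised and the boundary is reflective, so the total
    activity in the volume is conserved to numerical precision; blurring a
    constant field returns the constant.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValidationError("PSF FWHM must be >= 0")
    if np.all(fwhm == 0):
        return vol.copy()
    sigma_vox = fwhm * FWHM_TO_SIGMA / vol.spacing
    blurred = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="reflect")
    return vol.with_data(blurred)


def resample_to_grid(
    vol: Volume3D, affine: np.ndarray, shape: tuple[int, int, int], order: int = 1
) -> Volume3D:
    """Resample a volume onto a new grid given by (affine, shape).

    Trilinear by default; points outside the source grid take the nearest
    edge value.  When the target grid is identical to the source the data is
    copied untouched.
    """
    affine = np.asarray(affine, dtype=float)
    if tuple(shape) == vol.shape and np.allclose(affine, vol.affine, atol=1e-12):
        return vol.copy()
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    world = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    src = vol.world_to_voxel(world)
    out = ndimage.map_coordinates(vol.data, src.T, order=order, mode="nearest")
    return Volume3D(out.reshape(shape), affine)


def voi_radius_mm(volume_cm3: float) -> float:
    """Radius of a sphere of the given volume: r = (3V / 4 pi)^(1/3)."""
    if volume_cm3 <= 0:
        raise ValidationError("VOI volume must be > 0")
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def require_nonempty(mask: np.ndarray, what: str) -> None:
    if not mask.any():
        raise EmptySupportError(f"{what} covers no voxel of the grid")
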