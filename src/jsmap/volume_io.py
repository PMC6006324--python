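"""Image volume I/O, voxel/world geometry, and 1D ray sampling.

Volumes are scalar 3D grids in Hounsfield units with a 4x4 voxel-index to
world-millimetre affine.  All downstream measurement happens on 1D density
profiles interpolated along world-space rays (a patch vertex plus its outward
normal), parameterised in millimetres with t = 0 at the ray origin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Unreadable or unsupported volume file."""


class OutOfBoundsError(ValueError):
    """Requested ray segment lies entirely outside the image grid."""


@dataclass
class ImageVolume:
    """A 3D scalar image in HU with voxel-to-world affine geometry.

    ``data[i, j, k]`` corresponds to the world point ``affine @ (i, j, k, 1)``.
    Anisotropic spacing (e.g. 0.31 x 0.31 mm in-plane, 1.5 mm slices) is the
    normal case for clinical CT.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> np.ndarray:
        """(2, 3) min/max world coordinates of the eight grid corners."""
        n = np.array(self.shape, dtype=float) - 1
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])]
        )
        w = self.voxel_to_world(corners)
        return np.vstack([w.min(axis=0), w.max(axis=0)])


@dataclass
class LineProfile:
    """Interpolated HU samples along a world-space ray.

    ``values[i]`` is the image intensity at ``origin + t[i] * direction``;
    t is uniform and strictly increasing, in mm.  ``oob`` flags samples that
    fell outside the grid and were filled with the nearest edge value.
    """

    t: np.ndarray
    values: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    oob: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        self.direction = d / n
        if self.oob is None:
            self.oob = np.zeros(self.t.shape, dtype=bool)
        steps = np.diff(self.t)
        if len(steps) and (steps.min() <= 0 or np.ptp(steps) > 1e-9):
            raise ValueError("t must be strictly increasing with constant step")

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def oob_fraction(self) -> float:
        return float(self.oob.mean()) if len(self.oob) else 0.0

    def reversed(self) -> "LineProfile":
        """The same physical samples walked in the opposite direction."""
        return LineProfile(
            t=-self.t[::-1],
            values=self.values[::-1].copy(),
            origin=self.origin,
            direction=-self.direction,
            oob=self.oob[::-1].copy(),
        )


def load_volume(path: str | os.PathLike) -> ImageVolume:
    """Load a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    HU values are passed through unrescaled beyond the format's own
    slope/intercept (applied by the reader).
    """
    path = os.fspath(path)
    lower = path.lower()
    try:
        if lower.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(path)
            return ImageVolume(np.asarray(img.get_fdata()), np.asarray(img.affine))
        if lower.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.ReadImage(path)
            return ImageVolume(*_from_sitk(img))
    except (OSError, ValueError) as exc:  # pragma: no cover - passthrough detail
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    raise VolumeFormatError(f"unsupported volume format: {path!r}")


def save_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                                 volume.affine), path)
        return
    if lower.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        sitk.WriteImage(_to_sitk(volume), path)
        return
    raise VolumeFormatError(f"unsupported volume format: {path!r}")


def _from_sitk(img) -> tuple[np.ndarray, np.ndarray]:
    import SimpleITK as sitk  # noqa: F401

    # sitk arrays are (z, y, x); transpose to index order (x, y, z) = (i, j, k)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing())
    origin = np.asarray(img.GetOrigin())
    affine = np.eye(4)
    affine[:3, :3] = direction @ np.diag(spacing)
    affine[:3, 3] = origin
    return data, affine


def _to_sitk(volume: ImageVolume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(volume.data.transpose(2, 1, 0), dtype=np.float32)
    )
    spacing = volume.spacing
    direction = volume.affine[:3, :3] / spacing[np.newaxis, :]
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetDirection(tuple(direction.ravel()))
    img.SetOrigin(tuple(volume.affine[:3, 3]))
    return img


def sample_profile(
    volume: ImageVolume,
    origin: np.ndarray,
    direction: np.ndarray,
    t_min: float,
    t_max: float,
    step: float,
    order: int = 3,
) -> LineProfile:
    """Interpolate a 1D density profile along ``origin + t * direction``.

    Order 3 (tricubic spline) is the default; order 1 gives trilinear.
    Samples beyond the grid take the nearest-edge value and are flagged in
    ``LineProfile.oob``; a segment entirely outside raises OutOfBoundsError.
    """
    if step <= 0 or t_max <= t_min:
        raise ValueError("need step > 0 and t_max > t_min")
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = int(round((t_max - t_min) / step)) + 1
    t = t_min + step * np.arange(n)
    points = origin[np.newaxis, :] + t[:, np.newaxis] * direction[np.newaxis, :]
    vox = volume.world_to_voxel(points)
    hi = np.array(volume.shape, dtype=float) - 1
    oob = np.any((vox < 0) | (vox > hi), axis=1)
    if oob.all():
        raise OutOfBoundsError("profile segment lies entirely outside the volume")
    values = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), vox.T, order=order, mode="nearest"
    )
    return LineProfile(t=t, values=values, origin=origin, direction=direction,
                       oob=oob)


def sample_profiles(
    volume: ImageVolume,
    origins: np.ndarray,
    directions: np.ndarray,
    t: np.ndarray,
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised profile sampling for many rays sharing one t grid.

    Returns ``(values, oob)`` of shape (n_rays, n_t).  Used for whole-patch
    sampling where a Python loop over scipy calls would dominate runtime.
    """
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    directions = directions / np.maximum(norms, 1e-12)
    t = np.asarray(t, dtype=float)
    pts = origins[:, np.newaxis, :] + t[np.newaxis, :, np.newaxis] * directions[:, np.newaxis, :]
    flat = pts.reshape(-1, 3)
    vox = volume.world_to_voxel(flat)
    hi = np.array(volume.shape, dtype=float) - 1
    oob = np.any((vox < 0) | (vox > hi), axis=1).reshape(len(origins), len(t))
    values = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), vox.T, order=order, mode="nearest"
    ).reshape(len(origins), len(t))
    return values, oob
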