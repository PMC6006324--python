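"""Synthetic two-bone CT phantoms with analytic ground-truth joint space width.

Two geometries are provided:

* ``plates`` — two parallel cortical plates perpendicular to the z axis,
  separated by a uniform gap of joint tissue.  The simplest test object for
  profile models and edge localisation.
* ``ball_socket`` — a spherical "femoral head" (cortical shell over a
  trabecular interior) opposed by a concentric acetabular shell subtending a
  polar cap, with a radially measured gap g(theta, phi) of joint tissue in
  between.  The cap rim is the joint margin and is emitted as a boundary
  polyline; the region outside the cap is uncovered so that boundary
  extraction is non-trivial.

Continuous geometry is rendered with per-axis sub-voxel supersampling
(partial volume), convolved with an anisotropic Gaussian PSF, and corrupted
with iid Gaussian noise.  Densities, spacings and blurs default to a clinical
hip CT regime: 0.31 x 0.31 mm pixels, 1.5 mm slices, PSF FWHM 0.87 mm
in-plane and 1.00 mm out-of-plane, joint tissue 35 HU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: clinical CT acquisition regime used throughout validation
CLINICAL_SPACING = (0.31, 0.31, 1.5)
CLINICAL_PSF_FWHM = (0.87, 0.87, 1.00)

#: high-resolution peripheral QCT regime (isotropic)
HR_SPACING = (0.082, 0.082, 0.082)
HR_PSF_FWHM = (0.089, 0.089, 0.089)

GapFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class PhantomSpec:
    """Parametric description of a two-bone phantom.

    ``gap`` is either a constant in mm or a function g(theta, phi) of the
    polar/azimuthal angles (ball_socket) returning mm; it must be >= 0
    everywhere.  ``psf`` is the per-axis Gaussian blur, interpreted as FWHM
    when ``psf_is_fwhm`` (the manufacturer-style convention) else as sigma.
    """

    geometry: str = "ball_socket"
    femoral_radius: float = 20.0
    cortex_thickness: float = 1.5
    gap: float | GapFunction = 3.0
    interior_hu: float = 300.0
    cortex_hu: float = 1400.0
    joint_tissue_hu: float = 35.0
    background_hu: float = 35.0
    psf: tuple[float, float, float] = CLINICAL_PSF_FWHM
    psf_is_fwhm: bool = True
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = CLINICAL_SPACING
    cap_angle_deg: float = 60.0
    plate_extent: float = 20.0
    margin: float = 4.0
    supersample: int = 3
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("plates", "ball_socket"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        if self.cortex_hu <= self.joint_tissue_hu:
            raise ValueError("cortex density must exceed joint tissue density")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def psf_sigma(self) -> np.ndarray:
        s = np.asarray(self.psf, dtype=float)
        return s * FWHM_TO_SIGMA if self.psf_is_fwhm else s

    def gap_at(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        if callable(self.gap):
            g = np.asarray(self.gap(np.asarray(theta), np.asarray(phi)),
                           dtype=float)
        else:
            g = np.full(np.broadcast(np.asarray(theta),
                                     np.asarray(phi)).shape, float(self.gap))
        return g

    @property
    def max_gap(self) -> float:
        th = np.linspace(0, math.pi, 181)
        ph = np.linspace(0, 2 * math.pi, 181)
        tt, pp = np.meshgrid(th, ph)
        return float(self.gap_at(tt, pp).max())


def _ramp(u, w):
    """Linear edge ramp: 0 below -w/2, 1 above +w/2.

    Antialiases material boundaries at one sub-voxel width so that the box
    average over sub-samples localises each edge without alignment bias (a
    hard threshold lands edges on the sub-grid with a systematic
    half-sub-voxel shift).  The extra symmetric blur (w/sqrt(12), well below
    the PSF) is absorbed by the fitted profile sigma.
    """
    return np.clip(u / w + 0.5, 0.0, 1.0)


def _density_ball_socket(spec: PhantomSpec, x, y, z, sub_sp) -> np.ndarray:
    r = np.sqrt(x * x + y * y + z * z)
    rs = np.maximum(r, 1e-9)
    # edge ramp width: sub-voxel size projected onto the radial normal
    w = np.sqrt(((x / rs) * sub_sp[0]) ** 2 + ((y / rs) * sub_sp[1]) ** 2
                + ((z / rs) * sub_sp[2]) ** 2)
    w = np.maximum(w, float(min(sub_sp)) / 2.0)
    # polar angle from +z; cap centred on the pole
    theta = np.arccos(np.clip(z / rs, -1, 1))
    phi = np.arctan2(y, x)
    g = spec.gap_at(theta, phi)
    if np.any(g < 0):
        raise ValueError("gap function must be >= 0 everywhere")
    R = spec.femoral_radius
    tc = spec.cortex_thickness
    ci, cc, cj, cb = (spec.interior_hu, spec.cortex_hu,
                      spec.joint_tissue_hu, spec.background_hu)

    shared = ci + (cc - ci) * _ramp(r - (R - tc), w)
    v_cap = shared + (cj - cc) * _ramp(r - R, w) \
        + (cc - cj) * _ramp(r - (R + g), w) \
        + (cb - cc) * _ramp(r - (R + g + tc), w)
    v_out = shared + (cb - cc) * _ramp(r - R, w)
    # blend across the cap rim along the tangential arc length
    cap_w = _ramp(R * (math.radians(spec.cap_angle_deg) - theta), w)
    return (cap_w * v_cap + (1.0 - cap_w) * v_out).astype(np.float32)


def _density_plates(spec: PhantomSpec, x, y, z, sub_sp) -> np.ndarray:
    g = float(spec.gap) if not callable(spec.gap) else float(
        spec.gap_at(np.array(0.0), np.array(0.0)))
    if g < 0:
        raise ValueError("gap must be >= 0")
    tc = spec.cortex_thickness
    w = float(sub_sp[2])  # plate normals are +z
    ci, cc, cj, cb = (spec.interior_hu, spec.cortex_hu,
                      spec.joint_tissue_hu, spec.background_hu)
    out = ci + (cc - ci) * _ramp(z + tc, w) + (cj - cc) * _ramp(z, w) \
        + (cc - cj) * _ramp(z - g, w) + (cb - cc) * _ramp(z - g - tc, w)
    return out.astype(np.float32)


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Affine and shape covering the phantom plus margin, centred on origin."""
    sp = np.asarray(spec.spacing, dtype=float)
    if spec.geometry == "ball_socket":
        half = spec.femoral_radius + spec.max_gap + spec.cortex_thickness + spec.margin
        half = np.array([half, half, half])
    else:
        half = np.array([
            spec.plate_extent,
            spec.plate_extent,
            spec.cortex_thickness + float(spec.max_gap) + spec.margin,
        ])
    shape = tuple(int(np.ceil(2 * h / s)) + 1 for h, s in zip(half, sp))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    center = np.asarray(spec.center_offset, dtype=float)
    affine[:3, 3] = center - sp * (np.array(shape) - 1) / 2.0
    return affine, shape


def _render(spec: PhantomSpec, density_fn, affine, shape,
            blur: bool) -> np.ndarray:
    """Supersample, evaluate, optionally PSF-blur, box-average back to voxels."""
    S = spec.supersample
    sp = np.asarray(spec.spacing, dtype=float)
    sub_sp = sp / S
    center = np.asarray(spec.center_offset, dtype=float)
    axes = []
    for a in range(3):
        # sub-sample centres within each voxel
        idx = np.arange(shape[a] * S)
        coord = affine[a, 3] + sp[a] * ((idx + 0.5) / S - 0.5) - center[a]
        axes.append(coord.astype(np.float32))
    # slab-wise evaluation with broadcasting keeps peak memory at one
    # float32 supersampled volume plus a thin slab of intermediates
    nx = shape[0] * S
    vol = np.empty((nx, shape[1] * S, shape[2] * S), dtype=np.float32)
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    chunk = max(1, int(2e7 / (vol.shape[1] * vol.shape[2])))
    for i0 in range(0, nx, chunk):
        x = axes[0][i0:i0 + chunk, None, None]
        vol[i0:i0 + chunk] = density_fn(spec, x, y, z, sub_sp)
    if blur:
        sigma_vox = spec.psf_sigma / sub_sp
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    # box-average S^3 sub-voxels -> voxel value (detector partial volume)
    vol = vol.reshape(shape[0], S, shape[1], S, shape[2], S).mean(axis=(1, 3, 5))
    return vol.astype(np.float32)


def _femoral_mask(spec: PhantomSpec, x, y, z, sub_sp) -> np.ndarray:
    if spec.geometry == "ball_socket":
        r = np.sqrt(x * x + y * y + z * z)
        rs = np.maximum(r, 1e-9)
        w = np.sqrt(((x / rs) * sub_sp[0]) ** 2 + ((y / rs) * sub_sp[1]) ** 2
                    + ((z / rs) * sub_sp[2]) ** 2)
        w = np.maximum(w, float(min(sub_sp)) / 2.0)
        return _ramp(spec.femoral_radius - r, w).astype(np.float32)
    return _ramp(-z, float(sub_sp[2])).astype(np.float32)


def boundary_polyline(spec: PhantomSpec, n_points: int = 200) -> np.ndarray:
    """Closed joint-margin loop on the femoral outer surface (world mm)."""
    center = np.asarray(spec.center_offset, dtype=float)
    if spec.geometry == "ball_socket":
        cap = math.radians(spec.cap_angle_deg)
        phi = np.linspace(0, 2 * math.pi, n_points, endpoint=False)
        pts = np.stack([
            spec.femoral_radius * math.sin(cap) * np.cos(phi),
            spec.femoral_radius * math.sin(cap) * np.sin(phi),
            np.full_like(phi, spec.femoral_radius * math.cos(cap)),
        ], axis=1) + center
    else:
        e = spec.plate_extent - spec.margin
        k = n_points // 4
        side = np.linspace(-e, e, k, endpoint=False)
        pts = np.concatenate([
            np.stack([side, np.full(k, -e), np.zeros(k)], axis=1),
            np.stack([np.full(k, e), side, np.zeros(k)], axis=1),
            np.stack([-side, np.full(k, e), np.zeros(k)], axis=1),
            np.stack([np.full(k, -e), -side, np.zeros(k)], axis=1),
        ]) + center
    return np.vstack([pts, pts[:1]])  # closed loop


def generate_volume(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, np.ndarray]:
    """Render ``(image, femoral mask, joint-margin boundary polyline)``.

    Deterministic: identical spec (including seed) gives a bit-identical
    volume.
    """
    affine, shape = _grid(spec)
    density_fn = (_density_ball_socket if spec.geometry == "ball_socket"
                  else _density_plates)
    data = _render(spec, density_fn, affine, shape, blur=True)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd,
                                 size=data.shape).astype(np.float32)
    mask = _render(spec, _femoral_mask, affine, shape, blur=False)
    mask = (mask >= 0.5).astype(np.uint8)
    boundary = boundary_polyline(spec)
    return ImageVolume(data, affine), ImageVolume(mask, affine), boundary


def ground_truth_jsw(spec: PhantomSpec, patch, tolerance: float = 1.0) -> np.ndarray:
    """Analytic per-vertex joint space width for ``patch`` on this phantom.

    Vertices must lie on the femoral outer surface to within ``tolerance``
    (mm); the voxelised surface mesh carries discretisation error up to about
    half a slice thickness, hence the default.
    """
    verts = np.asarray(patch.mesh.vertices if hasattr(patch, "mesh")
                       else patch.vertices, dtype=float)
    center = np.asarray(spec.center_offset, dtype=float)
    p = verts - center
    if spec.geometry == "ball_socket":
        r = np.linalg.norm(p, axis=1)
        off = np.abs(r - spec.femoral_radius)
        if off.max() > tolerance:
            raise ValueError(
                f"vertex {off.argmax()} is {off.max():.2f} mm off the femoral "
                f"surface (tolerance {tolerance} mm)")
        theta = np.arccos(np.clip(p[:, 2] / np.maximum(r, 1e-12), -1, 1))
        phi = np.arctan2(p[:, 1], p[:, 0])
        return spec.gap_at(theta, phi)
    off = np.abs(p[:, 2])
    if off.max() > tolerance:
        raise ValueError("patch vertices are off the femoral plate surface")
    return np.full(len(p), float(spec.gap))


def simulate_two_operators(
    spec: PhantomSpec, boundary_jitter: float, n_points: int = 200,
    n_harmonics: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Two joint-margin delineations differing by a smooth tangential jitter.

    Emulates inter-operator variability in margin definition: the second loop
    displaces the cap rim along the sphere surface by a smooth periodic random
    field whose mean absolute amplitude equals ``boundary_jitter`` (mm).
    """
    if boundary_jitter < 0:
        raise ValueError("boundary_jitter must be >= 0")
    loop1 = boundary_polyline(spec, n_points)
    if boundary_jitter == 0:
        return loop1, loop1.copy()
    if spec.geometry != "ball_socket":
        raise NotImplementedError("operator simulation needs ball_socket")
    rng = np.random.default_rng(spec.seed + 1)
    phi = np.linspace(0, 2 * math.pi, n_points, endpoint=False)
    f = np.zeros(n_points)
    for k in range(1, n_harmonics + 1):
        f += rng.normal() * np.cos(k * phi) + rng.normal() * np.sin(k * phi)
    f /= max(np.abs(f).mean(), 1e-12)
    cap = math.radians(spec.cap_angle_deg)
    dtheta = (boundary_jitter / spec.femoral_radius) * f
    theta = np.clip(cap + dtheta, 0.05, math.pi - 0.05)
    center = np.asarray(spec.center_offset, dtype=float)
    pts = np.stack([
        spec.femoral_radius * np.sin(theta) * np.cos(phi),
        spec.femoral_radius * np.sin(theta) * np.sin(phi),
        spec.femoral_radius * np.cos(theta),
    ], axis=1) + center
    loop2 = np.vstack([pts, pts[:1]])
    return loop1, loop2


def clinical_spec(**overrides) -> PhantomSpec:
    """Ball-and-socket phantom at the clinical CT acquisition regime."""
    return replace(PhantomSpec(), **overrides)


def hr_spec(**overrides) -> PhantomSpec:
    """Phantom at the high-resolution (0.082 mm isotropic) regime."""
    base = PhantomSpec(spacing=HR_SPACING, psf=HR_PSF_FWHM, noise_sd=50.0)
    return replace(base, **overrides)
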