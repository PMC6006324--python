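"""Shared fixtures: small synthetic phantoms and derived surfaces.

Everything is generated at run time; fixture phantoms use coarser
supersampling and smaller geometry than the clinical-regime studies in the
acceptance tests, purely to keep the unit suite fast.
"""

import numpy as np
import pytest
import trimesh

from jsmap import (JSMConfig, PhantomSpec, cut_patch, generate_volume,
                   mesh_from_mask, retriangulate)


@pytest.fixture(scope="session")
def ball_phantom():
    """Isotropic 0.5 mm ball-and-socket phantom, uniform 3.0 mm gap,
    noiseless; radius 10 mm, cortex 1.5 mm."""
    spec = PhantomSpec(geometry="ball_socket", femoral_radius=10.0, gap=3.0,
                       cortex_thickness=1.5, spacing=(0.5, 0.5, 0.5),
                       psf=(0.8, 0.8, 0.8), psf_is_fwhm=False, noise_sd=0.0,
                       cap_angle_deg=60, margin=3.0, supersample=2, seed=0)
    volume, mask, boundary = generate_volume(spec)
    return spec, volume, mask, boundary


@pytest.fixture(scope="session")
def ball_mesh(ball_phantom):
    _, _, mask, _ = ball_phantom
    return mesh_from_mask(mask)


@pytest.fixture(scope="session")
def ball_patch(ball_phantom, ball_mesh):
    spec, volume, _, boundary = ball_phantom
    patch = cut_patch(ball_mesh, boundary,
                      seed_point=np.array([0.0, 0.0, spec.femoral_radius + 3]))
    return retriangulate(patch, 1000)


@pytest.fixture(scope="session")
def measured_ball(ball_phantom, ball_mesh, ball_patch):
    """Raw per-vertex measurement of the uniform-gap ball phantom."""
    from jsmap import estimate_peak_density, measure_patch

    spec, volume, _, _ = ball_phantom
    y_peak = estimate_peak_density(volume, ball_mesh)
    jsw_map = measure_patch(ball_patch, volume, y_peak=y_peak)
    return spec, jsw_map


@pytest.fixture(scope="session")
def bumpy_cap():
    """Asymmetric open cap surface: all similarity DOF observable."""
    m = trimesh.creation.icosphere(4, radius=15.0)
    v = np.asarray(m.vertices)
    u = v / np.linalg.norm(v, axis=1)[:, None]
    bump = (1.0 + 0.12 * np.sin(6.3 * u[:, 0])
            + 0.10 * np.cos(7.5 * u[:, 1] + 1.0)
            + 0.08 * np.sin(6.8 * u[:, 2] + 0.5))
    v2 = u * (15.0 * bump)[:, None]
    keep = v2[:, 2] > 4.0
    fi = keep[m.faces].all(axis=1)
    faces = m.faces[fi]
    vids = np.unique(faces)
    remap = -np.ones(len(v2), dtype=int)
    remap[vids] = np.arange(len(vids))
    return trimesh.Trimesh(v2[vids], remap[faces], process=False)


@pytest.fixture
def config():
    return JSMConfig()
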