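"""Synthetic phantom generator: geometry, PSF realism, ground truth."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.special import ndtr

from jsmap import (PhantomSpec, generate_volume, ground_truth_jsw,
                   simulate_two_operators)


def fine_plates(**over):
    base = PhantomSpec(geometry="plates", gap=8.0, cortex_thickness=8.0,
                       plate_extent=6.0, spacing=(0.25, 0.25, 0.25),
                       psf=(0.8, 0.8, 0.8), psf_is_fwhm=False, noise_sd=0.0,
                       margin=5.0, supersample=3, seed=0)
    return dataclasses.replace(base, **over)


def test_determinism_bit_identical():
    spec = fine_plates(noise_sd=15.0, spacing=(0.5, 0.5, 0.5))
    v1, m1, b1 = generate_volume(spec)
    v2, m2, b2 = generate_volume(spec)
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(m1.data, m2.data)
    np.testing.assert_array_equal(b1, b2)


def test_negative_gap_rejected():
    spec = PhantomSpec(geometry="ball_socket", femoral_radius=8.0,
                       gap=lambda th, ph: np.cos(2 * th) - 0.5,
                       spacing=(1.0, 1.0, 1.0), supersample=1, noise_sd=0)
    with pytest.raises(ValueError, match="gap"):
        generate_volume(spec)


def test_gap_voxel_is_joint_tissue():
    spec = fine_plates(psf=(1e-6, 1e-6, 1e-6), gap=3.0)
    vol, _, _ = generate_volume(spec)
    centre = vol.world_to_voxel(np.array([0.0, 0.0, 1.5]))[0]
    idx = tuple(int(round(c)) for c in centre)
    assert vol.data[idx] == pytest.approx(35.0, abs=0.5)


def test_blurred_plate_matches_erf_closed_form():
    from jsmap import sample_profile

    spec = fine_plates()
    vol, _, _ = generate_volume(spec)
    prof = sample_profile(vol, np.array([0.3, -0.2, 4.0]),
                          np.array([0.0, 0.0, 1.0]), -6, 6, 0.05)
    # composite kernel: PSF + voxel box + geometry antialias ramp
    sig = np.sqrt(0.8 ** 2 + 0.25 ** 2 / 12 + (0.25 / 3) ** 2 / 12)
    z = prof.t + 4.0
    expected = np.full_like(z, spec.interior_hu)
    for edge, jump in ((-8.0, spec.cortex_hu - spec.interior_hu),
                       (0.0, spec.joint_tissue_hu - spec.cortex_hu),
                       (8.0, spec.cortex_hu - spec.joint_tissue_hu),
                       (16.0, spec.background_hu - spec.cortex_hu)):
        expected += jump * ndtr((z - edge) / sig)
    rms = np.sqrt(np.mean((prof.values - expected) ** 2))
    assert rms < 1.0


def test_edge_spread_recovers_psf_sigma():
    from jsmap import sample_profile

    spec = fine_plates(spacing=(0.1, 0.1, 0.1))
    vol, _, _ = generate_volume(spec)
    prof = sample_profile(vol, np.array([0.0, 0.0, 0.0]),
                          np.array([0.0, 0.0, 1.0]), -4, 4, 0.02)
    f = lambda t, e, s, lo, hi: lo + (hi - lo) * ndtr((t - e) / s)
    p, _ = curve_fit(f, prof.t, prof.values, p0=[0.0, 0.5, 1400.0, 35.0])
    assert abs(p[0]) < 0.01
    assert abs(abs(p[1]) - 0.8) / 0.8 < 0.02


def test_ground_truth_constant_gap(ball_patch, ball_phantom):
    spec = ball_phantom[0]
    truth = ground_truth_jsw(spec, ball_patch)
    np.testing.assert_allclose(truth, 3.0, atol=1e-12)


def test_ground_truth_angular_function():
    spec = PhantomSpec(geometry="ball_socket", femoral_radius=10.0,
                       gap=lambda th, ph: 2.5 + 1.0 * np.cos(th))

    class FakePatch:
        vertices = np.array([[0.0, 0.0, 10.0],      # pole, theta = 0
                             [10.0, 0.0, 0.0]])      # equator, theta = pi/2

    truth = ground_truth_jsw(spec, FakePatch())
    np.testing.assert_allclose(truth, [3.5, 2.5], atol=1e-12)


def test_ground_truth_rejects_off_surface_vertices():
    spec = PhantomSpec(geometry="ball_socket", femoral_radius=10.0, gap=3.0)

    class FakePatch:
        vertices = np.array([[0.0, 0.0, 14.0]])

    with pytest.raises(ValueError, match="off the femoral"):
        ground_truth_jsw(spec, FakePatch())


def test_ground_truth_radial_ray_cast_oracle():
    # independent oracle: cast dense radial rays through the *continuous*
    # phantom density and find the joint-tissue -> acetabular-cortex
    # transition; compare with the analytic per-vertex ground truth
    from jsmap.phantom import _density_ball_socket

    spec = PhantomSpec(geometry="ball_socket", femoral_radius=10.0,
                       gap=lambda th, ph: 2.0 + 0.8 * np.cos(th),
                       cap_angle_deg=60)
    rng = np.random.default_rng(3)
    theta = rng.uniform(0.05, np.radians(50), 20)
    phi = rng.uniform(0, 2 * np.pi, 20)
    dirs = np.stack([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi), np.cos(theta)], axis=1)

    class FakePatch:
        vertices = dirs * spec.femoral_radius

    truth = ground_truth_jsw(spec, FakePatch())
    sub = np.full(3, 1e-4)
    ts = np.arange(0.0005, 5.0, 0.001)
    for d, g_true in zip(dirs, truth):
        pts = d[None, :] * (spec.femoral_radius + ts[:, None])
        dens = _density_ball_socket(spec, pts[:, 0], pts[:, 1], pts[:, 2],
                                    sub)
        in_cortex = dens > 0.5 * (spec.cortex_hu + spec.joint_tissue_hu)
        crossing = ts[np.argmax(in_cortex)]
        assert abs(crossing - g_true) < 0.005


def test_two_operators_jitter():
    spec = PhantomSpec(geometry="ball_socket", femoral_radius=20.0, gap=3.0,
                       seed=5)
    l1, l2 = simulate_two_operators(spec, 0.0)
    np.testing.assert_array_equal(l1, l2)
    l1, l2 = simulate_two_operators(spec, 2.0)
    d = np.linalg.norm(l1 - l2, axis=1).mean()
    assert 1.0 <= d <= 3.0
    # determinism
    l1b, l2b = simulate_two_operators(spec, 2.0)
    np.testing.assert_array_equal(l2, l2b)
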