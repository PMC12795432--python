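import math

import numpy as np
import pytest

from octsim import accumulate_profile, make_rng_stream
from octsim.detection import (assign_bin, attenuation_adjustment,
                              corrected_opl, detect_conventional,
                              detect_hybrid, direction_weight,
                              position_weight, transmission_T)
from octsim.simulate import simulate_profiles
from octsim.transport import PhotonRecord, PhotonRecords


def make_records(**overrides) -> PhotonRecords:
    """One-record batch with a perfectly mode-matched default exit."""
    defaults = dict(weight=1.0, exit_x=0.0, exit_y=0.0, vx=0.0, vy=0.0,
                    vz=-1.0, theta_i=0.0, opl_total=2.0, lsx=0.0, lsy=0.0,
                    lsz=1.0, n_scatters=1)
    defaults.update(overrides)
    return PhotonRecords.from_records([PhotonRecord(**defaults)])


# --- amplitude weights ----------------------------------------------------

def test_position_weight(beam):
    w0 = beam.w0
    assert position_weight(0, 0, w0) == pytest.approx(1.0)
    assert position_weight(w0, 0, w0) == pytest.approx(math.exp(-1))
    assert position_weight(3 * w0, 4 * w0, w0) == pytest.approx(math.exp(-25))


def test_direction_weight(beam):
    td = beam.theta_div
    assert direction_weight(0, 0, td) == pytest.approx(1.0)
    assert direction_weight(td, 0, td) == pytest.approx(math.exp(-1))


def test_direction_weight_wavevector_identity(beam):
    """The plane-wave coupling exp(-zR^2 (vx^2+vy^2)/w0^2) equals the
    divergence-angle form for theta_div = w0/zR."""
    rng = make_rng_stream(3, 0)
    v = 0.02 * rng.standard_normal((100, 2))
    lhs = np.exp(-(beam.zR ** 2 / beam.w0 ** 2) * (v[:, 0] ** 2 + v[:, 1] ** 2))
    rhs = direction_weight(v[:, 0], v[:, 1], beam.theta_div)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


def test_detect_conventional_mode_matching(beam):
    # perfect mode match: on-axis, anti-axial
    assert detect_conventional(make_records(), beam)[0] == pytest.approx(1.0)
    # lateral offset w0 at the reference plane, anti-axial direction
    rec = make_records(exit_x=beam.w0)
    assert detect_conventional(rec, beam)[0] == pytest.approx(math.exp(-1))
    # oblique exit whose extension hits the reference plane on axis
    td = beam.theta_div
    vz = -math.sqrt(1.0 - td ** 2)
    exit_x = -td * beam.zf / vz
    rec = make_records(weight=0.5, exit_x=exit_x, vx=td, vz=vz,
                       theta_i=math.acos(-vz))
    assert detect_conventional(rec, beam)[0] == pytest.approx(
        0.5 * math.exp(-1), rel=1e-12)


# --- hybrid particle-wave pieces -----------------------------------------

def test_transmission_T(beam):
    t0 = (beam.w0 / beam.zR) ** 2
    assert transmission_T(0, 0, 0, beam) == pytest.approx(t0)
    assert transmission_T(0, 0, beam.zR, beam) == pytest.approx(t0 / 2)
    zp = 0.4
    on_axis = transmission_T(0, 0, zp, beam)
    wz = beam.width(zp)
    assert transmission_T(wz, 0, zp, beam) == pytest.approx(
        on_axis * math.exp(-2), rel=1e-12)


def test_transmission_T_matches_overlap_integral_quadrature(beam):
    """Numerical quadrature of the mode-overlap integral — paraxial
    spherical wave from the last-scatter point against the Gaussian mode at
    the surface plane, with the spherical wave's half-space power 2*pi as
    its norm — must reproduce the closed-form coupling within 1%."""
    k = 2.0 * beam.zR / beam.w0 ** 2
    w_plane = beam.w0 * math.sqrt(1 + (beam.zf / beam.zR) ** 2)
    half = 4.0 * w_plane
    ngrid = 501
    rng = make_rng_stream(4, 0)
    for _ in range(20):
        zp = rng.uniform(-beam.zR, beam.zR)
        zs = beam.zf + zp
        r = rng.uniform(0, beam.width(zp))
        ang = rng.uniform(0, 2 * math.pi)
        x0, y0 = r * math.cos(ang), r * math.sin(ang)
        xs = np.linspace(x0 - half, x0 + half, ngrid)
        ys = np.linspace(y0 - half, y0 + half, ngrid)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        q = beam.zf + 1j * beam.zR
        mode = (1.0 / q) * np.exp(-1j * k * (X ** 2 + Y ** 2) / (2 * q))
        rho2 = (X - x0) ** 2 + (Y - y0) ** 2
        sph = (1.0 / zs) * np.exp(-1j * k * rho2 / (2 * zs))
        dx = xs[1] - xs[0]
        num = abs(np.trapezoid(np.trapezoid(np.conj(mode) * sph, dx=dx),
                               dx=dx)) ** 2
        p_mode = np.trapezoid(np.trapezoid(np.abs(mode) ** 2, dx=dx), dx=dx)
        t_quad = num / (p_mode * 2 * math.pi)
        t_closed = transmission_T(x0, y0, zp, beam)
        assert t_quad == pytest.approx(t_closed, rel=0.01)


def test_attenuation_adjustment():
    assert attenuation_adjustment(5.0, 2.0, 0.0) == pytest.approx(1.0)
    assert attenuation_adjustment(0.0, 2.0, 1.0) == pytest.approx(1.0)
    assert attenuation_adjustment(3.15, 1.0, math.radians(60)) == pytest.approx(
        math.exp(3.15), rel=1e-12)
    with pytest.raises(ValueError):
        attenuation_adjustment(1.0, 1.0, math.pi / 2)


def test_attenuation_adjustment_at_least_one():
    rng = make_rng_stream(5, 0)
    z = rng.uniform(0, 4, 10_000)
    theta = rng.uniform(0, math.radians(50), 10_000)
    assert np.all(attenuation_adjustment(3.15, z, theta) >= 1.0)


def test_detect_hybrid(beam):
    from octsim import OpticalMedium
    medium = OpticalMedium(mua=0.15, mus=0.25, g=0.3, n=1.33)
    t0 = (beam.w0 / beam.zR) ** 2
    rec = make_records(lsx=0.0, lsy=0.0, lsz=beam.zf, theta_i=0.0)
    assert detect_hybrid(rec, beam, medium)[0] == pytest.approx(t0, rel=1e-12)
    rec = make_records(lsz=beam.zf + beam.zR, theta_i=0.0)
    assert detect_hybrid(rec, beam, medium)[0] == pytest.approx(t0 / 2,
                                                               rel=1e-12)
    rec = make_records(weight=0.0, lsz=beam.zf)
    assert detect_hybrid(rec, beam, medium)[0] == 0.0


def test_corrected_opl():
    assert corrected_opl(5.0, 1.33, 1.2, 0.0) == pytest.approx(5.0)
    assert corrected_opl(10.0, 1.33, 1.0, math.radians(60)) == pytest.approx(
        10.0 + 1.33 * (1 - 2), rel=1e-12)
    rng = make_rng_stream(6, 0)
    li = rng.uniform(0, 16, 10_000)
    zi = rng.uniform(0, 4, 10_000)
    th = rng.uniform(0, math.radians(50), 10_000)
    assert np.all(corrected_opl(li, 1.33, zi, th) <= li + 1e-15)


def test_assign_bin():
    lc = 4e-3
    assert assign_bin(0.0, lc) == 0
    assert assign_bin(8e-3, lc) == 1      # one-way 4 um, bin centre 1
    assert assign_bin(12e-3, lc) == 2     # boundary assigned upward


# --- accumulation ---------------------------------------------------------

def test_accumulate_empty(weak_config):
    empty = PhotonRecords.from_array(np.empty((0, 12)))
    profile = accumulate_profile(empty, "hybrid", weak_config.beam,
                                 weak_config.medium, weak_config.detection)
    assert np.all(profile.intensity == 0)
    assert len(profile) == weak_config.detection.n_bins
    assert np.all(np.diff(profile.physical_depth) > 0)


def test_accumulate_single_hybrid_record(weak_config):
    beam, med, det = (weak_config.beam, weak_config.medium,
                      weak_config.detection)
    rec = make_records(lsz=beam.zf, opl_total=2 * med.n * beam.zf)
    profile = accumulate_profile(rec, "hybrid", beam, med, det)
    expected = detect_hybrid(rec, beam, med)[0]
    j = int(assign_bin(2 * med.n * beam.zf, det.lc))
    assert profile.intensity[j] == pytest.approx(expected, rel=1e-12)
    assert profile.intensity.sum() == pytest.approx(expected, rel=1e-12)
    assert profile.n_contributing[j] == 1


def test_accumulate_order_invariant(weak_run, weak_config):
    r = weak_run.records
    perm = make_rng_stream(2, 0).permutation(len(r))
    shuffled = PhotonRecords(**{
        name: getattr(r, name)[perm]
        for name in ("weight", "exit_x", "exit_y", "vx", "vy", "vz",
                     "theta_i", "opl_total", "lsx", "lsy", "lsz",
                     "n_scatters")})
    for model in ("conventional", "hybrid"):
        a = accumulate_profile(r, model, weak_config.beam,
                               weak_config.medium, weak_config.detection)
        b = accumulate_profile(shuffled, model, weak_config.beam,
                               weak_config.medium, weak_config.detection)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12,
                                   atol=1e-300)


def test_streaming_kernel_matches_record_path(weak_config, weak_run):
    """The fused transport+detection kernel must reproduce the
    record-then-accumulate route exactly (same seed, same photons)."""
    config = weak_config.replace(n_photons=300_000)
    fused = simulate_profiles(config)
    for model in ("conventional", "hybrid"):
        via_records = accumulate_profile(weak_run.records, model,
                                         config.beam, config.medium,
                                         config.detection)
        np.testing.assert_allclose(fused.profiles[model].intensity,
                                   via_records.intensity,
                                   rtol=1e-9, atol=1e-30)
        np.testing.assert_array_equal(fused.profiles[model].n_contributing,
                                      via_records.n_contributing)


def test_detected_intensity_bounds(weak_run, weak_config):
    beam, med = weak_config.beam, weak_config.medium
    r = weak_run.records
    conv = detect_conventional(r, beam)
    assert np.all(conv <= r.weight * (1 + 1e-12))
    hyb = detect_hybrid(r, beam, med)
    padj = attenuation_adjustment(med.mut, r.lsz, r.theta_i)
    assert np.all(hyb <= r.weight * padj * (1 + 1e-12))
    assert np.all(conv >= 0) and np.all(hyb >= 0)
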