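"""Unit and property tests for the directional cumulative-profile matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wfpi import simulate as sim
from wfpi.core import (displacement_between_profiles, line_cumulative_transform,
                       recover_gradients, scale_gradients, transport_image)
from wfpi.types import (AngleGrid, GradientField, IntensityImage, LineProfile,
                        ScaleParams)


# ----------------------------------------------------------------------
# line cumulative transform
# ----------------------------------------------------------------------

def test_constant_image_profiles_are_ramps():
    img = IntensityImage(np.ones((8, 8)))
    profiles = line_cumulative_transform(img, 0.0)
    assert len(profiles) == 8
    for p in profiles:
        np.testing.assert_allclose(p.samples, np.arange(1, 9), atol=1e-12)


def test_delta_image_gives_unit_step():
    vals = np.zeros((8, 8))
    vals[3, 5] = 1.0
    profiles = line_cumulative_transform(IntensityImage(vals), 0.0)
    for i, p in enumerate(profiles):
        if i == 3:
            np.testing.assert_allclose(p.samples, np.r_[np.zeros(5), np.ones(3)])
        else:
            assert np.all(p.samples == 0)


def test_diagonal_profile_matches_bruteforce_bilinear():
    """At 45 deg the main-diagonal profile equals direct summation of
    bilinear samples taken along the diagonal."""
    vals = np.arange(1.0, 17.0).reshape(4, 4)
    img = IntensityImage(vals)
    angle = np.pi / 4
    profiles = line_cumulative_transform(img, angle)
    # brute-force oracle: sample (t, t) for t = 0..3 by hand and cumulate
    def bilinear(r, c):
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        if not (0 <= r0 < 4 and 0 <= c0 < 4):
            return 0.0
        fr, fc = r - r0, c - c0
        out = 0.0
        for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            rr, cc = r0 + dr, c0 + dc
            if rr < 4 and cc < 4:
                out += w * vals[rr, cc]
        return out
    expected = np.cumsum([bilinear(t, t) for t in range(4)])
    diag = [p for p in profiles
            if np.allclose(p.positions[:, 0], p.positions[:, 1])]
    assert len(diag) == 1
    np.testing.assert_allclose(diag[0].samples, expected, rtol=1e-12)


def test_negative_image_rejected():
    with pytest.raises(ValueError):
        IntensityImage(-np.ones((4, 4)))


@settings(deadline=None, max_examples=25)
@given(hnp.arrays(np.float64, (12, 12),
                  elements=st.floats(0, 100, allow_nan=False)),
       st.integers(0, 23))
def test_profiles_always_nondecreasing(vals, angle_idx):
    """Cumulatives of non-negative flux are monotone for any image/angle."""
    vals = vals + 0.0
    if vals.max() == 0:
        vals[3, 3] = 1.0
    angle = AngleGrid(24).angles[angle_idx]
    for p in line_cumulative_transform(IntensityImage(vals), angle):
        assert np.all(np.diff(p.samples) >= -1e-9 * max(p.total, 1.0))


# ----------------------------------------------------------------------
# profile displacement
# ----------------------------------------------------------------------

def _profile(samples):
    samples = np.asarray(samples, dtype=float)
    pos = np.column_stack([np.zeros(samples.size), np.arange(samples.size)])
    return LineProfile((0, 0), samples, pos)


def test_identical_profiles_zero_displacement():
    f = _profile(np.cumsum([0, 1, 2, 3, 1, 0]))
    d, valid = displacement_between_profiles(f, f)
    assert valid.any()
    np.testing.assert_allclose(d[valid], 0.0, atol=1e-12)


def test_shifted_profile_recovers_shift():
    flux = np.zeros(32)
    flux[8:16] = np.hanning(8) + 0.1
    f = _profile(np.cumsum(flux))
    g = _profile(np.cumsum(np.roll(flux, 3)))
    d, valid = displacement_between_profiles(f, g)
    np.testing.assert_allclose(d[valid][1:-1], 3.0, atol=1e-9)


def test_hand_computed_inverse_cdf_case():
    """Mass [0,1,1,0] against [0,0,1,1]: every flux sample moved one pixel."""
    f = _profile(np.cumsum([0.0, 1.0, 1.0, 0.0]))
    g = _profile(np.cumsum([0.0, 0.0, 1.0, 1.0]))
    d, valid = displacement_between_profiles(f, g)
    assert list(np.nonzero(valid)[0]) == [1, 2]
    np.testing.assert_allclose(d[valid], 1.0, atol=1e-12)


def test_nonmonotone_profile_rejected():
    with pytest.raises(ValueError):
        _profile([0.0, 2.0, 1.0])


def test_zero_flux_profile_all_invalid():
    f = _profile(np.cumsum([0, 1, 1, 0]))
    g = _profile(np.zeros(4))
    d, valid = displacement_between_profiles(f, g)
    assert not valid.any()


# ----------------------------------------------------------------------
# gradient recovery
# ----------------------------------------------------------------------

def test_identical_images_give_null_gradients(small_config):
    illum = sim.make_illumination(small_config)
    g = recover_gradients(illum, illum, 24)
    assert g.mask.sum() > 1000
    np.testing.assert_allclose(g.grad_h[g.mask], 0.0, atol=1e-9)
    np.testing.assert_allclose(g.grad_v[g.mask], 0.0, atol=1e-9)


def _tilt_pair(config, shift_px):
    """Analytic uniform-shift pair: the illumination displaced by ±shift/2."""
    illum = sim.make_illumination(config)
    zeros = np.zeros_like(illum.values)
    half = shift_px / 2.0
    i1 = transport_image(illum.values, zeros, zeros - half)
    i2 = transport_image(illum.values, zeros, zeros + half)
    return IntensityImage(i1), IntensityImage(i2)


def test_tilt_recovers_uniform_shift(small_config):
    i1, i2 = _tilt_pair(small_config, 2.0)
    g = recover_gradients(i1, i2, 24)
    interior = _interior(g.mask, 6)
    assert abs(np.mean(g.grad_h[interior]) - 2.0) < 0.1  # 5 %
    assert abs(np.mean(g.grad_v[interior])) < 0.1


@pytest.mark.parametrize("shift", [0.2, 1.0, 4.0, 10.0])
def test_shift_linearity(small_config, shift):
    """Recovered uniform displacement is linear in the tilt over [0.2, 10] px."""
    i1, i2 = _tilt_pair(small_config, shift)
    g = recover_gradients(i1, i2, 24)
    interior = _interior(g.mask, 8)
    assert abs(np.mean(g.grad_h[interior]) / shift - 1.0) < 0.05


def _interior(mask, n):
    from scipy import ndimage
    return ndimage.binary_erosion(mask, iterations=n)


def test_defocus_gradients_linear_and_matched(small_config):
    """Pure defocus: grad_h linear in x, grad_v linear in y, equal slopes
    matching the injected curvature within 5 %."""
    from wfpi.integrate import differentiate
    truth = sim.phase_from_refraction(2.0, 0.0, 0.0, small_config)
    i1, i2 = sim.simulate_pair(truth, small_config)
    g = recover_gradients(i1, i2, 40)
    gt = differentiate(truth)
    fac = 2 * small_config.delta_z / small_config.pixel_pitch ** 2
    sel = _interior(g.mask & gt.mask, 5)
    rr, cc = np.indices(g.mask.shape, dtype=float)
    slope_h = np.polyfit(cc[sel], g.grad_h[sel], 1)[0]
    slope_v = np.polyfit(rr[sel], g.grad_v[sel], 1)[0]
    true_h = np.polyfit(cc[sel], fac * gt.grad_h[sel], 1)[0]
    assert abs(slope_h / true_h - 1) < 0.05
    assert abs(slope_v / slope_h - 1) < 0.05


def test_rotation_equivariance(small_config):
    """Rotating both inputs by 90 deg rotates the recovered gradient field.

    For np.rot90 (which maps old (r, c) to new (N-1-c, r)) a displacement
    (gh, gv) at a point transforms to (gv, -gh) at the rotated point.
    """
    truth = sim.phase_from_refraction(0.0, 2.0, 30.0, small_config)
    i1, i2 = sim.simulate_pair(truth, small_config)
    g = recover_gradients(i1, i2, 24)
    i1r = IntensityImage(np.rot90(i1.values).copy())
    i2r = IntensityImage(np.rot90(i2.values).copy())
    gr = recover_gradients(i1r, i2r, 24)
    sel = _interior(g.mask, 4)
    selr = np.rot90(sel)
    rms = np.sqrt(np.mean(g.grad_h[sel] ** 2 + g.grad_v[sel] ** 2))
    err_h = gr.grad_h[selr] - np.rot90(g.grad_v)[selr]
    err_v = gr.grad_v[selr] + np.rot90(g.grad_h)[selr]
    assert np.sqrt(np.mean(err_h ** 2 + err_v ** 2)) < 0.05 * rms


def test_k_saturation(small_config):
    """Gradient error stops improving beyond k = 120 (within 5 %)."""
    from wfpi.integrate import differentiate
    truth = sim.phase_from_refraction(3.0, 0.0, 0.0, small_config)
    i1, i2 = sim.simulate_pair(truth, small_config)
    gt = differentiate(truth)
    fac = 2 * small_config.delta_z / small_config.pixel_pitch ** 2
    errs = []
    for k in (120, 240):
        g = recover_gradients(i1, i2, k, n_iter=3)
        sel = _interior(g.mask & gt.mask, 4)
        err = np.hypot(g.grad_h[sel] - fac * gt.grad_h[sel],
                       g.grad_v[sel] - fac * gt.grad_v[sel])
        errs.append(np.sqrt(np.mean(err ** 2)))
    assert abs(errs[0] - errs[1]) < 0.05 * max(errs)


def test_shape_mismatch_and_small_k_rejected():
    a = IntensityImage(np.ones((8, 8)))
    b = IntensityImage(np.ones((8, 10)))
    with pytest.raises(ValueError):
        recover_gradients(a, b, 8)
    with pytest.raises(ValueError):
        recover_gradients(a, a, 1)


# ----------------------------------------------------------------------
# metric scaling
# ----------------------------------------------------------------------

def test_scale_gradients_reference_arithmetic():
    """1 px displacement at s = 9 um, 2dz = 13.33 mm -> 6.08e-9 m per step."""
    ones = np.ones((4, 4))
    g = GradientField(ones, 0 * ones, np.ones((4, 4), bool), units="pixels")
    p = ScaleParams(s=9e-6, delta_z=13.33e-3 / 2)
    out = scale_gradients(g, p)
    np.testing.assert_allclose(out.grad_h, (9e-6) ** 2 / 13.33e-3, rtol=1e-12)
    assert out.units == "metres"
    np.testing.assert_allclose(out.grad_h[0, 0], 6.08e-9, rtol=2e-3)


def test_scale_zero_field_and_delta_z_law():
    zeros = np.zeros((4, 4))
    g = GradientField(zeros, zeros, np.ones((4, 4), bool), units="pixels")
    p = ScaleParams(s=9e-6, delta_z=6.665e-3)
    assert np.all(scale_gradients(g, p).grad_h == 0)
    ones = np.ones((4, 4))
    g1 = GradientField(ones, ones, np.ones((4, 4), bool), units="pixels")
    a = scale_gradients(g1, ScaleParams(s=9e-6, delta_z=6.665e-3))
    b = scale_gradients(g1, ScaleParams(s=9e-6, delta_z=2 * 6.665e-3))
    np.testing.assert_allclose(b.grad_h, a.grad_h / 2)


def test_scale_params_validation():
    with pytest.raises(ValueError):
        ScaleParams(s=-1e-6, delta_z=1e-3)
    with pytest.raises(ValueError):
        ScaleParams(s=1e-6, delta_z=0.0)
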