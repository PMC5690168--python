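"""TG-43 formalism: geometry function, S_K windowing, g_L and F tables."""

import math

import numpy as np
import pytest

from plaquedose import tg43


def test_geometry_function_reference_value():
    # beta = 2 atan(0.15) = 0.29786 rad; G_L = beta / (L r) at theta0
    g = tg43.geometry_function_L(1.0, math.pi / 2, 0.3)
    assert g == pytest.approx(2 * math.atan(0.15) / 0.3, rel=1e-12)
    assert g == pytest.approx(0.9926, abs=1e-4)


def test_geometry_function_point_source_limit():
    for r in (0.5, 1.0, 4.0):
        g = tg43.geometry_function_L(r, 1.1, 1e-5)
        assert g == pytest.approx(1.0 / r ** 2, rel=1e-6)


def test_geometry_function_on_axis():
    g = tg43.geometry_function_L(1.0, 0.0, 0.3)
    assert g == pytest.approx(1.0 / (1.0 - 0.0225), rel=1e-12)
    with pytest.raises(ValueError):
        tg43.geometry_function_L(0.1, 0.0, 0.3)
    with pytest.raises(ValueError):
        tg43.geometry_function_L(0.0, 1.0)


def test_geometry_function_matches_line_kernel_integration():
    """Independent oracle: G_L equals the numerically integrated line-source
    kernel (1/L) * int dl / d(l)^2 over the active length."""
    L = 0.3
    for r, th in ((1.0, math.pi / 2), (2.0, math.pi / 2), (1.0, 0.7),
                  (0.6, 1.2)):
        ls = np.linspace(-L / 2, L / 2, 20001)
        z = r * math.cos(th)
        rho = r * math.sin(th)
        d2 = rho ** 2 + (z - ls) ** 2
        oracle = np.trapezoid(1.0 / d2, ls) / L
        assert tg43.geometry_function_L(r, th, L) == pytest.approx(
            oracle, rel=1e-6)


def test_air_kerma_strength_windowing():
    d = np.array([0.05, 0.5, 1.0, 2.0, 5.0, 10.0])
    kd2 = np.array([0.4, 0.9, 1.0, 1.0, 1.0, 1.0])  # near-source droop
    curve = np.column_stack([d, kd2, np.zeros_like(d)])
    assert tg43.air_kerma_strength(curve) == 1.0
    # points inside 1 cm are excluded: corrupting them changes nothing
    curve2 = curve.copy()
    curve2[0, 1] = 99.0
    assert tg43.air_kerma_strength(curve2) == 1.0
    # nonconstant plateau rejected
    bad = curve.copy()
    bad[3, 1] = 1.2
    with pytest.raises(ValueError, match="nonconstant"):
        tg43.air_kerma_strength(bad)
    with pytest.raises(ValueError, match="cover"):
        tg43.air_kerma_strength(curve[:2])


def test_dose_rate_constant_scale_invariance():
    lam = tg43.dose_rate_constant(2.0e-14, 4.0e-14)
    assert tg43.dose_rate_constant(4.0e-14, 8.0e-14) == lam
    with pytest.raises(ValueError):
        tg43.dose_rate_constant(1.0, 0.0)


def test_radial_dose_function_normalization_and_identity():
    radii = np.array([0.5, 1.0, 2.0, 5.0])
    # synthetic profile falling exactly like the geometry function -> g == 1
    doses = tg43.geometry_function_L(radii, math.pi / 2, 0.3)
    g = tg43.radial_dose_function(radii, doses)
    assert np.allclose(g[:, 1], 1.0, rtol=1e-12)
    # g_L with the correct L differs from the point-source form by exactly
    # the geometry-function ratio (algebraic identity)
    doses2 = 1.0 / radii ** 2
    g_line = tg43.radial_dose_function(radii, doses2, L=0.3)
    gl = tg43.geometry_function_L(radii, math.pi / 2, 0.3)
    expect = (1.0 / radii ** 2) / (gl / gl[1])
    assert np.allclose(g_line[:, 1], expect / expect[1], rtol=1e-12)
    with pytest.raises(ValueError, match="r0"):
        tg43.radial_dose_function([0.5, 2.0], [1.0, 0.2])


def test_seed_anisotropy_decreases_toward_long_axis():
    """A short Monte Carlo run of the encapsulated seed: oblique filtration
    through the capsule and rod must depress F(r, theta) at small polar
    angles relative to the transverse plane."""
    pars = tg43.single_seed_study(histories=1_500_000, air_histories=300_000,
                                  seed=7, anisotropy=True)
    f1 = dict(zip(np.degrees(pars.f_rtheta[1.0][:, 0]).round().astype(int),
                  pars.f_rtheta[1.0][:, 1]))
    assert f1[90] == 1.0                       # exact normalization
    assert 0.2 < f1[10] < 0.95                 # suppressed near the axis
    assert f1[10] < f1[40]


def test_anisotropy_function_normalization():
    thetas = np.array([0.3, 0.8, math.pi / 2])
    doses = tg43.geometry_function_L(1.0, thetas, 0.3)
    f = tg43.anisotropy_function(1.0, thetas, doses)
    assert np.allclose(f[:, 1], 1.0, rtol=1e-12)  # isotropic source -> F = 1
    with pytest.raises(ValueError):
        tg43.anisotropy_function(1.0, [0.2, 0.4], [1.0, 1.0])
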