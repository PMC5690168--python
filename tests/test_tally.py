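"""Tally geometry, chord scoring and batch statistics."""

import numpy as np
import pytest

from plaquedose import _kernel, tally, xsdata
from plaquedose.fixtures import _bare_scene, _mono
from plaquedose.geometry import Region
from plaquedose.transport import (KEV_PER_G_TO_GY, RunConfig, TallyResult,
                                  run)


@pytest.mark.parametrize("r,expect", [(0.07, 0.008), (0.1, 0.008),
                                      (0.5, 0.01), (1.0, 0.01), (3.0, 0.05),
                                      (5.0, 0.05), (8.0, 0.1)])
def test_toroid_minor_radius_schedule(r, expect):
    assert tally.toroid_minor_radius(r) == expect


@pytest.mark.parametrize("kind,params", [
    ("box", (0.2, -0.3, 0.5, 0.4, 0.25, 0.6)),
    ("sphere", (0.1, 0.0, -0.2, 0.7)),
    ("shell", (0.0, 0.1, 0.0, 0.4, 0.8)),
    ("washer", (0.0, 0.0, 0.2, 0.0, 0.0, 1.0, 0.0, 1.0, 0.05)),
])
def test_region_volume_matches_chord_integral(kind, params):
    """Cauchy: mean chord x crossing rate reproduces the volume, so the
    segment-chord code and the analytic volume must agree."""
    reg = Region("r", kind, params)
    p = np.array(list(reg.params) + [0.0] * (9 - len(reg.params)))
    rng = np.random.default_rng(5)
    half = 2.0
    n = 60_000
    # parallel +x rays with uniform (y,z): sum of chords * face area / n = V
    total = 0.0
    kcode = {"box": 0, "washer": 1, "sphere": 2, "shell": 3}[kind]
    for _ in range(n):
        y, z = rng.uniform(-half, half, size=2)
        total += _kernel._region_chord(kcode, p, -half, float(y), float(z),
                                       1.0, 0.0, 0.0, 100.0)
    mc_volume = total / n * (2 * half) ** 2
    assert mc_volume == pytest.approx(reg.volume, rel=0.05)


def test_chord_additivity_split_segment():
    p = np.zeros(9)
    p[:9] = (0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.05)  # washer
    full = _kernel._region_chord(1, p, 0.5, -2.0, 0.0, 0.0, 1.0, 0.0, 4.0)
    first = _kernel._region_chord(1, p, 0.5, -2.0, 0.0, 0.0, 1.0, 0.0, 1.9)
    second = _kernel._region_chord(1, p, 0.5, -0.1, 0.0, 0.0, 1.0, 0.0, 2.1)
    assert first + second == pytest.approx(full, abs=1e-12)
    outside = _kernel._region_chord(1, p, 5.0, 5.0, 5.0, 0.0, 0.0, 1.0, 1.0)
    assert outside == 0.0


def test_beam_through_voxel_matches_closed_form():
    """Pencil beam through a cube in vacuum: kerma = Phi E mu_en/rho with
    Phi = chord/V per history."""
    sc = _bare_scene("vacuum", source=((0.0, 0.0, -2.0), (0.0, 0.0, 1.0)))
    sc.add_region(Region("vox", "box", (0, 0, 0, 0.5, 0.5, 0.5),
                         medium="water"))
    n = 20_000
    res = run(sc, RunConfig(histories=n, batches=4, seed=41),
              spectrum=_mono(30.0), source_mode="pencil")
    w = xsdata.get_material("water")
    expect = (30.0 * xsdata.mu_en_mass(w, 30.0) * 1.0 / 1.0
              * KEV_PER_G_TO_GY)  # chord 1 cm / volume 1 cm^3
    assert res["vox"].mean == pytest.approx(expect, rel=1e-9)


def test_air_kerma_curve_flags_empty_toroid():
    from plaquedose.transport import RunResult
    fake = RunResult(tallies={"air_1": TallyResult("air_1", 0.0, 0.0, 1.0,
                                                   hits=0)},
                     energy_balance=np.zeros((1, 3)), lost_particles=0)
    with pytest.raises(ValueError, match="no tracks"):
        tally.air_kerma_curve(fake, radii=(1.0,))


def test_variance_scales_with_histories():
    """Doubling histories roughly halves the variance of the mean."""
    case_scene = _bare_scene("water")
    case_scene.add_region(Region("probe", "shell", (0, 0, 0, 0.95, 1.05)))
    spec = _mono(30.0)
    r1 = run(case_scene, RunConfig(histories=40_000, batches=20, seed=42),
             spectrum=spec, source_mode="point")
    r2 = run(case_scene, RunConfig(histories=160_000, batches=20, seed=43),
             spectrum=spec, source_mode="point")
    # 4x histories -> ~2x smaller relative error (allow wide stochastic band)
    ratio = r1["probe"].rel_err / r2["probe"].rel_err
    assert 1.2 < ratio < 3.5
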