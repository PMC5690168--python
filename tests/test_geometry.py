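"""CSG scenes: cell location, ray tracing, phantom anatomy."""

import numpy as np
import pytest

from plaquedose.eye_analysis import scenario_scene
from plaquedose.geometry import (EYE_RADII, SKULL_RADII, _check_seed_overlaps,
                                 add_tumor, build_eye_phantom,
                                 seed_slots_coms16, single_seed_scene)
from plaquedose.transport import CompiledScene


@pytest.fixture(scope="module")
def eye_cs():
    return CompiledScene(scenario_scene("eye", plaque=True, tumor=True))


@pytest.fixture(scope="module")
def bare_cs():
    return CompiledScene(build_eye_phantom("eye"))


@pytest.mark.parametrize("point,cell", [
    ((0, 0, 0), "vitreous"),
    ((0, 1.18, 0), "sclera"),            # radius 1.18, away from the plaque
    ((0, 0.98, 0), "retina"),
    ((0, 1.08, 0), "choroid"),
    ((0, 0, 0.66), "lens"),
    ((0.375, 0, -1.30), "optic_nerve"),
    ((0, 1.7, 0), "skull"),
    ((0, 1.4, 0), "world"),              # gap between sclera and skull
    ((5, 5, 5), "world"),
    ((20, 0, 0), "<escaped>"),
])
def test_locate_anatomy(bare_cs, point, cell):
    assert bare_cs.locate(point) == cell


def test_locate_treatment_cells(eye_cs):
    assert eye_cs.locate((0.63, 0, 0)) == "tumor"       # apex point
    assert eye_cs.locate((1.0, 0, 0)) == "tumor"
    assert eye_cs.locate((1.49, 0, 0)) == "plaque_backing"
    assert eye_cs.locate((1.30, 0, 0.2)) == "seed_carrier"
    assert eye_cs.locate((-1.18, 0, 0)) == "sclera"     # opposite side


def test_trace_first_boundary(bare_cs):
    cell, dist = bare_cs.trace((0, 0, 0), (0, 1, 0))
    assert cell == "vitreous"
    assert dist == pytest.approx(EYE_RADII[0], abs=1e-9)
    cell, dist = bare_cs.trace((0, 1.6, 0), (0, 1, 0))
    assert dist == pytest.approx(SKULL_RADII[1] - 1.6, abs=1e-9)


def test_trace_apex_distance(eye_cs):
    # from the globe center toward the plaque, first surface is the tumor apex
    _, dist = eye_cs.trace((0, 0, 0), (1, 0, 0))
    assert dist == pytest.approx(0.63, abs=1e-9)


def test_partition_every_point_in_exactly_one_cell(eye_cs):
    rng = np.random.default_rng(7)
    pts = rng.uniform(-2.4, 2.4, size=(100_000, 3))
    assert all(eye_cs.locate(p) != "<escaped>" for p in pts)


def test_trace_consistent_with_locate(eye_cs):
    """Stepping just past the reported boundary must land in a cell, and the
    cell is constant strictly inside the segment (no skipped surfaces)."""
    rng = np.random.default_rng(11)
    for _ in range(300):
        p = rng.uniform(-1.6, 1.6, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        start, dist = eye_cs.trace(p, d)
        if start == "<escaped>":
            continue
        for f in (0.25, 0.5, 0.9):
            assert eye_cs.locate(p + f * dist * d) == start
        assert eye_cs.locate(p + (dist + 1e-6) * d) != ""


def test_shell_volumes_match_analytic(bare_cs):
    """MC point-sampling volume of each eye shell within 1%."""
    rng = np.random.default_rng(3)
    n = 400_000
    pts = rng.uniform(-1.3, 1.3, size=(n, 3))
    box = 2.6 ** 3
    cells = [bare_cs.locate(p) for p in pts]
    counts = {c: cells.count(c) for c in ("retina", "choroid", "sclera")}
    for (cell, r1, r2) in (("retina", 0.93, 1.03), ("choroid", 1.03, 1.13),
                           ("sclera", 1.13, 1.23)):
        analytic = 4.0 / 3.0 * np.pi * (r2 ** 3 - r1 ** 3)
        mc = counts[cell] / n * box
        # binomial error ~1.5% at this n; 1% bias would show as >2 sigma
        assert mc == pytest.approx(analytic, rel=0.05)


def test_water_mode_same_geometry_different_materials():
    eye = scenario_scene("eye", plaque=True, tumor=True)
    wat = scenario_scene("water", plaque=True, tumor=True)
    assert np.allclose(np.asarray(eye.surf_par), np.asarray(wat.surf_par))
    assert eye.cell_names == wat.cell_names
    ce = CompiledScene(eye)
    cw = CompiledScene(wat)
    for p in [(0, 0, 0), (0, 1.18, 0), (0.63, 0, 0), (0, 0, 0.66)]:
        assert ce.locate(p) == cw.locate(p)
    assert cw.material_names.count("water") == 1
    ocular = {"vitreous", "sclera", "lens", "optic_nerve", "skull_bone",
              "tumor"}
    assert not ocular & set(cw.material_names)


def test_tumor_preconditions():
    sc = build_eye_phantom("eye")
    n_obj = len(sc.objects)
    assert add_tumor(sc, apex_height=0.0) is sc
    assert len(sc.objects) == n_obj
    with pytest.raises(ValueError):
        add_tumor(build_eye_phantom("eye"), apex_height=2.0)
    with pytest.raises(ValueError):
        add_tumor(build_eye_phantom("eye"), apex_height=0.1)


def test_tumor_apex_and_base():
    sc = build_eye_phantom("eye")
    add_tumor(sc, apex_height=0.5)
    cs = CompiledScene(sc)
    assert cs.locate((0.631, 0, 0)) == "tumor"       # just behind the apex
    assert cs.locate((0.629, 0, 0)) == "vitreous"    # just inside the apex
    assert cs.locate((1.10, 0, 0)) == "tumor"        # near the base
    assert cs.locate((1.10, 0.55, 0.0)) != "tumor"   # outside basal chord


def test_seed_layout_valid():
    slots = seed_slots_coms16()
    assert len(slots) == 13
    _check_seed_overlaps(slots)  # must not raise
    for pos, ax in slots:
        assert np.isclose(np.linalg.norm(ax), 1.0)
        assert 1.23 + 0.04 < np.linalg.norm(pos) < 1.47 - 0.04
        # tangent orientation: long axis perpendicular to the radial vector
        assert abs(np.dot(pos, ax)) < 1e-9


def test_overlapping_seeds_rejected():
    slots = seed_slots_coms16()
    with pytest.raises(ValueError):
        _check_seed_overlaps([slots[0], slots[0]])


def test_seed_cells_present():
    cs = CompiledScene(single_seed_scene("water"))
    assert cs.locate((0, 0, 0)) == "seed0_rod"
    assert cs.locate((0.03, 0, 0)) == "seed0_interior"
    assert cs.locate((0.038, 0, 0)) == "seed0_capsule"
    assert cs.locate((0.05, 0, 0)) == "world"
    assert cs.locate((0, 0, 0.222)) == "seed0_capsule"  # end weld
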