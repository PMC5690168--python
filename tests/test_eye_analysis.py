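"""Prescription scaling, depth-dose bookkeeping and DEF machinery (cheap
checks; the physics-level comparisons live in test_acceptance)."""

import numpy as np
import pytest

from plaquedose.eye_analysis import (APEX_X, PrescriptionPolicy,
                                     def_from_response, def_scan,
                                     depth_dose_curve, depth_positions,
                                     poi_coordinates, prescribe,
                                     run_scenario, scenario_compare,
                                     scenario_scene)
from plaquedose.transport import CompiledScene, RunConfig


@pytest.fixture(scope="module")
def small_run():
    return run_scenario("water", plaque=True,
                        config=RunConfig(histories=400_000, batches=10,
                                         seed=13))


def test_effective_irradiation_time():
    pol = PrescriptionPolicy()
    lam = np.log(2) / (59.4 * 24)
    assert pol.decay_constant_per_h == pytest.approx(lam, rel=1e-12)
    # closed form evaluated independently
    assert pol.effective_time_h == pytest.approx(
        (1 - np.exp(-lam * 100.0)) / lam, rel=1e-12)
    assert pol.effective_time_h == pytest.approx(97.6, abs=0.1)


def test_depth_grid():
    d = depth_positions()
    assert len(d) == 48
    assert np.isclose(d, 0.5).any()            # a cell centered at the apex
    assert d[0] == pytest.approx(-0.05)        # first cell inside the sclera
    assert np.allclose(np.diff(d), 0.05)


def test_poi_cells_sit_in_their_anatomy():
    cs = CompiledScene(scenario_scene("eye", plaque=True, tumor=True))
    where = {"sclera": "sclera", "apex": "tumor", "center_of_eye": "vitreous",
             "opposite_side": "sclera", "optic_disk": "optic_nerve",
             "lens": "lens", "macula": "retina"}
    for name, (c, h) in poi_coordinates().items():
        assert cs.locate(c) == where[name], name
        # corners stay inside the same cell (no medium mixing)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    corner = (c[0] + sx * h[0] * 0.999,
                              c[1] + sy * h[1] * 0.999,
                              c[2] + sz * h[2] * 0.999)
                    assert cs.locate(corner) == where[name], (name, corner)


def test_prescription_sets_apex_dose(small_run):
    rep = prescribe(small_run)
    assert rep.doses_gy["apex"] == pytest.approx(85.0, rel=1e-12)
    assert all(v >= 0 for v in rep.doses_gy.values())
    # shared emission rate scales every point linearly
    rep2 = prescribe(small_run, emission_rate_per_h=rep.emission_rate_per_h
                     / 2.0)
    for k in rep.doses_gy:
        assert rep2.doses_gy[k] == pytest.approx(rep.doses_gy[k] / 2.0,
                                                 rel=1e-12)


def test_depth_dose_normalized_at_apex_depth(small_run):
    curve = depth_dose_curve(small_run, max_apex_err=0.2)
    i = int(np.argmin(np.abs(curve[:, 0] - 0.5)))
    assert curve[i, 1] == 1.0
    with pytest.raises(ValueError, match="relative error"):
        depth_dose_curve(small_run, max_apex_err=1e-6)


def test_def_zero_concentration_is_exactly_one(small_run):
    cfg = RunConfig(histories=400_000, batches=10, seed=13)
    profiles = def_scan((0.0,), phantom="water", config=cfg,
                        baseline=small_run)
    assert profiles[0].def_apex == 1.0
    assert np.all(profiles[0].def_depth == 1.0)


def test_def_response_estimator_monotone(small_run):
    defs = def_from_response(small_run)
    vals = [defs[c] for c in (7.0, 10.0, 18.0, 30.0)]
    assert vals[0] > 1.0
    assert np.all(np.diff(vals) > 0)


def test_scenario_compare_percentages():
    class R:
        def __init__(self, doses):
            self.doses_gy = doses
    reports = {"a": R({"sclera": 90.0, "lens": 20.0}),
               "b": R({"sclera": 100.0, "lens": 10.0})}
    out = scenario_compare(reports)
    assert out[("a", "b")]["sclera"] == pytest.approx(-10.0)
    assert out[("a", "b")]["lens"] == pytest.approx(100.0)
    assert out[("b", "a")]["sclera"] == pytest.approx(100.0 / 9.0)


def test_prescribe_requires_apex_signal():
    from plaquedose.transport import RunResult, TallyResult
    fake = RunResult(tallies={"poi_apex": TallyResult("poi_apex", 0.0, 0.0,
                                                      1.0, hits=0)},
                     energy_balance=np.zeros((1, 3)), lost_particles=0)
    with pytest.raises(ValueError, match="apex"):
        prescribe(fake)
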