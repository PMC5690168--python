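"""Shared fixtures.

The heavy Monte Carlo products (single-seed TG-43 benchmark, plaque-on-eye
scenario runs, GNP concentration scan) are session-scoped so the whole suite
pays for each simulation once. History counts are sized for ~0.5-3% relative
errors on the quantities the tests assert; RNG seeds are fixed so the suite
is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from plaquedose.eye_analysis import (PrescriptionPolicy, def_scan, prescribe,
                                     run_scenario)
from plaquedose.transport import RunConfig

SEED = 2024


@pytest.fixture(scope="session")
def tg43_params():
    from plaquedose import tg43
    return tg43.single_seed_study(histories=12_000_000,
                                  air_histories=8_000_000,
                                  seed=SEED, batches=25)


@pytest.fixture(scope="session")
def scenario_runs():
    """S.W / P.W / plaque-in-eye runs plus GNP-loaded variants."""
    heavy = RunConfig(histories=10_000_000, batches=20, seed=SEED)
    mid = RunConfig(histories=6_000_000, batches=20, seed=SEED)
    light = RunConfig(histories=3_000_000, batches=20, seed=SEED)
    runs = {
        "sw": run_scenario("water", plaque=False, config=mid),
        "pw": run_scenario("water", plaque=True, config=heavy),
        "eye": run_scenario("eye", plaque=True, config=heavy),
    }
    for c in (7.0, 10.0, 18.0, 30.0):
        runs[f"w{c:g}"] = run_scenario("water", plaque=True, gnp=c,
                                       config=light)
    runs["e30"] = run_scenario("eye", plaque=True, gnp=30.0, config=light)
    return runs


@pytest.fixture(scope="session")
def dose_reports(scenario_runs):
    pol = PrescriptionPolicy()
    rep_sw = prescribe(scenario_runs["sw"], pol)
    rate = rep_sw.emission_rate_per_h
    return {
        "sw": rep_sw,
        "pw": prescribe(scenario_runs["pw"], pol, emission_rate_per_h=rate),
        "eye": prescribe(scenario_runs["eye"], pol, emission_rate_per_h=rate),
    }


def def_apex(scenario_runs, conc, phantom):
    base = scenario_runs["pw" if phantom == "water" else "eye"]
    key = f"w{conc:g}" if phantom == "water" else f"e{conc:g}"
    num = scenario_runs[key]["apex_sphere"]
    den = base["apex_sphere"]
    return (num.mean / den.mean,
            float(np.hypot(num.rel_err, den.rel_err)))
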