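"""Synthetic oracle scenes with closed-form expected values.

Every transport ingredient is testable against analytic results without any
external data: exponential attenuation of a pencil beam, the inverse-square
law for an isotropic point source in vacuum, and layered exponential
attenuation of the uncollided component in a two-media sphere. Full-scatter
quantities have no closed form; their correctness is covered by the TG-43
benchmark instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import xsdata
from .geometry import Cell, Region, Scene
from .source import EmissionSpectrum
from .tally import add_transverse_toroids
from .transport import KEV_PER_G_TO_GY, RunConfig, RunResult, run


@dataclass
class OracleCase:
    """A scene plus the closed-form quantity a run must reproduce."""

    name: str
    scene: Scene
    spectrum: EmissionSpectrum
    source_mode: str
    expected: dict                 # quantity name -> analytic value
    rel_tol_sigma: float = 3.0     # acceptance band in standard errors
    notes: str = ""
    rng_seed: int = 1

    def run(self, histories: int = 200_000, batches: int = 10,
            seed: int | None = None) -> RunResult:
        cfg = RunConfig(histories=histories, batches=batches,
                        seed=self.rng_seed if seed is None else seed)
        return run(self.scene, cfg, spectrum=self.spectrum,
                   source_mode=self.source_mode)


def _bare_scene(world_material: str, half: float = 20.0,
                source=((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))) -> Scene:
    sc = Scene(mode="water")
    planes = []
    for ax in range(3):
        n = [0.0, 0.0, 0.0]
        n[ax] = 1.0
        planes.append((sc.plane(tuple(n), half), -1))
        planes.append((sc.plane(tuple(n), -half), 1))
    sc.add_object("world", 100, [Cell("world", world_material, planes)],
                  bound=None)
    sc.seed_transforms.append(source)
    return sc


def _mono(e_keV: float) -> EmissionSpectrum:
    return EmissionSpectrum(f"mono{e_keV:g}", np.array([float(e_keV)]),
                            np.array([1.0]))


def make_attenuation_slab(material: str = "water", thickness: float = 1.0,
                          e_keV: float = 30.0) -> OracleCase:
    """Pencil beam through a slab in vacuum: the fraction of histories that
    escape without any interaction equals exp(-mu * t)."""
    sc = _bare_scene("vacuum", source=((0.0, 0.0, -1.0), (0.0, 0.0, 1.0)))
    p0 = sc.plane((0, 0, 1), 0.0)
    p1 = sc.plane((0, 0, 1), thickness)
    cells = [Cell("slab", material, [(p0, 1), (p1, -1)])]
    sc.add_object("slab", 10, cells, bound=None)
    mu = xsdata.mu_total(xsdata.get_material(material), e_keV)
    return OracleCase(
        name=f"attenuation_{material}_{thickness:g}cm_{e_keV:g}keV",
        scene=sc, spectrum=_mono(e_keV), source_mode="pencil",
        expected={"uncollided_fraction": math.exp(-mu * thickness)},
        notes="binomial statistics on the uncollided-escape counter")


def make_point_source_vacuum(e_keV: float = 30.0,
                             distances=(1.0, 2.0, 5.0, 10.0)) -> OracleCase:
    """Isotropic point source in vacuum: air kerma x d^2 is the constant
    E * (mu_en/rho)_air / (4 pi) per history."""
    sc = _bare_scene("vacuum", half=25.0)
    add_transverse_toroids(sc, distances, medium="dry_air", prefix="air")
    k = (e_keV * xsdata.mu_en_mass(xsdata.get_material("dry_air"), e_keV)
         / (4.0 * math.pi) * KEV_PER_G_TO_GY)
    return OracleCase(
        name=f"point_vacuum_{e_keV:g}keV",
        scene=sc, spectrum=_mono(e_keV), source_mode="point",
        expected={f"kerma_d2_{d:g}": k for d in distances},
        notes="Gy cm^2 per history in each dry-air toroid")


def make_two_media_sphere(inner: str = "sclera", outer: str = "water",
                          r_inner: float = 1.0, r_probe: float = 2.0,
                          e_keV: float = 30.0) -> OracleCase:
    """Point source at the center of a two-layer sphere: the uncollided kerma
    at ``r_probe`` follows layered exponential attenuation; the full-transport
    result must exceed it (scatter buildup)."""
    sc = _bare_scene("vacuum", half=25.0)
    s_in = sc.sphere((0, 0, 0), r_inner)
    s_out = sc.sphere((0, 0, 0), r_probe + 0.5)
    sc.add_object("layers", 10, [
        Cell("inner", inner, [(s_in, -1)]),
        Cell("outer", outer, [(s_in, 1), (s_out, -1)]),
    ], bound=(0, 0, 0, r_probe + 0.5))
    sc.add_region(Region("probe", "shell",
                         (0, 0, 0, r_probe - 0.01, r_probe + 0.01)))
    mi = xsdata.mu_total(xsdata.get_material(inner), e_keV)
    mo = xsdata.mu_total(xsdata.get_material(outer), e_keV)
    muen = xsdata.mu_en_mass(xsdata.get_material(outer), e_keV)
    att = math.exp(-mi * r_inner - mo * (r_probe - r_inner))
    # exact average of E muen exp(.)/(4 pi r^2) over the thin probe shell
    rr = np.linspace(r_probe - 0.01, r_probe + 0.01, 801)
    vals = (e_keV * muen * np.exp(-mi * r_inner - mo * (rr - r_inner))
            / (4.0 * math.pi * rr * rr) * KEV_PER_G_TO_GY)
    w = rr * rr
    return OracleCase(
        name=f"two_media_{inner}_{outer}_{e_keV:g}keV",
        scene=sc, spectrum=_mono(e_keV), source_mode="point",
        expected={"primary_kerma": float((vals * w).sum() / w.sum()),
                  "uncollided_attenuation": att},
        notes="probe shell scores in Gy/history; primary component only")


def oracle_suite() -> list:
    """The standard oracle set used by the test suite and the CLI."""
    return [
        make_attenuation_slab("water", 1.0, 30.0),
        make_attenuation_slab("water", 0.0, 30.0),
        make_attenuation_slab("gold", 0.05, 30.0),
        make_point_source_vacuum(30.0),
        make_two_media_sphere("sclera", "water"),
        make_two_media_sphere("water", "water"),
    ]
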