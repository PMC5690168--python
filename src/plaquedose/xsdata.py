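"""Element and material photon-interaction data.

Per-element tables (photoabsorption, incoherent and coherent scattering,
mass energy-absorption coefficient, coherent form factor ``F(x,Z)`` and
incoherent scattering function ``S(x,Z)``) are vendored as CSV files under
``plaquedose/data/elements`` and regenerated by
``scripts/generate_xs_tables.py``. Materials are elemental mixtures with a
density; interaction coefficients follow the usual mass-fraction mixture rule

    mu/rho (E) = sum_i w_i (sigma_pe + sigma_incoh + sigma_coh)_i(E)

with log-log interpolation on each element's energy grid. Gold-nanoparticle
loading treats the nanoparticles as a homogeneous gold/tissue mixture:
``c`` mg of gold added per gram of tissue gives a gold mass fraction
``c/(1000+c)`` and a density from the inverse mass-fraction rule with bulk
gold at 19.32 g/cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

GOLD_DENSITY = 19.32  # g/cm^3, bulk

_DATA = resources.files("plaquedose") / "data"


class UnknownElementError(KeyError):
    pass


class EnergyRangeError(ValueError):
    pass


@dataclass(frozen=True)
class ElementTable:
    """Photon interaction data for one element.

    Energies in keV; partial cross sections and ``mu_en_rho`` are mass
    coefficients in cm^2/g; ``x`` is the momentum-transfer variable
    sin(theta/2)/lambda in 1/Angstrom.
    """

    symbol: str
    Z: int
    A: float
    e_keV: np.ndarray
    sigma_pe: np.ndarray
    sigma_incoh: np.ndarray
    sigma_coh: np.ndarray
    mu_en_rho: np.ndarray
    x: np.ndarray
    F: np.ndarray
    S: np.ndarray
    edges: tuple = ()

    def _interp(self, col: np.ndarray, e: np.ndarray | float) -> np.ndarray | float:
        e_arr = np.asarray(e, dtype=float)
        lo, hi = self.e_keV[0], self.e_keV[-1]
        if np.any(e_arr < lo * (1 - 1e-9)) or np.any(e_arr > hi * (1 + 1e-9)):
            raise EnergyRangeError(
                f"{self.symbol}: energy outside table range "
                f"[{self.e_keV[0]:g}, {self.e_keV[-1]:g}] keV")
        out = np.exp(np.interp(np.log(e_arr), np.log(self.e_keV),
                               np.log(np.maximum(col, 1e-300))))
        return float(out) if np.isscalar(e) else out


@lru_cache(maxsize=None)
def _constants() -> dict:
    with (_DATA / "elements" / "constants.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def element_table(symbol: str) -> ElementTable:
    consts = _constants()["elements"]
    if symbol not in consts:
        raise UnknownElementError(f"no vendored data for element {symbol!r}")
    c = consts[symbol]
    xs = np.genfromtxt((_DATA / "elements" / f"{symbol}.xs.csv").open("rb"),
                       delimiter=",", names=True, skip_header=1)
    ff = np.genfromtxt((_DATA / "elements" / f"{symbol}.ff.csv").open("rb"),
                       delimiter=",", names=True, skip_header=1)
    return ElementTable(
        symbol=symbol, Z=c["Z"], A=c["A"],
        e_keV=np.ascontiguousarray(xs["E_keV"]),
        sigma_pe=np.ascontiguousarray(xs["sigma_pe"]),
        sigma_incoh=np.ascontiguousarray(xs["sigma_incoh"]),
        sigma_coh=np.ascontiguousarray(xs["sigma_coh"]),
        mu_en_rho=np.ascontiguousarray(xs["mu_en_rho"]),
        x=np.ascontiguousarray(ff["x_invA"]),
        F=np.ascontiguousarray(ff["F"]),
        S=np.ascontiguousarray(ff["S"]),
        edges=tuple(c.get("edges", [])),
    )


@dataclass(frozen=True)
class Material:
    """Named elemental mixture: mass fractions (summing to 1) and density."""

    name: str
    density: float  # g/cm^3
    fractions: dict = field(default_factory=dict)  # element symbol -> w_i

    def __post_init__(self):
        total = sum(self.fractions.values())
        assert abs(total - 1.0) < 1e-9, f"{self.name}: fractions sum {total}"

    @property
    def elements(self) -> list[str]:
        return list(self.fractions)


def build_material(name: str, fractions: dict, density: float) -> Material:
    """Build a material from mass fractions (any scale; renormalized).

    Fractions may be given in percent or as unit fractions; their sum must be
    within 0.5% of either 1 or 100 (printed composition tables carry rounding
    at that level) and is renormalized exactly. Unknown element symbols or a
    non-positive total are errors.
    """
    if density <= 0:
        raise ValueError(f"{name}: density must be positive")
    total = float(sum(fractions.values()))
    if total <= 0:
        raise ValueError(f"{name}: zero total mass fraction")
    scale = 100.0 if abs(total - 100.0) < abs(total - 1.0) else 1.0
    if abs(total / scale - 1.0) > 5e-3:
        raise ValueError(f"{name}: fractions sum to {total:g}, expected "
                         f"{scale:g} within 1e-6")
    norm = {}
    for sym, w in fractions.items():
        if w < 0:
            raise ValueError(f"{name}: negative fraction for {sym}")
        element_table(sym)  # raises UnknownElementError if unregistered
        if w > 0:
            norm[sym] = w / total
    return Material(name=name, density=float(density), fractions=norm)


@lru_cache(maxsize=None)
def _registry() -> dict:
    with (_DATA / "materials.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {name: build_material(name, spec["fractions"], spec["density"])
            for name, spec in raw.items()}


def get_material(name: str) -> Material:
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown material {name!r}; available: {sorted(reg)}")
    return reg[name]


def available_materials() -> list[str]:
    return sorted(_registry())


def load_gnp_tumor(base: Material, c_mg_per_g: float) -> Material:
    """Load ``base`` tissue with gold nanoparticles at ``c`` mg Au per g tissue.

    Modelled as a homogeneous mixture: w_Au = c/(1000+c), the other fractions
    are scaled by 1000/(1000+c), and the density follows the inverse
    mass-fraction rule 1/rho = sum_i w_i/rho_i with bulk gold density.
    """
    if c_mg_per_g < 0:
        raise ValueError("GNP concentration must be non-negative")
    if base.fractions.get("Au", 0.0) > 0:
        raise ValueError(f"base material {base.name!r} already contains gold")
    if c_mg_per_g == 0:
        return base
    w_au = c_mg_per_g / (1000.0 + c_mg_per_g)
    fractions = {sym: w * (1.0 - w_au) for sym, w in base.fractions.items()}
    fractions["Au"] = w_au
    inv_rho = (1.0 - w_au) / base.density + w_au / GOLD_DENSITY
    return Material(name=f"{base.name}+Au{c_mg_per_g:g}mg/g",
                    density=1.0 / inv_rho, fractions=fractions)


def mu_partials(m: Material, e_keV) -> tuple:
    """Linear attenuation partials (mu_pe, mu_incoh, mu_coh) in 1/cm."""
    pe = inc = coh = 0.0
    for sym, w in m.fractions.items():
        t = element_table(sym)
        pe = pe + w * t._interp(t.sigma_pe, e_keV)
        inc = inc + w * t._interp(t.sigma_incoh, e_keV)
        coh = coh + w * t._interp(t.sigma_coh, e_keV)
    rho = m.density
    return pe * rho, inc * rho, coh * rho


def mu_total(m: Material, e_keV) -> float | np.ndarray:
    """Total linear attenuation coefficient, 1/cm."""
    pe, inc, coh = mu_partials(m, e_keV)
    return pe + inc + coh


def mu_en_mass(m: Material, e_keV) -> float | np.ndarray:
    """Mass energy-absorption coefficient mu_en/rho, cm^2/g."""
    out = 0.0
    for sym, w in m.fractions.items():
        t = element_table(sym)
        out = out + w * t._interp(t.mu_en_rho, e_keV)
    return out
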