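"""Model-6711 I-125 seed: capsule/rod dimensions and photon emission.

The seed is a titanium capsule (0.8 mm outer diameter, 0.05 mm wall, 4.5 mm
long, flat end welds) holding a 3.0 x 0.5 mm silver rod whose surface
carries the radioiodine (AgI layer); emission is sampled uniformly on the
rod surface with isotropic directions. Initial energies come from the I-125
line spectrum; silver K x-rays arise physically from photoelectric events in
the rod during transport rather than being folded into the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from . import _kernel
from .geometry import (SEED_CAPSULE_HALF_LEN, SEED_CAPSULE_R,
                       SEED_CAPSULE_WALL, SEED_ROD_HALF_LEN, SEED_ROD_R)


@dataclass(frozen=True)
class SeedModel6711:
    capsule_outer_diameter: float = 2 * SEED_CAPSULE_R
    capsule_wall: float = SEED_CAPSULE_WALL
    capsule_length: float = 2 * SEED_CAPSULE_HALF_LEN
    rod_diameter: float = 2 * SEED_ROD_R
    rod_length: float = 2 * SEED_ROD_HALF_LEN

    @property
    def active_length(self) -> float:
        return self.rod_length


@dataclass(frozen=True)
class EmissionSpectrum:
    name: str
    energies: np.ndarray      # keV
    intensities: np.ndarray   # photons per decay

    @property
    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.intensities)
        return c / c[-1]

    @property
    def mean_energy(self) -> float:
        return float((self.energies * self.intensities).sum()
                     / self.intensities.sum())


_SPECTRA = {"6711-TG43": "i125_tg43.csv", "I125": "i125_tg43.csv"}


@lru_cache(maxsize=None)
def load_spectrum(name: str = "6711-TG43") -> EmissionSpectrum:
    if name not in _SPECTRA:
        raise KeyError(f"unknown spectrum {name!r}; known: {sorted(_SPECTRA)}")
    path = resources.files("plaquedose") / "data" / "spectra" / _SPECTRA[name]
    raw = np.genfromtxt(path.open("rb"), delimiter=",", names=True,
                        skip_header=4)
    e = np.atleast_1d(raw["energy_keV"])
    p = np.atleast_1d(raw["intensity_per_decay"])
    if np.any(p <= 0):
        raise ValueError("spectrum intensities must be positive")
    return EmissionSpectrum(name=name, energies=np.ascontiguousarray(e),
                            intensities=np.ascontiguousarray(p))


def sample_emission(n: int, seed: int = 1, transform=None,
                    spectrum: EmissionSpectrum | None = None):
    """Sample ``n`` emission (position, direction, energy) triples.

    ``transform`` is a (position, axis) pair; defaults to a seed at the
    origin with its long axis along +z.
    """
    if spectrum is None:
        spectrum = load_spectrum()
    pos, axis = transform or ((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    h = np.array([1.0, 0.0, 0.0])
    if abs(a @ h) > 0.9:
        h = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, h)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return _kernel.sample_emissions(
        n, np.asarray([pos], float), np.asarray([a]), np.asarray([e1]),
        np.asarray([e2]), SEED_ROD_R, SEED_ROD_HALF_LEN,
        spectrum.energies, spectrum.cdf, seed)
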