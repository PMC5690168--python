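"""Tally geometry and batch statistics.

Transverse-plane dose falloff around a single seed is scored in revolved
("toroid") cells centered on the seed's transverse plane, with the minor
radius shrinking toward the source to limit volume averaging:

    R = 0.008 cm for 0.05 < r <= 0.1 cm
    R = 0.01  cm for 0.1  < r <= 1 cm
    R = 0.05  cm for 1    < r <= 5 cm
    R = 0.1   cm for 5    < r <= 10 cm (and beyond)

Air-kerma tallies reuse the same shapes, filled with dry air as a fixed
scoring medium, in vacuum. The toroid cells are modelled with a square cross
section of half-width R (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .geometry import Region, Scene

# Table-style radial grid used for the radial dose function (cm)
RDF_RADII = (0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.15, 0.20, 0.25, 0.30,
             0.40, 0.50, 0.60, 0.70, 0.75, 0.80, 0.90, 1.0, 1.5, 2.0, 2.5,
             3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5,
             9.0, 9.5, 10.0)
AIR_KERMA_RADII = tuple(list(RDF_RADII) + [12.5, 15.0, 20.0])


def toroid_minor_radius(r: float) -> float:
    if r <= 0.1:
        return 0.008
    if r <= 1.0:
        return 0.01
    if r <= 5.0:
        return 0.05
    return 0.1


def add_transverse_toroids(scene: Scene, radii, axis=(0, 0, 1),
                           center=(0, 0, 0), medium: str = "local",
                           prefix: str = "tor") -> list:
    """Toroid tallies on the transverse plane of a seed at ``center`` whose
    long axis is ``axis``. Returns the region names in radius order."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    names = []
    for r in radii:
        hw = toroid_minor_radius(r)
        name = f"{prefix}_{r:g}"
        scene.add_region(Region(
            name=name, kind="washer",
            params=(center[0], center[1], center[2], a[0], a[1], a[2],
                    0.0, r, hw),
            medium=medium))
        names.append(name)
    return names


def add_reference_torus(scene: Scene, axis=(0, 0, 1), center=(0, 0, 0),
                        r0: float = 1.0, minor_diameter: float = 0.01,
                        name: str = "ref_torus") -> str:
    """The dose-rate-constant scoring cell: a thin torus at r0 on the
    transverse plane with 0.01 cm minor cross-sectional diameter."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    scene.add_region(Region(
        name=name, kind="washer",
        params=(center[0], center[1], center[2], a[0], a[1], a[2],
                0.0, r0, minor_diameter / 2.0),
        medium="local"))
    return name


def air_kerma_curve(result, radii=AIR_KERMA_RADII, prefix: str = "air"):
    """(d, K*d^2, rel_err) triples from an in-vacuum air-kerma run.

    K*d^2 is in Gy*cm^2 per history; empty toroids are flagged."""
    out = []
    for r in radii:
        t = result[f"{prefix}_{r:g}"]
        if t.hits == 0:
            raise ValueError(f"air-kerma toroid at {r} cm scored no tracks")
        out.append((r, t.mean * r * r, t.rel_err))
    return np.array(out)


def batch_rel_err(batch_means: np.ndarray) -> float:
    m = batch_means.mean()
    if m == 0:
        return 0.0
    return float(batch_means.std(ddof=1) / np.sqrt(batch_means.size) / m)
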