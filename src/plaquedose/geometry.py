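"""Constructive-solid-geometry scenes for the eye phantom and seed sources.

A :class:`Scene` is an ordered collection of *objects* (seed capsules, plaque,
tumor, lens, optic nerve, eye shells, skull, enclosing water cube), each made
of one or more *cells* -- intersections of signed quadric half-spaces. Objects
carry a priority: a point belongs to the first (highest-priority) cell that
contains it, which lets embedded bodies (seeds inside the Silastic carrier,
tumor inside the eye) be expressed without explicit complements.

Geometry of the phantom (all lengths cm, origin at the globe center):

* vitreous inside r=0.93; retina 0.93-1.03 and choroid 1.03-1.13 (water
  composition); sclera 1.13-1.23;
* ellipsoidal lens, equatorial diameters 0.8 x 0.9, polar thickness 0.25,
  centered on the anterior (+z) axis;
* optic nerve as the annulus between coaxial cylinders of diameters 0.7 and
  0.8 along the posterior (-z) axis, from the globe to the skull;
* skull shell between spheres 1.505 and 2.05;
* everything inside a 30x30x30 water cube.

The 16 mm COMS plaque is a spherical-cap gold-alloy (Modulay) backing with a
Silastic seed carrier conformal to the outer sclera, holding 13 model-6711
seeds tangent to the cap; the tumor is a spherical-cap dome based on the
inner sclera with its apex 6 mm from the exterior scleral surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .xsdata import Material

# surface type codes shared with the transport kernel
SPHERE, PLANE, CYL, ELLIPSOID, CONE = 0, 1, 2, 3, 4

EYE_RADII = (0.93, 1.03, 1.13, 1.23)
SKULL_RADII = (1.505, 2.05)
CUBE_HALF = 15.0

# model 6711 seed (CLRP-style description): titanium capsule 0.8 mm OD,
# 0.05 mm wall, 4.5 mm long with flat end welds; 3.0 x 0.5 mm silver rod.
SEED_CAPSULE_R = 0.040
SEED_CAPSULE_WALL = 0.005
SEED_CAPSULE_HALF_LEN = 0.225
SEED_ROD_R = 0.025
SEED_ROD_HALF_LEN = 0.150

# COMS 16 mm plaque package defaults (editable via add_coms_plaque arguments)
PLAQUE_INNER_R = 1.23          # conformal to outer sclera
SILASTIC_THICKNESS = 0.24
BACKING_THICKNESS = 0.05
PLAQUE_HALF_ANGLE = math.degrees(math.asin(0.8 / 1.23))  # 16 mm footprint
LIP_ANGLE = 4.0
SEED_CENTER_R = 1.35
# two concentric rings (5 + 8 seeds): polar angle (deg), count, first
# azimuth (deg), orientation of the long axis ('meridian' or 'azimuthal')
SEED_RINGS = ((13.0, 5, 0.0, "meridian"), (31.5, 8, 22.5, "azimuthal"))


@dataclass
class Cell:
    name: str
    material: str  # material name; "vacuum" for void
    surfaces: list  # [(surface index, sign)], sign=-1 inside (f<0)


@dataclass
class SceneObject:
    name: str
    priority: int
    cells: list
    bound: tuple | None  # (cx, cy, cz, R) bounding sphere, None = unbounded


@dataclass
class Region:
    """Tally region: 'box' (axis-aligned), 'washer' (revolved square cross
    section standing in for the toroid cells), 'sphere' or 'shell'."""

    name: str
    kind: str
    params: tuple
    medium: str = "local"  # 'local' or a fixed material name

    @property
    def volume(self) -> float:
        p = self.params
        if self.kind == "box":
            return 8.0 * p[3] * p[4] * p[5]
        if self.kind == "washer":
            r, hw = p[7], p[8]
            return 8.0 * math.pi * r * hw * hw
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * p[3] ** 3
        if self.kind == "shell":
            return 4.0 / 3.0 * math.pi * (p[4] ** 3 - p[3] ** 3)
        raise ValueError(self.kind)

    @property
    def bound(self) -> tuple:
        p = self.params
        if self.kind == "box":
            return (p[0], p[1], p[2], math.hypot(p[3], math.hypot(p[4], p[5])))
        if self.kind == "washer":
            return (p[0], p[1], p[2], p[7] + 2.0 * p[8])
        if self.kind == "sphere":
            return (p[0], p[1], p[2], p[3])
        return (p[0], p[1], p[2], p[4])


@dataclass
class Scene:
    surf_type: list = field(default_factory=list)
    surf_par: list = field(default_factory=list)
    objects: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    seed_transforms: list = field(default_factory=list)  # (pos, axis)
    custom_materials: dict = field(default_factory=dict)  # name -> Material
    mode: str = "eye"
    tags: dict = field(default_factory=dict)

    # -- surface helpers -------------------------------------------------
    def _surf(self, kind: int, *par) -> int:
        p = list(par) + [0.0] * (7 - len(par))
        self.surf_type.append(kind)
        self.surf_par.append(p)
        return len(self.surf_type) - 1

    def sphere(self, c, r) -> int:
        return self._surf(SPHERE, c[0], c[1], c[2], r)

    def plane(self, n, d) -> int:
        n = np.asarray(n, float)
        n = n / np.linalg.norm(n)
        return self._surf(PLANE, n[0], n[1], n[2], d)

    def cylinder(self, p, axis, r) -> int:
        a = np.asarray(axis, float)
        a = a / np.linalg.norm(a)
        return self._surf(CYL, p[0], p[1], p[2], a[0], a[1], a[2], r)

    def ellipsoid(self, c, semi) -> int:
        return self._surf(ELLIPSOID, c[0], c[1], c[2], semi[0], semi[1], semi[2])

    def cone(self, apex, axis, half_angle_deg) -> int:
        a = np.asarray(axis, float)
        a = a / np.linalg.norm(a)
        c2 = math.cos(math.radians(half_angle_deg)) ** 2
        return self._surf(CONE, apex[0], apex[1], apex[2], a[0], a[1], a[2], c2)

    def add_object(self, name, priority, cells, bound=None) -> None:
        self.objects.append(SceneObject(name, priority, cells, bound))

    def add_region(self, region: Region) -> None:
        self.regions.append(region)

    def material_for(self, name: str) -> str:
        """Apply composition mode: in the all-water phantom every ocular
        material becomes water; construction materials are unaffected."""
        ocular = {"vitreous", "sclera", "lens", "optic_nerve", "skull_bone",
                  "tumor", "retina", "choroid", "aqueous_humor"}
        if self.mode == "water" and name in ocular:
            return "water"
        if name in ("retina", "choroid"):
            return "water"  # modelled as water in both modes
        return name

    @property
    def cell_names(self) -> list:
        out = []
        for obj in sorted(self.objects, key=lambda o: o.priority):
            out.extend(c.name for c in obj.cells)
        return out


def _rotation_to(axis) -> np.ndarray:
    """Rotation matrix mapping +x onto ``axis``."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, a)
    c = float(np.dot(x, a))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_eye_phantom(composition_mode: str = "eye",
                      lens_polar_thickness: float = 0.25,
                      cube_half: float = CUBE_HALF,
                      world_material: str = "water") -> Scene:
    """Heterogeneous eye globe (or its all-water twin) in a 30 cm water cube.

    ``composition_mode='water'`` keeps the identical geometry but assigns
    water to every ocular cell.
    """
    if composition_mode not in ("eye", "water"):
        raise ValueError("composition_mode must be 'eye' or 'water'")
    sc = Scene(mode=composition_mode)
    m = sc.material_for

    s_eye = [sc.sphere((0, 0, 0), r) for r in EYE_RADII]
    s_len = sc.ellipsoid((0, 0, 0.66), (0.40, 0.45, lens_polar_thickness / 2))
    sc.add_object("lens", 30, [Cell("lens", m("lens"), [(s_len, -1)])],
                  bound=(0, 0, 0.66, 0.52))

    s_cyl_in = sc.cylinder((0, 0, 0), (0, 0, 1), 0.35)
    s_cyl_out = sc.cylinder((0, 0, 0), (0, 0, 1), 0.40)
    s_zneg = sc.plane((0, 0, 1), 0.0)
    s_skull = [sc.sphere((0, 0, 0), r) for r in SKULL_RADII]
    sc.add_object("optic_nerve", 40, [Cell(
        "optic_nerve", m("optic_nerve"),
        [(s_cyl_in, 1), (s_cyl_out, -1), (s_zneg, -1),
         (s_eye[3], 1), (s_skull[0], -1)])],
        bound=(0, 0, -1.37, 0.60))

    sc.add_object("eye", 50, [
        Cell("vitreous", m("vitreous"), [(s_eye[0], -1)]),
        Cell("retina", m("retina"), [(s_eye[0], 1), (s_eye[1], -1)]),
        Cell("choroid", m("choroid"), [(s_eye[1], 1), (s_eye[2], -1)]),
        Cell("sclera", m("sclera"), [(s_eye[2], 1), (s_eye[3], -1)]),
    ], bound=(0, 0, 0, EYE_RADII[3]))

    sc.add_object("skull", 60, [Cell(
        "skull", m("skull_bone"), [(s_skull[0], 1), (s_skull[1], -1)])],
        bound=(0, 0, 0, SKULL_RADII[1]))

    planes = []
    for ax in range(3):
        n = [0.0, 0.0, 0.0]
        n[ax] = 1.0
        planes.append((sc.plane(tuple(n), cube_half), -1))
        planes.append((sc.plane(tuple(n), -cube_half), 1))
    sc.add_object("world", 100, [Cell("world", world_material, planes)],
                  bound=None)
    sc.tags["cube_half"] = cube_half
    return sc


def add_tumor(scene: Scene, apex_height: float = 0.5, axis=(1, 0, 0),
              basal_chord: float = 1.1, material: "str | Material" = None) -> Scene:
    """Dome-shaped (spherical-cap) choroidal melanoma based on the inner
    sclera, apex ``apex_height`` cm toward the globe center (i.e. the apex is
    ``apex_height + 0.1`` cm from the exterior scleral surface)."""
    if apex_height == 0:
        return scene
    if not 0.25 <= apex_height <= 1.0:
        raise ValueError("apex height outside the plaque-therapy range "
                         "(0.25-1.0 cm)")
    rot = _rotation_to(axis)
    x_apex = EYE_RADII[2] - apex_height
    b = basal_chord / 2.0
    x_base = math.sqrt(EYE_RADII[2] ** 2 - b * b)
    d = x_base - x_apex
    r_t = (d * d + b * b) / (2.0 * d)
    center = rot @ np.array([x_apex + r_t, 0.0, 0.0])

    if material is None:
        material = scene.material_for("tumor")
    if isinstance(material, Material):
        scene.custom_materials[material.name] = material
        mat_name = material.name
    else:
        mat_name = material

    s_t = scene.sphere(center, r_t)
    s_in = scene.sphere((0, 0, 0), EYE_RADII[2])
    scene.add_object("tumor", 20,
                     [Cell("tumor", mat_name, [(s_t, -1), (s_in, -1)])],
                     bound=tuple(rot @ np.array([0.88, 0, 0])) + (0.62,))
    scene.tags["tumor"] = dict(apex_height=apex_height, axis=tuple(axis),
                               x_apex=x_apex, r=r_t, center=tuple(center))
    return scene


def seed_slots_coms16(axis=(1, 0, 0)) -> list:
    """13 seed transforms (center, long axis) tangent to the 16 mm cap."""
    rot = _rotation_to(axis)
    out = []
    for polar, n, az0, orient in SEED_RINGS:
        th = math.radians(polar)
        for k in range(n):
            ph = math.radians(az0 + 360.0 * k / n)
            radial = np.array([math.cos(th),
                               math.sin(th) * math.cos(ph),
                               math.sin(th) * math.sin(ph)])
            if orient == "meridian":  # along the great circle toward the pole
                tang = np.array([-math.sin(th),
                                 math.cos(th) * math.cos(ph),
                                 math.cos(th) * math.sin(ph)])
            else:  # tangent along the ring
                tang = np.array([0.0, -math.sin(ph), math.cos(ph)])
            out.append((rot @ (SEED_CENTER_R * radial), rot @ tang))
    return out


def _check_seed_overlaps(transforms) -> None:
    h, rad = SEED_CAPSULE_HALF_LEN, SEED_CAPSULE_R
    for i in range(len(transforms)):
        for j in range(i + 1, len(transforms)):
            pi, ai = transforms[i]
            pj, aj = transforms[j]
            ts = np.linspace(-h, h, 9)
            dmin = min(np.linalg.norm((pi + t1 * ai) - (pj + t2 * aj))
                       for t1 in ts for t2 in ts)
            if dmin < 2 * rad + 0.005:
                raise ValueError(f"seed slots {i} and {j} overlap "
                                 f"(min distance {dmin:.4f} cm)")


def add_seed(scene: Scene, pos, axis, index: int) -> None:
    pos = np.asarray(pos, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    cyl_rod = scene.cylinder(pos, a, SEED_ROD_R)
    cyl_in = scene.cylinder(pos, a, SEED_CAPSULE_R - SEED_CAPSULE_WALL)
    cyl_out = scene.cylinder(pos, a, SEED_CAPSULE_R)
    d0 = float(np.dot(a, pos))

    def pl(h):
        return (scene.plane(a, d0 + h), -1), (scene.plane(a, d0 - h), 1)

    p_rod_hi, p_rod_lo = pl(SEED_ROD_HALF_LEN)
    p_in_hi, p_in_lo = pl(SEED_CAPSULE_HALF_LEN - SEED_CAPSULE_WALL)
    p_out_hi, p_out_lo = pl(SEED_CAPSULE_HALF_LEN)
    cells = [
        Cell(f"seed{index}_rod", "silver", [(cyl_rod, -1), p_rod_hi, p_rod_lo]),
        Cell(f"seed{index}_interior", "dry_air",
             [(cyl_in, -1), p_in_hi, p_in_lo]),
        Cell(f"seed{index}_capsule", "titanium",
             [(cyl_out, -1), p_out_hi, p_out_lo]),
    ]
    scene.add_object(f"seed{index}", index, cells,
                     bound=tuple(pos) + (0.25,))
    scene.seed_transforms.append((tuple(pos), tuple(a)))


def add_coms_plaque(scene: Scene, diameter: float = 16.0, axis=(1, 0, 0),
                    include_plaque: bool = True) -> Scene:
    """Fully loaded 16 mm COMS plaque: Modulay backing + Silastic carrier +
    13 model-6711 seeds. ``include_plaque=False`` places the same 13 seeds
    without the carrier and backing ("seeds in water")."""
    if diameter != 16.0:
        raise ValueError("only the 16 mm COMS plaque is modelled")
    transforms = seed_slots_coms16(axis)
    _check_seed_overlaps(transforms)
    for i, (pos, a) in enumerate(transforms):
        add_seed(scene, pos, a, index=i)

    if include_plaque:
        rot = _rotation_to(axis)
        r_sil = PLAQUE_INNER_R + SILASTIC_THICKNESS
        r_back = r_sil + BACKING_THICKNESS
        s_in = scene.sphere((0, 0, 0), PLAQUE_INNER_R)
        s_sil = scene.sphere((0, 0, 0), r_sil)
        s_back = scene.sphere((0, 0, 0), r_back)
        c_main = scene.cone((0, 0, 0), rot @ np.array([1.0, 0, 0]),
                            PLAQUE_HALF_ANGLE)
        c_lip = scene.cone((0, 0, 0), rot @ np.array([1.0, 0, 0]),
                           PLAQUE_HALF_ANGLE + LIP_ANGLE)
        s_half = scene.plane(rot @ np.array([1.0, 0, 0]), 0.0)
        cells = [
            Cell("plaque_backing", "modulay",
                 [(s_sil, 1), (s_back, -1), (c_main, -1), (s_half, 1)]),
            Cell("plaque_lip", "modulay",
                 [(s_in, 1), (s_back, -1), (c_main, 1), (c_lip, -1),
                  (s_half, 1)]),
            Cell("seed_carrier", "silastic",
                 [(s_in, 1), (s_sil, -1), (c_main, -1), (s_half, 1)]),
        ]
        bc = rot @ np.array([0.95, 0, 0])
        scene.add_object("plaque", 15, cells, bound=tuple(bc) + (1.15,))
    scene.tags["plaque"] = dict(diameter=diameter, axis=tuple(axis),
                                include_plaque=include_plaque)
    return scene


def single_seed_scene(world_material: str = "water",
                      cube_half: float = CUBE_HALF) -> Scene:
    """One model-6711 seed at the origin, long axis +z, in a water cube or
    (``world_material='vacuum'``) in vacuum for air-kerma runs."""
    sc = Scene(mode="water")
    planes = []
    for ax in range(3):
        n = [0.0, 0.0, 0.0]
        n[ax] = 1.0
        planes.append((sc.plane(tuple(n), cube_half), -1))
        planes.append((sc.plane(tuple(n), -cube_half), 1))
    add_seed(sc, (0, 0, 0), (0, 0, 1), index=0)
    sc.add_object("world", 100, [Cell("world", world_material, planes)],
                  bound=None)
    sc.tags["cube_half"] = cube_half
    return sc
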