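"""Analog photon Monte Carlo driver.

Compiles a :class:`~plaquedose.geometry.Scene` plus its material assignments
into the flat arrays consumed by the numba kernel, runs batches of histories
and returns per-region track-length kerma tallies with batch statistics.

Physics configuration lives in :class:`RunConfig`: number of histories,
batch count, RNG seed, the 5 keV photon cutoff, and whether gold L-shell
fluorescence photons are transported (by default they are deposited locally;
the K fluorescence of silver, palladium and copper is always transported
since those lines fall inside the source energy window).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import _kernel, xsdata
from .geometry import Scene

KEV_PER_G_TO_GY = 1.602176634e-13  # (keV/g) -> Gy


@dataclass
class RunConfig:
    histories: int = 1_000_000
    batches: int = 20
    seed: int = 1
    cutoff_keV: float = 5.0
    emit_au_l: bool = False

    def __post_init__(self):
        if not self.histories >= self.batches >= 2:
            raise ValueError("need histories >= batches >= 2")


@dataclass
class TallyResult:
    """Per-region kerma score in Gy per history with batch statistics."""

    name: str
    mean: float          # Gy per history (track-length estimator)
    rel_err: float       # relative standard error of the mean
    volume: float        # cm^3
    hits: int
    collision_mean: float = 0.0  # collision-estimator cross-check
    primary_mean: float = 0.0    # uncollided (first-flight) component

    @property
    def value(self):
        return self.mean


@dataclass
class RunResult:
    tallies: dict
    energy_balance: np.ndarray  # per batch: emitted, deposited, escaped
    lost_particles: int
    manifest: dict = field(default_factory=dict)
    uncollided_escapes: int = 0

    def __getitem__(self, name: str) -> TallyResult:
        return self.tallies[name]


class CompiledScene:
    """Scene + materials flattened for the kernel; reusable across runs."""

    def __init__(self, scene: Scene, cutoff_keV: float = 5.0,
                 emit_au_l: bool = False):
        self.scene = scene
        self.cutoff = cutoff_keV
        objs = sorted(scene.objects, key=lambda o: o.priority)
        self.surf_type = np.asarray(scene.surf_type, dtype=np.int64)
        self.surf_par = np.asarray(scene.surf_par, dtype=np.float64)

        # materials referenced by cells and fixed-medium regions
        names: list[str] = []

        def mat_index(name: str) -> int:
            if name == "vacuum":
                return -1
            if name not in names:
                names.append(name)
            return names.index(name)

        obj_bound, obj_cell_ptr, cell_ptr = [], [0], [0]
        csi, css, cmat, osp, osi = [], [], [], [0], []
        self.cell_names: list[str] = []
        for o in objs:
            if o.bound is None:
                obj_bound.append((0.0, 0.0, 0.0, _kernel.INF))
            else:
                obj_bound.append(o.bound)
            surfs = []
            for c in o.cells:
                self.cell_names.append(c.name)
                for si, sign in c.surfaces:
                    csi.append(si)
                    css.append(float(sign))
                    if si not in surfs:
                        surfs.append(si)
                cell_ptr.append(len(csi))
                cmat.append(mat_index(c.material))
            obj_cell_ptr.append(len(cmat))
            osi.extend(surfs)
            osp.append(len(osi))
        self.obj_bound = np.asarray(obj_bound, dtype=np.float64)
        self.obj_cell_ptr = np.asarray(obj_cell_ptr, dtype=np.int64)
        self.cell_surf_ptr = np.asarray(cell_ptr, dtype=np.int64)
        self.cell_surf_idx = np.asarray(csi, dtype=np.int64)
        self.cell_surf_sign = np.asarray(css, dtype=np.float64)
        self.cell_mat = np.asarray(cmat, dtype=np.int64)
        self.obj_surf_ptr = np.asarray(osp, dtype=np.int64)
        self.obj_surf_idx = np.asarray(osi, dtype=np.int64)

        # regions (fixed media may add materials)
        self.region_names = [r.name for r in scene.regions]
        self.reg_volumes = np.array([r.volume for r in scene.regions])
        rtypes = {"box": _kernel.R_BOX, "washer": _kernel.R_WASHER,
                  "sphere": _kernel.R_SPHERE, "shell": _kernel.R_SHELL}
        n_reg = len(scene.regions)
        self.reg_type = np.array([rtypes[r.kind] for r in scene.regions],
                                 dtype=np.int64)
        self.reg_par = np.zeros((n_reg, 9))
        self.reg_bound = np.zeros((n_reg, 4))
        self.reg_matref = np.zeros(n_reg, dtype=np.int64)
        for i, r in enumerate(scene.regions):
            p = list(r.params) + [0.0] * (9 - len(r.params))
            self.reg_par[i] = p
            self.reg_bound[i] = r.bound
            self.reg_matref[i] = (-1 if r.medium == "local"
                                  else mat_index(r.medium))
        if n_reg:
            gr = max(np.linalg.norm(self.reg_bound[i, :3]) + self.reg_bound[i, 3]
                     for i in range(n_reg))
            self.reg_gbound = np.array([0.0, 0.0, 0.0, gr])
        else:
            self.reg_gbound = np.array([0.0, 0.0, 0.0, -1.0])

        self._compile_materials(names, cutoff_keV, emit_au_l)

    # -- material tables --------------------------------------------------
    def _compile_materials(self, names, cutoff, emit_au_l):
        self.material_names = names
        mats = [self.scene.custom_materials.get(n) or xsdata.get_material(n)
                for n in names]
        grids, lpe, linc, lcoh, ltot, lmuen = [], [], [], [], [], []
        mat_ptr = [0]
        for m in mats:
            grid = np.unique(np.concatenate(
                [xsdata.element_table(s).e_keV for s in m.fractions]))
            pe, inc, coh = xsdata.mu_partials(m, grid)
            muen = xsdata.mu_en_mass(m, grid)
            grids.append(np.log(grid))
            lpe.append(np.log(pe))
            linc.append(np.log(inc))
            lcoh.append(np.log(coh))
            ltot.append(np.log(pe + inc + coh))
            lmuen.append(np.log(muen))
            mat_ptr.append(mat_ptr[-1] + grid.size)
        self.mat_ptr = np.asarray(mat_ptr, dtype=np.int64)
        self.mat_le = (np.concatenate(grids) if grids
                       else np.zeros(0))
        self.mat_lpe = np.concatenate(lpe) if lpe else np.zeros(0)
        self.mat_linc = np.concatenate(linc) if linc else np.zeros(0)
        self.mat_lcoh = np.concatenate(lcoh) if lcoh else np.zeros(0)
        self.mat_ltot = np.concatenate(ltot) if ltot else np.zeros(0)
        self.mat_lmuen = np.concatenate(lmuen) if lmuen else np.zeros(0)

        # incoherent-function rejection tables (shared x grid)
        any_el = xsdata.element_table("O")
        self.sx_grid = any_el.x
        nmat = max(len(mats), 1)
        self.mat_sfrac = np.zeros((nmat, self.sx_grid.size))
        # coherent form-factor cumulative over x^2
        self.x2_grid = np.concatenate([[0.0], np.geomspace(1e-4, 64.0, 255)])
        self.mat_fcum = np.zeros((nmat, self.x2_grid.size))
        for i, m in enumerate(mats):
            ssum = np.zeros_like(self.sx_grid)
            zsum = 0.0
            f2 = np.zeros_like(self.x2_grid)
            for sym, w in m.fractions.items():
                t = xsdata.element_table(sym)
                ssum += (w / t.A) * t.S
                zsum += (w / t.A) * t.Z
                f2 += (w / t.A) * np.interp(np.sqrt(self.x2_grid),
                                            t.x, t.F) ** 2
            self.mat_sfrac[i] = ssum / zsum
            mid = 0.5 * (f2[1:] + f2[:-1]) * np.diff(self.x2_grid)
            self.mat_fcum[i][1:] = np.cumsum(mid)

        # fluorescence lines per material
        fl_ptr, fl_e, fl_pp_ptr, fl_p = [0], [], [0], []
        for mi, m in enumerate(mats):
            grid = np.exp(self.mat_le[self.mat_ptr[mi]:self.mat_ptr[mi + 1]])
            sig_pe_mat = np.zeros_like(grid)
            for sym, w in m.fractions.items():
                t = xsdata.element_table(sym)
                sig_pe_mat += w * t._interp(t.sigma_pe, grid)
            for sym, w in m.fractions.items():
                t = xsdata.element_table(sym)
                for edge in t.edges:
                    if edge["shell"].startswith("L") and not emit_au_l \
                            and sym in ("Au", "Pt"):
                        continue
                    share = np.where(grid > edge["E_keV"],
                                     edge["share_above_edge"], 0.0)
                    for eh, sh in zip(edge["higher_edges"],
                                      edge["higher_shares"]):
                        share = share * np.where(grid > eh, 1.0 - sh, 1.0)
                    frac_el = w * t._interp(t.sigma_pe, grid) / \
                        np.maximum(sig_pe_mat, 1e-300)
                    for line in edge["lines"]:
                        if line["E_keV"] < cutoff:
                            continue
                        p = (frac_el * share * edge["fluor_yield"]
                             * line["frac"])
                        if p.max() <= 0:
                            continue
                        fl_e.append(line["E_keV"])
                        fl_p.extend(p)
                        fl_pp_ptr.append(len(fl_p))
            fl_ptr.append(len(fl_e))
        self.fl_ptr = np.asarray(fl_ptr, dtype=np.int64)
        self.fl_e = np.asarray(fl_e if fl_e else [0.0], dtype=np.float64)
        self.fl_pp_ptr = np.asarray(fl_pp_ptr, dtype=np.int64)
        self.fl_p = np.asarray(fl_p if fl_p else [0.0], dtype=np.float64)

    def locate(self, point) -> str:
        """Name of the cell containing ``point`` ('<escaped>' outside)."""
        c = _kernel.locate(point[0], point[1], point[2], self.surf_type,
                           self.surf_par, self.obj_bound, self.obj_cell_ptr,
                           self.cell_surf_ptr, self.cell_surf_idx,
                           self.cell_surf_sign)
        return self.cell_names[c] if c >= 0 else "<escaped>"

    def trace(self, point, direction) -> tuple:
        """(cell name at point, distance to the next surface crossing)."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        cell = self.locate(point)
        t = _kernel.boundary_distance(point[0], point[1], point[2],
                                      d[0], d[1], d[2], self.surf_type,
                                      self.surf_par, self.obj_bound,
                                      self.obj_surf_ptr, self.obj_surf_idx)
        return cell, float(t)


SOURCE_MODES = {"seed": 0, "point": 1, "pencil": 2}


def run(scene: Scene, config: RunConfig, spectrum=None,
        compiled: CompiledScene | None = None,
        source_mode: str = "seed") -> RunResult:
    """Transport ``config.histories`` photons through ``scene``.

    Histories are attributed round-robin to the scene's sources (equal
    activity). ``source_mode`` selects 6711 rod-surface emission (default),
    an isotropic point source, or a pencil beam along the source axis; the
    latter two are used by the analytic oracle fixtures. Returns per-region
    kerma in Gy per history.
    """
    from .source import load_spectrum

    if spectrum is None:
        spectrum = load_spectrum("6711-TG43")
    cs = compiled or CompiledScene(scene, config.cutoff_keV, config.emit_au_l)
    if not scene.seed_transforms:
        raise ValueError("scene has no sources")
    src_pos = np.array([t[0] for t in scene.seed_transforms])
    src_ax = np.array([t[1] for t in scene.seed_transforms])
    src_e1 = np.empty_like(src_ax)
    src_e2 = np.empty_like(src_ax)
    for i, a in enumerate(src_ax):
        h = np.array([1.0, 0.0, 0.0])
        if abs(a @ h) > 0.9:
            h = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, h)
        e1 /= np.linalg.norm(e1)
        src_e1[i] = e1
        src_e2[i] = np.cross(a, e1)

    from .geometry import SEED_ROD_HALF_LEN, SEED_ROD_R

    t0 = time.perf_counter()
    scores, prim, coll, hits, ebook, lost, unc = _kernel.run_kernel(
        cs.surf_type, cs.surf_par, cs.obj_bound, cs.obj_cell_ptr,
        cs.cell_surf_ptr, cs.cell_surf_idx, cs.cell_surf_sign, cs.cell_mat,
        cs.obj_surf_ptr, cs.obj_surf_idx,
        cs.mat_ptr, cs.mat_le, cs.mat_lpe, cs.mat_linc, cs.mat_lcoh,
        cs.mat_ltot, cs.mat_lmuen,
        cs.sx_grid, cs.mat_sfrac, cs.x2_grid, cs.mat_fcum,
        cs.fl_ptr, cs.fl_e, cs.fl_pp_ptr, cs.fl_p,
        SOURCE_MODES[source_mode], src_pos, src_ax, src_e1, src_e2,
        SEED_ROD_R if source_mode == "seed" else 0.0, SEED_ROD_HALF_LEN,
        spectrum.energies, spectrum.cdf,
        cs.reg_type, cs.reg_par, cs.reg_bound, cs.reg_matref, cs.reg_gbound,
        config.histories, config.batches, config.cutoff_keV, config.seed,
    )
    elapsed = time.perf_counter() - t0
    if not np.all(np.isfinite(scores)):
        raise RuntimeError("non-finite tally score detected")

    nb = config.batches
    per_batch = config.histories // nb
    tallies = {}
    for i, name in enumerate(cs.region_names):
        batch_means = scores[:, i] / per_batch / cs.reg_volumes[i] \
            * KEV_PER_G_TO_GY
        mean = float(batch_means.mean())
        se = float(batch_means.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
        coll_mean = float(coll[:, i].mean() / per_batch / cs.reg_volumes[i]
                          * KEV_PER_G_TO_GY)
        prim_mean = float(prim[:, i].mean() / per_batch / cs.reg_volumes[i]
                          * KEV_PER_G_TO_GY)
        tallies[name] = TallyResult(
            name=name, mean=mean,
            rel_err=(se / mean if mean > 0 else 0.0),
            volume=float(cs.reg_volumes[i]), hits=int(hits[i]),
            collision_mean=coll_mean, primary_mean=prim_mean)
    manifest = dict(histories=config.histories, batches=nb,
                    seed=config.seed, cutoff_keV=config.cutoff_keV,
                    lost_particles=int(lost), elapsed_s=round(elapsed, 2),
                    n_seeds=len(scene.seed_transforms),
                    source_mode=source_mode,
                    uncollided_escapes=int(unc),
                    scene_mode=scene.mode, tags=dict(scene.tags))
    return RunResult(tallies=tallies, energy_balance=ebook,
                     lost_particles=int(lost), manifest=manifest,
                     uncollided_escapes=int(unc))
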