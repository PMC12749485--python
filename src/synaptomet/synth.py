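"""Synthetic synaptosome generator.

Produces density volumes plus perfectly known ground-truth segmentations
with the statistical structure the downstream analysis assumes: a closed,
gently deformed ellipsoidal plasma membrane; non-overlapping intraluminal
vesicles with controlled diameter and sphericity distributions; tethers
(vesicle-to-membrane) and connectors (vesicle-to-vesicle) rendered as
cylindrical density bridges; and, for paired scenes, an apposed second
compartment with a planar contact patch, a configurable cleft width and an
optional post-synaptic density slab.

Everything is deterministic per (params, seed): the same inputs yield
byte-identical volumes, labels and ground truth.

Geometric conventions: positions in nm, (z, y, x) order; vesicles are
prolate spheroids whose axis ratio is solved from a target Wadell index,
so sphericity is controlled directly by the one shape statistic the
analysis reports.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import sph_harm_y

from .volio import DensityVolume, Segmentation
import pandas as pd


class SynthesisError(RuntimeError):
    """Raised when a scene cannot be realised under the given constraints."""


# label id scheme: per compartment c (1-based), membrane = 1000c+1,
# cytoplasm = 1000c+2, AZ membrane = 1000c+3, PSD = 1000c+4,
# vesicles = 1000c+10 ... ; 0 = extracellular background.
def membrane_label(comp: int) -> int:
    return 1000 * comp + 1


def cytoplasm_label(comp: int) -> int:
    return 1000 * comp + 2


def az_label(comp: int) -> int:
    return 1000 * comp + 3


def psd_label(comp: int) -> int:
    return 1000 * comp + 4


def vesicle_label(comp: int, i: int) -> int:
    return 1000 * comp + 10 + i


@dataclass
class SynthParams:
    """Parameters of one synthetic synaptosome population.

    Defaults follow the glutamatergic (GLU) striatal measurements; use
    :meth:`glu` / :meth:`da` for the two named presets.  All lengths in nm,
    densities in µm^-3, fractions in [0, 1].
    """

    population: str = "GLU"
    #: synaptosome maximal extension distribution (nm)
    synaptosome_diameter_mean: float = 823.0
    synaptosome_diameter_sd: float = 250.0
    #: either an explicit vesicle count, or a density target (µm^-3)
    vesicle_count: int | None = None
    vesicle_density: float = 1956.0
    #: outer (volume-equivalent) vesicle diameter distribution (nm)
    vesicle_diameter_mean: float = 40.4
    vesicle_diameter_sd: float = 7.0
    vesicle_diameter_min: float = 20.0
    vesicle_diameter_max: float = 120.0
    #: target Wadell-index distribution; axis ratios are solved from it
    wadell_mean: float = 0.98
    wadell_sd: float = 0.02
    #: fraction of proximal (<45 nm) vesicles carrying >=1 tether
    tethered_fraction: float = 0.52
    #: membrane gap of tethered vesicles: half-normal scale (nm); small,
    #: so the vesicle-occupancy profile peaks ~20 nm from the membrane
    #: (center of a ~40 nm vesicle sitting nearly docked)
    tethered_gap_scale: float = 4.0
    #: tether length distribution (nm); lengths exceed the gap by obliquity
    tether_length_mean: float = 13.9
    tether_length_sd: float = 7.5
    tether_radius: float = 2.0
    #: oblique tethers let the length distribution exceed the membrane gap;
    #: with obliquity off, tethers are radial and the gap is drawn from the
    #: length distribution directly (length == gap; useful for fixtures)
    tether_obliquity: bool = True
    #: cap on tethers per vesicle; close vesicles carry up to this many
    max_tethers: int = 3
    #: fraction of all vesicles linked to another vesicle by a connector
    connected_fraction: float = 0.64
    connector_length_mean: float = 12.0
    connector_length_sd: float = 6.0
    connector_max_gap: float = 40.0
    #: active-zone patch area (µm^2) carved out of the membrane; tethered
    #: vesicles gather there and distances are AZ-referenced downstream.
    #: None (the DA case) leaves the whole membrane as the reference.
    az_area_um2: float | None = 0.079
    #: minimum membrane gap for initially placed (untethered) vesicles, nm;
    #: keeps fixture scenes free of sub-resolution gaps that no detector
    #: could distinguish from a contact
    placement_min_gap: float = 0.0
    #: geometry / rendering
    membrane_thickness: float = 5.0
    membrane_perturbation: float = 0.04
    proximal_cutoff: float = 45.0
    voxel_size: float = 1.595
    margin: float = 50.0
    noise_sd: float = 0.1
    contrast: str = "dark"  # protein-dark (cryo-ET convention) or "bright"
    missing_wedge: bool = False
    missing_wedge_sigma: float = 2.0

    @classmethod
    def glu(cls, **over) -> "SynthParams":
        """Glutamatergic preset (dense, round, short-tethered vesicles)."""
        return cls(**over)

    @classmethod
    def da(cls, **over) -> "SynthParams":
        """Dopaminergic preset: sparser, larger, more pleomorphic vesicles,
        fewer and longer tethers, fewer connectors."""
        base = dict(
            population="DA",
            synaptosome_diameter_mean=575.0,
            synaptosome_diameter_sd=180.0,
            vesicle_density=682.0,
            vesicle_diameter_mean=45.1,
            vesicle_diameter_sd=9.7,
            wadell_mean=0.93,
            wadell_sd=0.05,
            tethered_fraction=0.25,
            tethered_gap_scale=14.0,
            az_area_um2=None,
            tether_length_mean=22.4,
            tether_length_sd=12.7,
            connected_fraction=0.24,
        )
        base.update(over)
        return cls(**base)

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise SynthesisError("voxel size must be positive")
        for name in ("synaptosome_diameter_sd", "vesicle_diameter_sd",
                     "tether_length_sd", "connector_length_sd", "noise_sd",
                     "wadell_sd"):
            if getattr(self, name) < 0:
                raise SynthesisError(f"{name} must be >= 0")
        for name in ("tethered_fraction", "connected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthesisError(f"{name} must be in [0, 1], got {v}")
        if self.vesicle_diameter_mean >= self.synaptosome_diameter_mean:
            raise SynthesisError(
                "vesicle diameters must be smaller than the synaptosome diameter"
            )
        if self.contrast not in ("dark", "bright"):
            raise SynthesisError("contrast must be 'dark' or 'bright'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlacedVesicle:
    """Ground-truth record of one rendered vesicle."""

    label: int
    compartment: int
    center: tuple[float, float, float]  # nm, (z, y, x)
    semi_axes: tuple[float, float, float]  # body frame, nm
    rotation: list  # 3x3 row-major, body axis vectors in world coords
    diameter: float  # volume-equivalent outer diameter, nm
    wadell: float  # closed-form prolate-spheroid sphericity
    membrane_gap: float  # edge-to-edge distance to membrane, nm
    tethered: bool = False
    n_tethers: int = 0
    n_connectors: int = 0


@dataclass
class PlacedFilament:
    """Ground-truth record of one rendered tether or connector."""

    kind: str  # "tether" | "connector"
    partners: tuple[int, ...]  # label ids (membrane + vesicle, or 2 vesicles)
    p0: tuple[float, float, float]  # nm endpoint on first partner surface
    p1: tuple[float, float, float]
    length: float  # nm, straight-line endpoint distance
    radius: float


@dataclass
class GroundTruth:
    """Complete generative record of a synthetic scene."""

    seed: int
    params: list[dict]
    vesicles: list[PlacedVesicle] = field(default_factory=list)
    filaments: list[PlacedFilament] = field(default_factory=list)
    compartments: dict = field(default_factory=dict)
    contact: dict | None = None
    psd: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        text = json.dumps(dataclasses.asdict(self), default=enc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Prolate-spheroid shape helpers
# ---------------------------------------------------------------------------

def prolate_wadell(q: float) -> float:
    """Wadell sphericity of a prolate spheroid with axis ratio q = c/a >= 1."""
    if q < 1.0:
        raise ValueError("axis ratio must be >= 1")
    if q == 1.0:
        return 1.0
    a, c = 1.0, float(q)
    e = math.sqrt(1.0 - (a / c) ** 2)
    s = 2 * math.pi * a * a * (1 + (c / (a * e)) * math.asin(e))
    v = 4 * math.pi / 3 * a * a * c
    return math.pi ** (1 / 3) * (6 * v) ** (2 / 3) / s


def axis_ratio_for_wadell(w: float) -> float:
    """Invert :func:`prolate_wadell`: the prolate axis ratio with sphericity w."""
    w = float(min(w, 1.0))
    if w >= 1.0 - 1e-9:
        return 1.0
    if w < 0.5:
        raise ValueError(f"target Wadell index {w} below supported range")
    return brentq(lambda q: prolate_wadell(q) - w, 1.0 + 1e-9, 12.0, xtol=1e-6)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _radial_extent(rot: np.ndarray, semi: np.ndarray, d: np.ndarray) -> float:
    """Distance from center to the spheroid surface along world direction d."""
    b = rot @ d
    return 1.0 / math.sqrt(float(np.sum((b / semi) ** 2)))


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

class _Scene:
    """Mutable voxel scene: protein-occupancy grid + label grid."""

    def __init__(self, shape, voxel_size):
        self.shape = tuple(int(s) for s in shape)
        self.vs = float(voxel_size)
        self.protein = np.zeros(self.shape, np.float32)
        self.labels = np.zeros(self.shape, np.int32)
        self.rows: list[dict] = []

    def coords_nm(self, idx):
        return tuple((np.asarray(i) + 0.5) * self.vs for i in idx)

    def add_row(self, label, klass, comp):
        self.rows.append({"label": int(label), "klass": klass,
                          "compartment": int(comp)})

    def paint_cylinder(self, p0, p1, radius, value=1.0, extend=0.0):
        """Set protein density inside a capsule around segment p0->p1 (nm)."""
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        axis = p1 - p0
        norm = np.linalg.norm(axis)
        if norm > 0 and extend > 0:
            u = axis / norm
            p0 = p0 - u * extend
            p1 = p1 + u * extend
            axis = p1 - p0
            norm = np.linalg.norm(axis)
        lo = np.minimum(p0, p1) - radius - self.vs
        hi = np.maximum(p0, p1) + radius + self.vs
        sl, grids = self._crop(lo, hi)
        if sl is None:
            return
        pts = np.stack(grids, axis=-1)  # (..., 3) voxel centers in nm
        if norm < 1e-9:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip((pts - p0) @ axis / (norm * norm), 0.0, 1.0)
            proj = p0 + t[..., None] * axis
            dist = np.linalg.norm(pts - proj, axis=-1)
        mask = dist <= radius
        region = self.protein[sl]
        region[mask] = np.maximum(region[mask], value)

    def _crop(self, lo_nm, hi_nm):
        lo = np.maximum(np.floor(np.asarray(lo_nm) / self.vs).astype(int), 0)
        hi = np.minimum(np.ceil(np.asarray(hi_nm) / self.vs).astype(int) + 1,
                        self.shape)
        if np.any(lo >= hi):
            return None, None
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        grids = np.meshgrid(*[(np.arange(a, b) + 0.5) * self.vs
                              for a, b in zip(lo, hi)], indexing="ij")
        return sl, grids

    def spheroid_masks(self, center, semi, rot, shell):
        """Return (crop slice, full mask, lumen mask) of a spheroid."""
        rb = float(np.max(semi))
        lo = np.asarray(center) - rb - self.vs
        hi = np.asarray(center) + rb + self.vs
        sl, grids = self._crop(lo, hi)
        if sl is None:
            return None, None, None
        pts = np.stack(grids, axis=-1) - np.asarray(center)
        body = pts @ rot.T  # world -> body
        r2 = np.sum((body / np.asarray(semi)) ** 2, axis=-1)
        full = r2 <= 1.0
        inner_semi = np.maximum(np.asarray(semi) - shell, 0.5)
        r2i = np.sum((body / inner_semi) ** 2, axis=-1)
        lumen = r2i <= 1.0
        return sl, full, lumen


def _perturbed_solid(scene: _Scene, center, semi, rng, amplitude,
                     cap_plane=None):
    """Boolean solid of a spherical-harmonic-perturbed ellipsoid.

    ``cap_plane = (axis_index, sign, plane_nm)`` flattens the solid against
    a plane (used for contact patches): voxels beyond the plane along the
    signed axis are cut.
    """
    center = np.asarray(center, float)
    semi = np.asarray(semi, float)
    # random real spherical-harmonic coefficients up to degree 3
    lm = [(l, m) for l in (2, 3) for m in range(-l, l + 1)]
    coeffs = rng.normal(0.0, 1.0, size=len(lm))
    if coeffs.size:
        coeffs *= amplitude / math.sqrt(len(lm))
    zz, yy, xx = np.meshgrid(
        *[(np.arange(n) + 0.5) * scene.vs for n in scene.shape], indexing="ij")
    u = np.stack([(zz - center[0]) / semi[0], (yy - center[1]) / semi[1],
                  (xx - center[2]) / semi[2]], axis=-1)
    rho = np.linalg.norm(u, axis=-1)
    solid = rho <= 1.0 - 3.0 * amplitude  # certainly inside
    band = (rho > 1.0 - 3.0 * amplitude) & (rho < 1.0 + 3.0 * amplitude)
    if np.any(band) and amplitude > 0:
        ub = u[band]
        rb = np.linalg.norm(ub, axis=-1)
        theta = np.arccos(np.clip(ub[:, 0] / np.maximum(rb, 1e-12), -1, 1))
        phi = np.arctan2(ub[:, 1], ub[:, 2])
        eps = np.zeros(rb.shape)
        for (l, m), c in zip(lm, coeffs):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                ylm = math.sqrt(2) * (-1) ** m * y.real
            elif m < 0:
                ylm = math.sqrt(2) * (-1) ** m * y.imag
            else:
                ylm = y.real
            eps += c * ylm
        solid[band] = rb <= 1.0 + eps
    elif np.any(band):
        solid[band] = rho[band] <= 1.0
    if cap_plane is not None:
        ax, sign, plane = cap_plane
        coord = (zz, yy, xx)[ax]
        solid &= (coord * sign) <= (plane * sign)
    return solid


def _populate_compartment(scene: _Scene, solid: np.ndarray, comp: int,
                          params: SynthParams, rng: np.random.Generator,
                          gt: GroundTruth,
                          az_spec: tuple | None = None) -> None:
    """Fill one compartment: membrane shell, AZ patch, cytoplasm, vesicles,
    filaments.  ``az_spec = (center_nm, direction, cos_alpha)`` carves an
    angular-cap active-zone patch out of the membrane; tether placement is
    then referenced to the AZ instead of the whole membrane."""
    vs = scene.vs
    t_vox = params.membrane_thickness
    edt_in = ndimage.distance_transform_edt(solid, sampling=vs)
    mem = solid & (edt_in <= t_vox)
    interior = edt_in > t_vox
    if not np.any(mem):
        raise SynthesisError("compartment too small to form a membrane shell")

    scene.labels[mem] = membrane_label(comp)
    scene.labels[interior] = cytoplasm_label(comp)
    scene.protein[mem] = 1.0
    scene.add_row(membrane_label(comp), "membrane", comp)
    scene.add_row(cytoplasm_label(comp), "cytoplasm", comp)

    az_mask = None
    if az_spec is not None:
        az_center, az_dir, cos_alpha = az_spec
        mem_idx = np.argwhere(mem)
        pos = (mem_idx + 0.5) * vs - np.asarray(az_center)
        r = np.linalg.norm(pos, axis=1)
        cosang = pos @ np.asarray(az_dir) / np.maximum(r, 1e-9)
        sel = mem_idx[cosang >= cos_alpha]
        if len(sel):
            az_mask = np.zeros(scene.shape, bool)
            az_mask[tuple(sel.T)] = True
            scene.labels[az_mask] = az_label(comp)
            scene.add_row(az_label(comp), "AZ_membrane", comp)

    interior_um3 = float(interior.sum()) * vs ** 3 * 1e-9
    gt.compartments[comp] = {
        "population": params.population,
        "interior_volume_um3": interior_um3,
        "membrane_thickness_nm": params.membrane_thickness,
        "az_voxels": int(az_mask.sum()) if az_mask is not None else 0,
    }
    if params.vesicle_count is not None:
        n_ves = int(params.vesicle_count)
    else:
        n_ves = int(round(params.vesicle_density * interior_um3))
    if n_ves == 0:
        return

    # distance to the whole membrane (for the non-crossing constraint) and
    # to the tether reference (AZ patch where present, else whole membrane)
    dist_mem = ndimage.distance_transform_edt(~mem, sampling=vs)
    ref = az_mask if az_mask is not None else mem
    dist_ref, nearest = ndimage.distance_transform_edt(
        ~ref, sampling=vs, return_indices=True)

    # candidate center voxels, uniform over the interior
    cand = np.argwhere(interior)
    if cand.size == 0:
        raise SynthesisError("no interior voxels available for vesicles")

    placed: list[PlacedVesicle] = []
    centers = np.zeros((0, 3))
    radii = np.zeros(0)

    def fits(c, rb, rot, semi, skip=None, min_gap=None):
        """Exact membrane-crossing test (voxel level) plus bounding-sphere
        vesicle separation; returns (ok, center distance to membrane)."""
        if min_gap is None:
            min_gap = max(params.placement_min_gap, vs)
        iz, iy, ix = (int(round(c[0] / vs - 0.5)), int(round(c[1] / vs - 0.5)),
                      int(round(c[2] / vs - 0.5)))
        iz = np.clip(iz, 0, scene.shape[0] - 1)
        iy = np.clip(iy, 0, scene.shape[1] - 1)
        ix = np.clip(ix, 0, scene.shape[2] - 1)
        if not interior[iz, iy, ix]:
            return False, 0.0
        gap = float(dist_mem[iz, iy, ix]) - rb
        if len(centers):
            d = np.linalg.norm(centers - c, axis=1) - radii - rb
            if skip is not None:
                d[skip] = np.inf
            if np.min(d) <= vs:  # bounding-sphere separation > one voxel
                return False, gap
        if gap < min_gap:  # near the membrane: exact voxel check, with margin
            sl, full, _ = scene.spheroid_masks(
                c, np.asarray(semi) + max(min_gap, vs), rot, 0.0)
            if sl is None or np.any(full & ~interior[sl]):
                return False, gap
        return True, gap

    # each vesicle's geometry is drawn once, then positions are retried for
    # that fixed vesicle: redrawing the size per attempt would size-bias
    # acceptance toward small vesicles and shift the diameter distribution
    max_tries_each = 400
    for k in range(n_ves):
        ok = False
        # a handful of geometry redraws so that a tail-sampled vesicle too
        # large for the compartment does not abort the scene; size bias from
        # this is confined to otherwise-unplaceable giants
        for redraw in range(5):
            d = float(np.clip(rng.normal(params.vesicle_diameter_mean,
                                         params.vesicle_diameter_sd),
                              params.vesicle_diameter_min,
                              params.vesicle_diameter_max))
            w = float(np.clip(rng.normal(params.wadell_mean, params.wadell_sd),
                              0.62, 1.0))
            q = axis_ratio_for_wadell(w)
            r_eq = d / 2.0
            a = r_eq * q ** (-1 / 3)
            semi = np.array([a, a, a * q])
            rot = _random_rotation(rng)
            for attempt in range(max_tries_each):
                idx = cand[rng.integers(len(cand))]
                c = (idx + 0.5) * vs
                ok, _ = fits(c, float(semi.max()), rot, semi)
                if ok:
                    break
            if ok:
                break
        if not ok:
            raise SynthesisError(
                f"vesicle placement infeasible: placed {len(placed)}/{n_ves} "
                f"(no position found in {max_tries_each} tries x 5 redraws; "
                "density target too high for the compartment volume)")
        rec = PlacedVesicle(
            label=vesicle_label(comp, len(placed)), compartment=comp,
            center=tuple(c), semi_axes=tuple(semi), rotation=rot.tolist(),
            diameter=d, wadell=prolate_wadell(q), membrane_gap=math.nan)
        placed.append(rec)
        centers = np.vstack([centers, c])
        radii = np.append(radii, semi.max())

    # --- tether assignment: Bernoulli(tethered_fraction) among proximal ---
    # gaps are measured against the reference (AZ where present), matching
    # the downstream definition of proximal vesicles
    ref_vox = np.argwhere(ref)
    centroid = cand.mean(axis=0) * vs

    def ref_gap(rec, i):
        c = np.asarray(rec.center)
        iz, iy, ix = [int(np.clip(round(v / vs - 0.5), 0, s - 1))
                      for v, s in zip(c, scene.shape)]
        anchor = (nearest[:, iz, iy, ix] + 0.5) * vs
        u = anchor - c
        un = np.linalg.norm(u)
        if un < 1e-9:
            return 0.0
        r_dir = _radial_extent(np.asarray(rec.rotation),
                               np.asarray(rec.semi_axes), u / un)
        return float(dist_ref[iz, iy, ix]) - r_dir

    for i, rec in enumerate(placed):
        rec.membrane_gap = ref_gap(rec, i)
    for i, rec in enumerate(placed):
        rb = radii[i]
        rot = np.asarray(rec.rotation)
        semi = np.asarray(rec.semi_axes)
        if rec.membrane_gap < params.proximal_cutoff and \
                rng.random() < params.tethered_fraction:
            # reposition against a random reference anchor: small
            # half-normal gap (oblique mode) or a gap drawn from the length
            # distribution (radial mode, where length == gap)
            for _ in range(16):
                if params.tether_obliquity:
                    g = abs(rng.normal(0.0, params.tethered_gap_scale))
                    lo = 1.5 * vs
                else:
                    g = rng.normal(params.tether_length_mean,
                                   params.tether_length_sd)
                    # radial mode: length == gap, so respect the placement
                    # floor — no sub-resolution bridges
                    lo = max(1.5 * vs, params.placement_min_gap)
                g = float(np.clip(g, lo, params.proximal_cutoff - 1.0))
                anchor = (ref_vox[rng.integers(len(ref_vox))] + 0.5) * vs
                n = centroid - anchor
                nn_ = np.linalg.norm(n)
                if nn_ < 1e-9:
                    continue
                n /= nn_
                r_dir = _radial_extent(rot, semi, -n)
                # the centroid ray is oblique to the membrane normal on
                # aspherical membranes; correct the walk distance against
                # the distance field so the realized gap matches g
                t = g + r_dir
                for _ in range(4):
                    pos = anchor + n * t
                    jz, jy, jx = [int(np.clip(round(v / vs - 0.5), 0, s - 1))
                                  for v, s in zip(pos, scene.shape)]
                    m = float(dist_ref[jz, jy, jx]) - r_dir
                    if abs(m - g) <= 0.5 * vs:
                        break
                    t += g - m
                newc = anchor + n * t
                ok, _ = fits(newc, rb, rot, semi, skip=i, min_gap=vs)
                if ok:
                    rec.center = tuple(newc)
                    centers[i] = newc
                    rec.membrane_gap = ref_gap(rec, i)
                    break
            rec.tethered = True

    # --- rasterize vesicles ---
    for rec in placed:
        rot = np.asarray(rec.rotation)
        sl, full, lumen = scene.spheroid_masks(rec.center, rec.semi_axes, rot,
                                               params.membrane_thickness)
        if sl is None:
            continue
        region_ok = scene.labels[sl] == cytoplasm_label(comp)
        vox = full & region_ok
        scene.labels[sl][vox] = rec.label
        shell = vox & ~lumen
        pr = scene.protein[sl]
        pr[shell] = 1.0
        scene.add_row(rec.label, "vesicle", comp)

    # --- tethers: 1..3 oblique cylinders per tethered vesicle ---
    for i, rec in enumerate(placed):
        if not rec.tethered:
            continue
        c = np.asarray(rec.center)
        rot = np.asarray(rec.rotation)
        semi = np.asarray(rec.semi_axes)
        iz, iy, ix = [int(np.clip(round(v / vs - 0.5), 0, s - 1))
                      for v, s in zip(c, scene.shape)]
        mem_pt = (nearest[:, iz, iy, ix] + 0.5) * vs
        u = mem_pt - c
        un = np.linalg.norm(u)
        if un < 1e-9:
            continue
        u /= un
        p_ves = c + u * _radial_extent(rot, semi, u)
        gap = rec.membrane_gap
        if params.max_tethers > 1:
            mu = max(1.0, 3.0 - 2.0 * gap / 25.0)  # primed vesicles carry ~3
            n_teth = min(max(1, int(rng.poisson(mu))), params.max_tethers)
        else:
            n_teth = 1
        for _ in range(n_teth):
            if params.tether_obliquity:
                length = float(np.clip(rng.normal(params.tether_length_mean,
                                                  params.tether_length_sd),
                                       max(gap + vs, 4.0), 45.0))
            else:
                length = gap
            lateral = math.sqrt(max(length ** 2 - gap ** 2, 0.0))
            tvec = rng.normal(size=3)
            tvec -= u * (tvec @ u)
            tn = np.linalg.norm(tvec)
            tvec = tvec / tn if tn > 1e-9 else np.zeros(3)
            target = mem_pt + tvec * lateral
            jz, jy, jx = [int(np.clip(round(v / vs - 0.5), 0, s - 1))
                          for v, s in zip(target, scene.shape)]
            p_mem = (nearest[:, jz, jy, jx] + 0.5) * vs
            true_len = float(np.linalg.norm(p_mem - p_ves))
            scene.paint_cylinder(p_ves, p_mem, params.tether_radius,
                                 extend=1.5 * vs)
            gt.filaments.append(PlacedFilament(
                kind="tether", partners=(membrane_label(comp), rec.label),
                p0=tuple(p_mem), p1=tuple(p_ves), length=true_len,
                radius=params.tether_radius))
            rec.n_tethers += 1

    # --- connectors: greedy cover toward the connected-fraction target ---
    target_connected = int(round(params.connected_fraction * len(placed)))
    if target_connected >= 2 and len(placed) >= 2:
        pairs = []
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                gap_ij = (np.linalg.norm(centers[i] - centers[j])
                          - radii[i] - radii[j])
                if max(vs, params.placement_min_gap) < gap_ij \
                        < params.connector_max_gap:
                    pairs.append((i, j))
        order = rng.permutation(len(pairs))
        connected: set[int] = set()
        for k in order:
            i, j = pairs[k]
            if len(connected) >= target_connected:
                break
            if i in connected and j in connected:
                continue
            ci, cj = centers[i], centers[j]
            u = cj - ci
            u /= np.linalg.norm(u)
            pi = ci + u * _radial_extent(np.asarray(placed[i].rotation),
                                         np.asarray(placed[i].semi_axes), u)
            pj = cj - u * _radial_extent(np.asarray(placed[j].rotation),
                                         np.asarray(placed[j].semi_axes), u)
            length = float(np.linalg.norm(pj - pi))
            scene.paint_cylinder(pi, pj, params.tether_radius, extend=1.5 * vs)
            gt.filaments.append(PlacedFilament(
                kind="connector",
                partners=(placed[i].label, placed[j].label),
                p0=tuple(pi), p1=tuple(pj), length=length,
                radius=params.tether_radius))
            placed[i].n_connectors += 1
            placed[j].n_connectors += 1
            connected.update((i, j))

    gt.vesicles.extend(placed)


def _render(scene: _Scene, params: SynthParams,
            noise_rng: np.random.Generator) -> np.ndarray:
    """Turn the protein-occupancy grid into a noisy density map.

    Background (ice) sits at grey level 1; protein subtracts (dark, the
    cryo-ET convention) or adds (bright) its occupancy.
    """
    sign = -1.0 if params.contrast == "dark" else 1.0
    density = 1.0 + sign * scene.protein.astype(np.float32)
    if params.missing_wedge:
        density = ndimage.gaussian_filter1d(
            density, sigma=params.missing_wedge_sigma, axis=0)
    if params.noise_sd > 0:
        density = density + noise_rng.normal(
            0.0, params.noise_sd, size=scene.shape).astype(np.float32)
    return density


def _finish(scene: _Scene, params: SynthParams, gt: GroundTruth,
            noise_rng) -> tuple[DensityVolume, Segmentation, GroundTruth]:
    density = _render(scene, params, noise_rng)
    vol = DensityVolume(density, (scene.vs,) * 3)
    table = pd.DataFrame(scene.rows, columns=["label", "klass", "compartment"])
    seg = Segmentation(scene.labels, (scene.vs,) * 3, table)
    seg.validate()
    return vol, seg, gt


def generate_synaptosome(params: SynthParams, seed: int
                         ) -> tuple[DensityVolume, Segmentation, GroundTruth]:
    """Generate one synthetic synaptosome scene.

    Returns the density volume, the ground-truth segmentation and the full
    generative record.  Identical (params, seed) give byte-identical
    outputs.
    """
    params.validate()
    ss = np.random.SeedSequence(seed)
    place_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    dia = float(np.clip(place_rng.normal(params.synaptosome_diameter_mean,
                                         params.synaptosome_diameter_sd),
                        max(4 * params.vesicle_diameter_mean, 120.0), None))
    r0 = dia / 2.0
    ratios = place_rng.uniform(0.75, 1.0, size=2)
    semi = np.array([r0 * ratios[0], r0 * ratios[1], r0])  # x is the long axis
    vs = params.voxel_size
    extent = 2 * semi * (1 + 3 * params.membrane_perturbation) + 2 * params.margin
    shape = np.ceil(extent / vs).astype(int)
    scene = _Scene(shape, vs)
    center = (shape * vs) / 2.0

    gt = GroundTruth(seed=int(seed), params=[params.to_dict()])
    solid = _perturbed_solid(scene, center, semi, place_rng,
                             params.membrane_perturbation)
    az_spec = None
    if params.az_area_um2:
        u = place_rng.normal(size=3)
        u /= np.linalg.norm(u)
        r_eff = float(np.mean(semi))
        cos_a = 1.0 - params.az_area_um2 * 1e6 / (2 * math.pi * r_eff ** 2)
        az_spec = (center, u, float(np.clip(cos_a, -1.0, 0.9995)))
    _populate_compartment(scene, solid, 1, params, place_rng, gt,
                          az_spec=az_spec)
    gt.compartments[1]["true_max_extension_nm"] = float(2 * semi.max())
    return _finish(scene, params, gt, noise_rng)


def generate_hub(paramsA: SynthParams, paramsB: SynthParams,
                 cleft_width: float, seed: int,
                 patch_area_um2: float = 0.06,
                 psd: bool = True,
                 psd_depth_range: tuple[float, float] = (10.0, 25.0),
                 midline_density: float = 0.0,
                 ) -> tuple[DensityVolume, Segmentation, GroundTruth]:
    """Generate two apposed compartments separated by a planar cleft.

    The facing membranes are flattened against parallel planes over a disk
    patch of ``patch_area_um2`` so they are locally parallel at separation
    ``cleft_width`` (nm).  Compartment 1 follows ``paramsA`` (presynaptic
    side; its facing membrane is labelled as AZ), compartment 2 follows
    ``paramsB`` (e.g. a post-synaptic element with ``vesicle_count=0``).
    With ``psd=True`` a density slab is placed 10-25 nm beneath the facing
    membrane of compartment 2 and labelled PSD.
    """
    paramsA.validate()
    paramsB.validate()
    if cleft_width <= 0:
        raise SynthesisError("cleft width must be positive")
    ss = np.random.SeedSequence(seed)
    place_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    vs = paramsA.voxel_size

    patch_r = math.sqrt(patch_area_um2 * 1e6 / math.pi)  # nm
    rA = max(paramsA.synaptosome_diameter_mean / 2.0, patch_r * 1.4)
    rB = max(paramsB.synaptosome_diameter_mean / 2.0, patch_r * 1.4)
    hA = math.sqrt(max(rA ** 2 - patch_r ** 2, 0.0))
    hB = math.sqrt(max(rB ** 2 - patch_r ** 2, 0.0))

    margin = paramsA.margin
    ext_y = (rA + hA) + cleft_width + (rB + hB) + 2 * margin
    ext_zx = 2 * max(rA, rB) + 2 * margin
    shape = np.ceil(np.array([ext_zx, ext_y, ext_zx]) / vs).astype(int)
    scene = _Scene(shape, vs)

    z0 = shape[0] * vs / 2.0
    x0 = shape[2] * vs / 2.0
    capA_y = margin + 2 * rA - (rA - hA)  # plane of A's flattened face
    cA = np.array([z0, capA_y - hA, x0])
    capB_y = capA_y + cleft_width
    cB = np.array([z0, capB_y + hB, x0])
    if capB_y <= capA_y:
        raise SynthesisError("compartments overlap: cleft width too small")

    gt = GroundTruth(seed=int(seed),
                     params=[paramsA.to_dict(), paramsB.to_dict()])
    solidA = _perturbed_solid(scene, cA, np.full(3, rA), place_rng, 0.0,
                              cap_plane=(1, +1, capA_y))
    solidB = _perturbed_solid(scene, cB, np.full(3, rB), place_rng, 0.0,
                              cap_plane=(1, -1, capB_y))
    if np.any(solidA & solidB):
        raise SynthesisError("compartments overlap")
    _populate_compartment(scene, solidA, 1, paramsA, place_rng, gt)
    _populate_compartment(scene, solidB, 2, paramsB, place_rng, gt)

    # AZ: facing membrane of compartment 1 within the patch footprint
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5) * vs for n in shape],
                             indexing="ij")
    lateral = np.sqrt((zz - z0) ** 2 + (xx - x0) ** 2)
    in_patch = lateral <= patch_r
    memA = scene.labels == membrane_label(1)
    az = memA & in_patch & (yy > capA_y - 3 * paramsA.membrane_thickness)
    scene.labels[az] = az_label(1)
    scene.add_row(az_label(1), "AZ_membrane", 1)

    if psd:
        lo, hi = psd_depth_range
        memB_face = capB_y + paramsB.membrane_thickness
        slab = ((scene.labels == cytoplasm_label(2)) & in_patch
                & (yy >= memB_face + lo) & (yy < memB_face + hi))
        scene.labels[slab] = psd_label(2)
        scene.protein[slab] = np.maximum(scene.protein[slab], 0.8)
        scene.add_row(psd_label(2), "PSD", 2)
        gt.psd = {"depth_range_nm": [float(lo), float(hi)],
                  "compartment": 2}

    if midline_density > 0:
        mid_y = (capA_y + capB_y) / 2.0
        mid = ((scene.labels == 0) & in_patch
               & (np.abs(yy - mid_y) <= 2.0))
        scene.protein[mid] = np.maximum(scene.protein[mid],
                                        float(midline_density))

    gt.contact = {
        "cleft_width_nm": float(cleft_width),
        "patch_radius_nm": float(patch_r),
        "patch_area_um2": float(patch_area_um2),
        "axis": "y",
        "plane_A_nm": float(capA_y),
        "plane_B_nm": float(capB_y),
    }
    return _finish(scene, paramsA, gt, noise_rng)


# ---------------------------------------------------------------------------
# Config plumbing
# ---------------------------------------------------------------------------

def params_from_config(path: str | Path) -> SynthParams:
    """Load :class:`SynthParams` from a flat YAML key-value file."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    preset = cfg.pop("preset", None)
    if preset == "DA":
        return SynthParams.da(**cfg)
    if preset in (None, "GLU"):
        return SynthParams.glu(**cfg)
    raise SynthesisError(f"unknown preset {preset!r}; use GLU or DA")
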