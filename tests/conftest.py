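"""Shared fixtures: scaled-down synthetic scenes and hand-built voxel scenes.

Generated scenes use small synaptosomes (~200-240 nm) at 2 nm voxels so
the full pipeline stays fast; the vesicle-level parameters (diameters,
sphericity, tether statistics) are the population defaults.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from synaptomet.volio import DensityVolume, Segmentation
from synaptomet.synth import SynthParams, generate_synaptosome, generate_hub


def small_glu(**over) -> SynthParams:
    """GLU-parameter preset on a scaled-down synaptosome."""
    base = dict(synaptosome_diameter_mean=220.0, synaptosome_diameter_sd=20.0,
                voxel_size=2.0, margin=24.0, az_area_um2=0.006)
    base.update(over)
    return SynthParams.glu(**base)


def fixture_params(**over) -> SynthParams:
    """Noise-free single-radial-tether scenes for detection fixtures.

    Untethered vesicles keep at least a 6 nm membrane gap so no scene
    contains sub-resolution contacts that are indistinguishable from
    rendered bridges, and vesicles are spherical so the rendered radial
    tether length is the unique edge-to-edge distance."""
    base = dict(noise_sd=0.0, tether_obliquity=False, max_tethers=1,
                placement_min_gap=6.0, wadell_mean=1.0, wadell_sd=0.0,
                az_area_um2=None)
    base.update(over)
    return small_glu(**base)


@pytest.fixture(scope="session")
def glu_scene():
    """One noisy default-parameter GLU scene plus its ground truth."""
    vol, seg, gt = generate_synaptosome(small_glu(), seed=11)
    return vol, seg, gt


@pytest.fixture(scope="session")
def clean_scene():
    """One noise-free fixture scene (radial single tethers)."""
    vol, seg, gt = generate_synaptosome(fixture_params(), seed=3)
    return vol, seg, gt


@pytest.fixture(scope="session")
def hub_scene():
    """Two apposed compartments, 31.8 nm cleft, PSD on."""
    pa = SynthParams.glu(synaptosome_diameter_mean=200, synaptosome_diameter_sd=1,
                         voxel_size=2.5, margin=30.0, vesicle_count=3,
                         az_area_um2=None, noise_sd=0.05)
    pb = SynthParams.glu(synaptosome_diameter_mean=180, synaptosome_diameter_sd=1,
                         voxel_size=2.5, margin=30.0, vesicle_count=0,
                         az_area_um2=None, noise_sd=0.05, population="PSE")
    return generate_hub(pa, pb, cleft_width=31.8, seed=7,
                        patch_area_um2=0.02, psd=True)


# ---------------------------------------------------------------------------
# Hand-built voxel scenes
# ---------------------------------------------------------------------------

class SceneBuilder:
    """Minimal manual scene: labels + protein-occupancy rendering."""

    def __init__(self, shape=(64, 64, 64), vs=1.0):
        self.shape = tuple(shape)
        self.vs = float(vs)
        self.labels = np.zeros(self.shape, np.int32)
        self.protein = np.zeros(self.shape, np.float32)
        self.rows = []

    def grid_nm(self):
        return np.meshgrid(*[(np.arange(n) + 0.5) * self.vs
                             for n in self.shape], indexing="ij")

    def add(self, mask, label, klass, comp=1, protein=None):
        self.labels[mask] = label
        if protein is not None:
            self.protein[mask] = np.maximum(self.protein[mask], protein)
        if not any(r["label"] == label for r in self.rows):
            self.rows.append({"label": label, "klass": klass,
                              "compartment": comp})

    def paint_segments(self, points, radius, value=1.0):
        """Protein capsule chain through a list of nm points."""
        zz, yy, xx = self.grid_nm()
        pts = np.stack([zz, yy, xx], axis=-1)
        for p0, p1 in zip(points[:-1], points[1:]):
            p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
            axis = p1 - p0
            L2 = float(axis @ axis)
            if L2 < 1e-12:
                d = np.linalg.norm(pts - p0, axis=-1)
            else:
                t = np.clip((pts - p0) @ axis / L2, 0, 1)
                d = np.linalg.norm(pts - (p0 + t[..., None] * axis), axis=-1)
            m = d <= radius
            self.protein[m] = np.maximum(self.protein[m], value)

    def build(self, noise_sd=0.0, seed=0, contrast="dark"):
        sign = -1.0 if contrast == "dark" else 1.0
        density = 1.0 + sign * self.protein
        if noise_sd > 0:
            density = density + np.random.default_rng(seed).normal(
                0, noise_sd, self.shape).astype(np.float32)
        vol = DensityVolume(density.astype(np.float32), (self.vs,) * 3)
        seg = Segmentation(self.labels, (self.vs,) * 3,
                           pd.DataFrame(self.rows,
                                        columns=["label", "klass",
                                                 "compartment"]))
        return vol, seg


def bridge_scene(gap=15.0, kind="tether", with_bridge=True, arc_radius=None,
                 vs=1.0, shape=(64, 64, 64)):
    """Flat membrane + vesicle(s) + optional bridging filament density.

    ``kind='tether'`` bridges vesicle to membrane across ``gap`` nm;
    ``kind='connector'`` bridges two vesicles.  ``arc_radius`` replaces the
    straight tether by a quarter-circle arc of that radius whose endpoint
    chord is arc_radius*sqrt(2).
    """
    b = SceneBuilder(shape, vs)
    zz, yy, xx = b.grid_nm()
    nz, ny, nx = b.shape
    mem = (zz >= 4) & (zz < 9)
    b.add(mem, 1001, "membrane", protein=1.0)
    cyto = zz >= 9
    b.add(cyto, 1002, "cytoplasm")
    rv = 12.0
    if kind == "tether" and arc_radius is None:
        c = (9.0 + gap + rv, ny * vs / 2, nx * vs / 2)
        ves = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= rv ** 2
        b.add(ves & cyto, 1010, "vesicle", protein=1.0)
        if with_bridge:
            b.paint_segments([(7.0, c[1], c[2]), (9.0 + gap + 2.0, c[1], c[2])],
                             radius=1.6)
    elif kind == "tether" and arc_radius is not None:
        r = float(arc_radius)
        yc = ny * vs / 2
        xc = nx * vs / 2
        zc = 9.0 + r
        # quarter arc from the membrane anchor (9, yc, xc) to (zc, yc - r, xc)
        thetas = np.linspace(math.pi, math.pi / 2, 41)
        pts = [(zc + r * math.cos(t), yc + r * math.sin(t) - r, xc)
               for t in thetas]
        c = (zc, yc - r - rv, xc)
        ves = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= rv ** 2
        b.add(ves & cyto, 1010, "vesicle", protein=1.0)
        if with_bridge:
            b.paint_segments([(7.0, pts[0][1], xc)] + pts
                             + [(c[0], c[1] + rv - 2.0, xc)], radius=1.6)
    else:  # connector between two vesicles above the membrane
        zc = 30.0
        y1 = ny * vs / 2 - rv - gap / 2
        y2 = ny * vs / 2 + rv + gap / 2
        v1 = ((zz - zc) ** 2 + (yy - y1) ** 2 + (xx - nx * vs / 2) ** 2) <= rv ** 2
        v2 = ((zz - zc) ** 2 + (yy - y2) ** 2 + (xx - nx * vs / 2) ** 2) <= rv ** 2
        b.add(v1 & cyto, 1010, "vesicle", protein=1.0)
        b.add(v2 & cyto, 1011, "vesicle", protein=1.0)
        if with_bridge:
            b.paint_segments([(zc, y1 + rv - 2.0, nx * vs / 2),
                              (zc, y2 - rv + 2.0, nx * vs / 2)], radius=1.6)
    return b


def parallel_planes_seg(sep_nm, vs=1.0, shape=(40, 64, 40), thickness=5.0,
                        tilt=0.0):
    """Two slab membranes ``sep_nm`` apart (edge to edge) along y.

    ``tilt`` adds a linear gradient of the separation along x (total extra
    separation across the field), for the tilted-plane oracle.
    """
    b = SceneBuilder(shape, vs)
    zz, yy, xx = b.grid_nm()
    ny = shape[1] * vs
    y0 = ny / 2 - sep_nm / 2
    memA = (yy < y0) & (yy >= y0 - thickness)
    b.add(memA, 1001, "membrane", comp=1, protein=1.0)
    b.add(yy < y0 - thickness, 1002, "cytoplasm", comp=1)
    off = tilt * (xx / (shape[2] * vs))
    y1 = ny / 2 + sep_nm / 2 + off
    memB = (yy >= y1) & (yy < y1 + thickness)
    b.add(memB, 2001, "membrane", comp=2, protein=1.0)
    b.add(yy >= y1 + thickness, 2002, "cytoplasm", comp=2)
    return b
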