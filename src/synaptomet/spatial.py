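"""Along-membrane distances and the random null on a circle.

Tethered vesicles may cluster on the plasma membrane.  To test that, the
mean nearest-neighbour arc distance between tether anchor points is
compared with the distance expected between random points when the
synaptosome projection is approximated by a circle of radius R = D/2
(D the mean maximal diameter): the arc distance between two uniform
random points on the circle has mean pi*R/2 — half the length of a half
circle — and variance pi^2 R^2 / 12.

Arc distances on segmented membranes are shortest paths on the membrane
voxel graph (26-connectivity, Euclidean step weights); the projected
decomposition d = sqrt(d_xy^2 + d_z^2) used for per-plane measurements is
also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .volio import Segmentation
from .filaments import Filament


@dataclass
class NullModel:
    """Analytic circle null for arc distances between random points."""

    diameter: float  # D: mean maximal synaptosome diameter (nm)
    seed: int | None = None

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def mean(self) -> float:
        return math.pi * self.radius / 2.0

    @property
    def sd(self) -> float:
        return self.radius * math.pi / math.sqrt(12.0)


@dataclass
class ArcDistance:
    """Projected arc-distance decomposition."""

    d_xy: float  # in-plane arc component (nm)
    d_z: float  # inter-plane component (nm)

    @property
    def d(self) -> float:
        return arc_distance(self.d_xy, self.d_z)


def arc_distance(d_xy: float, d_z: float) -> float:
    """Combine in-plane arc and inter-plane components: sqrt(dxy^2 + dz^2)."""
    if d_xy < 0 or d_z < 0:
        raise ValueError(f"components must be >= 0, got ({d_xy}, {d_z})")
    return math.hypot(d_xy, d_z)


def analytic_null(radius: float) -> tuple[float, float]:
    """Mean and sd (nm) of the arc distance between random points on a
    circle of radius R: mean = pi R / 2, sd = R pi / sqrt(12)."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return math.pi * radius / 2.0, radius * math.pi / math.sqrt(12.0)


def mc_null(radius: float, n_pairs: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo twin of :func:`analytic_null`.

    Samples ``n_pairs`` independent pairs of angles uniform on [0, 2 pi);
    the arc distance is R * min(|dtheta|, 2 pi - |dtheta|).  Deterministic
    per seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2 * math.pi, size=(int(n_pairs), 2))
    dt = np.abs(theta[:, 0] - theta[:, 1])
    arc = radius * np.minimum(dt, 2 * math.pi - dt)
    return float(arc.mean()), float(arc.std())


# ---------------------------------------------------------------------------
# Surface-graph geodesics
# ---------------------------------------------------------------------------

class MembraneGraph:
    """Shortest-path machinery on a membrane voxel set.

    Nodes are membrane voxels, edges join 26-neighbours with Euclidean
    step weights in nm.  Raises if the anchors fall on disconnected
    membrane components.
    """

    def __init__(self, seg: Segmentation, compartment: int | None = None):
        rows = seg.table
        if compartment is not None:
            rows = rows[rows["compartment"] == compartment]
        ids = rows[rows["klass"].isin(["membrane", "AZ_membrane"])]["label"]
        mask = np.isin(seg.labels, list(ids))
        if not np.any(mask):
            raise ValueError("no membrane voxels for the arc-distance graph")
        self.vox = np.argwhere(mask)
        self.vs = np.broadcast_to(np.asarray(seg.voxel_size, float), (3,))
        self._index = {tuple(v): i for i, v in enumerate(self.vox)}
        n = len(self.vox)
        offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
        rows_, cols, w = [], [], []
        for i, v in enumerate(self.vox):
            for off in offsets:
                j = self._index.get((v[0] + off[0], v[1] + off[1],
                                     v[2] + off[2]))
                if j is not None and j > i:
                    rows_.append(i)
                    cols.append(j)
                    w.append(math.sqrt(sum((o * s) ** 2
                                           for o, s in zip(off, self.vs))))
        self.graph = coo_matrix((w, (rows_, cols)), shape=(n, n)).tocsr()

    def snap(self, point_nm) -> int:
        """Index of the membrane voxel nearest a point (nm)."""
        p = np.asarray(point_nm, float)
        d2 = np.sum(((self.vox + 0.5) * self.vs - p) ** 2, axis=1)
        return int(np.argmin(d2))

    def distances_from(self, node: int) -> np.ndarray:
        return dijkstra(self.graph, directed=False, indices=node)

    def arc_between(self, node_a: int, node_b: int) -> float:
        d = self.distances_from(node_a)[node_b]
        if not math.isfinite(d):
            raise ValueError(
                "anchors lie on disconnected membrane components")
        return float(d)


def membrane_arc_distance(seg: Segmentation, anchor_a, anchor_b,
                          compartment: int | None = None,
                          graph: MembraneGraph | None = None
                          ) -> tuple[float, ArcDistance]:
    """Shortest on-membrane path length (nm) between two anchors.

    Anchors are points in nm, snapped to the nearest membrane voxel.
    Also returns the projected decomposition: d_z is the inter-plane
    separation of the anchors and d_xy the in-plane length of the
    geodesic's projection, combined as sqrt(dxy^2 + dz^2).
    """
    g = graph or MembraneGraph(seg, compartment)
    ia, ib = g.snap(anchor_a), g.snap(anchor_b)
    arc = g.arc_between(ia, ib)
    pa = (g.vox[ia] + 0.5) * g.vs
    pb = (g.vox[ib] + 0.5) * g.vs
    d_z = abs(float(pa[0] - pb[0]))
    d_xy = math.sqrt(max(arc ** 2 - d_z ** 2, 0.0))
    return arc, ArcDistance(d_xy=d_xy, d_z=d_z)


def tether_anchors(filaments: list[Filament], seg: Segmentation) -> np.ndarray:
    """Anchor points (nm) of tethers: centroids of membrane-contact voxels."""
    vs = np.broadcast_to(np.asarray(seg.voxel_size, float), (3,))
    anchors = []
    for f in filaments:
        if f.kind != "tether" or f.branching:
            continue
        mem_partners = [p for p in f.partners if p % 1000 == 1]
        if not mem_partners:
            continue
        contact = f.contacts[mem_partners[0]]
        anchors.append(((np.asarray(contact).mean(axis=0)) + 0.5) * vs)
    return np.asarray(anchors).reshape(-1, 3)


def nn_tether_spacing(filaments: list[Filament], seg: Segmentation,
                      compartment: int | None = None) -> float:
    """Mean nearest-neighbour arc distance (nm) between tether anchors.

    Returns NaN when fewer than two tethers are present (such compartments
    are excluded from multi-tether statistics, not counted as zero).
    """
    anchors = tether_anchors(filaments, seg)
    if len(anchors) < 2:
        return math.nan
    g = MembraneGraph(seg, compartment)
    nodes = [g.snap(a) for a in anchors]
    nn = []
    for i, ni in enumerate(nodes):
        d = g.distances_from(ni)
        others = [d[nj] for j, nj in enumerate(nodes) if j != i]
        nn.append(min(others))
    return float(np.mean(nn))


def spacing_vs_null(filaments: list[Filament], seg: Segmentation,
                    diameter: float, compartment: int | None = None) -> dict:
    """Observed nearest-neighbour tether spacing against the circle null."""
    null = NullModel(diameter)
    observed = nn_tether_spacing(filaments, seg, compartment)
    z = (observed - null.mean) / null.sd if not math.isnan(observed) else math.nan
    return {"nn_mean_nm": observed, "null_mean_nm": null.mean,
            "null_sd_nm": null.sd, "z_score": z}
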