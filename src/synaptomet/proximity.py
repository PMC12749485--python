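"""Membrane-distance fields, layer occupancy, and distance-binned statistics.

The presynaptic cytoplasm (vesicles included) is divided into 1-voxel-thick
layers by Euclidean distance to the reference membrane — either the active
zone membrane or, where no AZ is identifiable (the dopaminergic case), the
whole plasma membrane — and the fraction of each layer occupied by vesicle
voxels is reported.  Distances are edge-to-edge (surface to surface), not
center-based: a vesicle's membrane distance is the minimum of the distance
field over its voxels.  Proximal vesicles are those within 45 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import Segmentation
from .morphometry import VesicleRecord, surface_area

PROXIMAL_CUTOFF_NM = 45.0
DEFAULT_TETHER_BINS_NM = (0.0, 5.0, 10.0, 25.0, 45.0)


class MissingRegionError(ValueError):
    """Requested reference region has no voxels."""


@dataclass
class LayerProfile:
    """Occupancy of one distance layer."""

    layer_index: int
    d_lo: float  # nm, half-open [d_lo, d_hi)
    d_hi: float
    cyto_voxels: int
    vesicle_voxels: int
    occupancy: float  # NaN when the layer is empty (undefined, not 0)
    region: str  # "AZ" | "whole"


def _reference_mask(seg: Segmentation, region: str,
                    compartment: int | None) -> np.ndarray:
    rows = seg.table
    if compartment is not None:
        rows = rows[rows["compartment"] == compartment]
    if region == "AZ":
        ids = rows[rows["klass"] == "AZ_membrane"]["label"]
        if len(ids) == 0:
            raise MissingRegionError(
                "no AZ membrane label in this compartment; no morphologically "
                "identifiable AZ — call with region='whole' to use the whole "
                "plasma membrane as reference")
    elif region == "whole":
        ids = rows[rows["klass"].isin(["membrane", "AZ_membrane"])]["label"]
        if len(ids) == 0:
            raise MissingRegionError("segmentation has no membrane label")
    else:
        raise ValueError(f"region must be 'AZ' or 'whole', got {region!r}")
    return np.isin(seg.labels, list(ids))


def membrane_distance_field(seg: Segmentation, region: str = "whole",
                            compartment: int | None = None) -> np.ndarray:
    """Euclidean distance (nm) from the reference membrane voxels.

    Evaluated everywhere; meaningful over the cytoplasm (vesicle voxels
    included).  The field is 1-Lipschitz per nm by construction.
    """
    ref = _reference_mask(seg, region, compartment)
    return ndimage.distance_transform_edt(~ref, sampling=seg.voxel_size)


def vesicle_membrane_distance(rec: VesicleRecord, field: np.ndarray,
                              seg: Segmentation,
                              cutoff: float = PROXIMAL_CUTOFF_NM
                              ) -> VesicleRecord:
    """Fill a record's minimal edge-to-edge membrane distance (in place).

    The distance is the minimum of the membrane distance field over the
    vesicle's voxels, i.e. from the vesicle surface to the membrane
    surface; the proximal flag is true iff distance < ``cutoff``.
    """
    mask = seg.labels == rec.label
    d = float(field[mask].min()) if np.any(mask) else math.nan
    rec.dist_membrane = d
    rec.proximal = bool(d < cutoff)
    return rec


def annotate_distances(records: list[VesicleRecord], seg: Segmentation,
                       region: str = "whole", compartment: int | None = None,
                       cutoff: float = PROXIMAL_CUTOFF_NM
                       ) -> list[VesicleRecord]:
    """Fill membrane distances for all records against one distance field."""
    field = membrane_distance_field(seg, region, compartment)
    for rec in records:
        vesicle_membrane_distance(rec, field, seg, cutoff)
    return records


def cytoplasm_mask(seg: Segmentation, compartment: int | None = None,
                   exclude_organelles: bool = True) -> np.ndarray:
    """Cytoplasm voxels including vesicles; organelles excluded by default."""
    rows = seg.table
    if compartment is not None:
        rows = rows[rows["compartment"] == compartment]
    keep = ["cytoplasm", "vesicle", "PSD"]
    if not exclude_organelles:
        keep += ["mitochondrion", "multivesicular_body", "large_organelle"]
    ids = rows[rows["klass"].isin(keep)]["label"]
    return np.isin(seg.labels, list(ids))


def layer_occupancy(seg: Segmentation, region: str = "whole",
                    compartment: int | None = None,
                    layer_width: float | None = None,
                    max_distance: float = 250.0,
                    exclude_organelles: bool = True) -> list[LayerProfile]:
    """Per-layer vesicle volume occupancy vs distance to the reference.

    ``layer_width`` defaults to one voxel.  Layers are half-open
    [d, d + w) bands; profiles extend to ``max_distance`` (>= 250 nm by
    default) or the deepest cytoplasm voxel, whichever is larger is cut at
    ``max_distance``.  Empty layers report occupancy NaN (undefined).
    """
    field = membrane_distance_field(seg, region, compartment)
    cyto = cytoplasm_mask(seg, compartment, exclude_organelles)
    rows = seg.table
    if compartment is not None:
        rows = rows[rows["compartment"] == compartment]
    ves_ids = rows[rows["klass"] == "vesicle"]["label"]
    ves = np.isin(seg.labels, list(ves_ids))

    w = float(layer_width) if layer_width else float(min(seg.voxel_size))
    n_layers = int(math.ceil(max_distance / w))
    idx = np.floor(field[cyto] / w).astype(int)
    idx_v = np.floor(field[cyto & ves] / w).astype(int)
    n_all = np.bincount(np.clip(idx, 0, n_layers), minlength=n_layers + 1)
    n_ves = np.bincount(np.clip(idx_v, 0, n_layers), minlength=n_layers + 1)
    out = []
    for i in range(n_layers):
        tot = int(n_all[i])
        out.append(LayerProfile(
            layer_index=i, d_lo=i * w, d_hi=(i + 1) * w,
            cyto_voxels=tot, vesicle_voxels=int(n_ves[i]),
            occupancy=(n_ves[i] / tot) if tot else math.nan,
            region=region))
    return out


def layers_frame(layers: list[LayerProfile]) -> pd.DataFrame:
    cols = ["layer_index", "d_lo_nm", "d_hi_nm", "cyto_voxels",
            "vesicle_voxels", "occupancy", "region"]
    rows = [{"layer_index": p.layer_index, "d_lo_nm": p.d_lo,
             "d_hi_nm": p.d_hi, "cyto_voxels": p.cyto_voxels,
             "vesicle_voxels": p.vesicle_voxels, "occupancy": p.occupancy,
             "region": p.region} for p in layers]
    return pd.DataFrame(rows, columns=cols)


def occupancy_peak(layers: list[LayerProfile],
                   min_distance: float = 0.0) -> tuple[float, float]:
    """(distance nm, occupancy) of the highest non-empty layer band."""
    best = (math.nan, -math.inf)
    for p in layers:
        if p.d_lo >= min_distance and p.cyto_voxels and not math.isnan(p.occupancy):
            if p.occupancy > best[1]:
                best = ((p.d_lo + p.d_hi) / 2.0, p.occupancy)
    return best


def tethers_by_distance(records: list[VesicleRecord],
                        bins=DEFAULT_TETHER_BINS_NM) -> pd.DataFrame:
    """Mean +/- sem tether count per vesicle in half-open distance bins.

    A vesicle at exactly a bin edge falls in the upper bin ([5, 10) for a
    5.0 nm distance).  Empty bins report NaN.
    """
    bins = list(bins)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        counts = [r.n_tethers for r in records
                  if not math.isnan(r.dist_membrane)
                  and lo <= r.dist_membrane < hi]
        n = len(counts)
        mean = float(np.mean(counts)) if n else math.nan
        sem = float(np.std(counts, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"d_lo_nm": lo, "d_hi_nm": hi, "n_vesicles": n,
                     "mean_tethers": mean, "sem_tethers": sem})
    return pd.DataFrame(rows)


def membrane_area_um2(seg: Segmentation, compartment: int | None = None) -> float:
    """Plasma membrane area (µm^2) from the isosurface of the enclosed solid."""
    rows = seg.table
    if compartment is not None:
        rows = rows[rows["compartment"] == compartment]
    ids = rows[rows["klass"] != "extracellular"]["label"]
    solid = np.isin(seg.labels, list(ids))
    if not np.any(solid):
        raise ValueError("no membrane-enclosed solid in this compartment")
    return surface_area(solid, seg.voxel_size) * 1e-6


def vesicles_per_membrane_area(records: list[VesicleRecord],
                               seg: Segmentation,
                               shells=(0.0, 45.0, 100.0, 200.0, 400.0),
                               compartment: int | None = None) -> pd.DataFrame:
    """Vesicle counts in distance shells, per µm^2 of plasma membrane."""
    area = membrane_area_um2(seg, compartment)
    if area <= 0:
        raise ValueError("membrane area is zero")
    shells = list(shells)
    rows = []
    for lo, hi in zip(shells[:-1], shells[1:]):
        n = sum(1 for r in records
                if not math.isnan(r.dist_membrane)
                and lo <= r.dist_membrane < hi)
        rows.append({"d_lo_nm": lo, "d_hi_nm": hi, "count": n,
                     "per_um2": n / area})
    return pd.DataFrame(rows)
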