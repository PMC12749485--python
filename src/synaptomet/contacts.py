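"""Contact zones: apposition patches, cleft widths, density profiles, PSD.

A contact zone between two membranes is the set of membrane faces of side
A lying within a tight-apposition cutoff (default 15 nm) of membrane B;
the active zone (AZ) is instead the presynaptic membrane portion facing
the PSD.  Cleft width is the per-face nearest membrane-to-membrane
distance averaged over the patch.  Intensity profiles (cleft midline and
perpendicular cytoplasmic) are normalized to a neighbouring background
region, so they are invariant to multiplicative intensity rescaling; the
PSD detector calls a post-synaptic density when the 10-25 nm depth band
rises above the 40-60 nm plateau by a configurable margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .volio import DensityVolume, Segmentation

TIGHT_APPOSITION_NM = 15.0
PSD_BAND_NM = (10.0, 25.0)
PSD_PLATEAU_NM = (40.0, 60.0)


class EmptyZoneError(ValueError):
    pass


@dataclass
class ContactZone:
    """An apposition patch between two membranes (or membrane and PSD)."""

    kind: str  # "AZ" | "DA_GLU" | "DA_PSE" | generic
    comp_a: int
    comp_b: int
    faces_a: np.ndarray  # (n, 3) voxel indices of the selected patch, side A
    faces_b: np.ndarray
    widths: np.ndarray  # per-face membrane-to-membrane distances (nm)
    voxel_size: tuple[float, float, float]
    empty: bool = False
    max_sep: float = TIGHT_APPOSITION_NM
    b_klasses: tuple[str, ...] = ("membrane", "AZ_membrane")
    psd_call: bool | None = None
    psd_band: tuple[float, float] | None = None

    @property
    def width_mean(self) -> float:
        if self.empty:
            raise EmptyZoneError("contact zone is empty")
        return float(self.widths.mean())

    @property
    def width_sd(self) -> float:
        if self.empty:
            raise EmptyZoneError("contact zone is empty")
        return float(self.widths.std())


def _protein_positive(vol: DensityVolume, seg: Segmentation) -> np.ndarray:
    """Return data with protein as positive contrast over the background.

    The contrast sign is read off the scene itself: if membrane voxels are
    darker than the extracellular background (the cryo-ET convention) the
    data are reflected about the background mean, so density excess is
    always an elevation.  The transform commutes with multiplicative
    rescaling, keeping normalized profiles scale-invariant.
    """
    data = np.asarray(vol.data, np.float64)
    mem = seg.mask("membrane") | seg.mask("AZ_membrane")
    bg_mask = seg.labels == 0
    if not np.any(bg_mask):
        bg_mask = ~mem
    bg = float(data[bg_mask].mean())
    if np.any(mem) and float(data[mem].mean()) < bg:
        data = 2.0 * bg - data
    return data


def _class_mask(seg: Segmentation, comp: int, klasses) -> np.ndarray:
    rows = seg.table
    ids = rows[(rows["compartment"] == comp)
               & rows["klass"].isin(list(klasses))]["label"]
    return np.isin(seg.labels, list(ids))


def define_contact_zone(seg: Segmentation, comp_a: int, comp_b: int,
                        max_sep: float = TIGHT_APPOSITION_NM,
                        kind: str = "contact",
                        az_mode: bool = False) -> ContactZone:
    """Select the apposed membrane patch between two compartments.

    The patch is the set of membrane-A surface voxels whose nearest
    distance to membrane B is below ``max_sep`` (tight apposition).  In
    ``az_mode`` the reference on side B is the PSD label instead of the
    membrane, matching the definition of the AZ as the membrane portion
    facing the PSD (the cutoff is widened by the cleft scale).  An empty
    result is returned flagged, not raised.
    """
    mem_a = _class_mask(seg, comp_a, ["membrane", "AZ_membrane"])
    b_klasses = ("PSD",) if az_mode else ("membrane", "AZ_membrane")
    mem_b = _class_mask(seg, comp_b, list(b_klasses))
    if not np.any(mem_a) or not np.any(mem_b):
        raise ValueError("both compartments need membrane (or PSD) labels")
    vs = seg.voxel_size
    d_to_b = ndimage.distance_transform_edt(~mem_b, sampling=vs)
    d_to_a = ndimage.distance_transform_edt(~mem_a, sampling=vs)
    # outer faces: membrane voxels adjacent to extracellular space (label 0);
    # the cytoplasm-facing inner surface must not enter the width statistics
    outside = ndimage.binary_dilation(seg.labels == 0)
    surf_a = mem_a & outside
    surf_b = mem_b & outside
    # voxel-center to voxel-center distances include one voxel of the two
    # half-voxel offsets to the faces; subtract it for the edge-to-edge gap
    corr = float(min(vs))
    sel_a = surf_a & (d_to_b - corr < max_sep)
    sel_b = surf_b & (d_to_a - corr < max_sep)
    faces_a = np.argwhere(sel_a)
    faces_b = np.argwhere(sel_b)
    if len(faces_a) == 0:
        return ContactZone(kind, comp_a, comp_b, faces_a, faces_b,
                           np.empty(0), vs, empty=True, max_sep=max_sep,
                           b_klasses=b_klasses)
    widths = d_to_b[sel_a] - corr
    widths = np.maximum(widths, 0.0)
    return ContactZone(kind, comp_a, comp_b, faces_a, faces_b, widths, vs,
                       max_sep=max_sep, b_klasses=b_klasses)


def cleft_width(zone: ContactZone) -> tuple[float, float]:
    """Mean and sd (nm) of the per-face membrane-to-membrane distance."""
    return zone.width_mean, zone.width_sd


def contact_area(seg: Segmentation, zone: ContactZone) -> float:
    """Patch area in µm^2 from a triangulated isosurface.

    The enclosed solid of side A is meshed (marching cubes on the lightly
    smoothed mask) and triangle areas are summed where the triangle
    centroid lies within the apposition cutoff of the side-B reference.
    """
    if zone.empty:
        raise EmptyZoneError("contact zone is empty")
    rows = seg.table
    ids = rows[(rows["compartment"] == zone.comp_a)
               & (rows["klass"] != "extracellular")]["label"]
    solid = np.isin(seg.labels, list(ids))
    vs = zone.voxel_size
    padded = np.pad(solid.astype(np.float32), 2)
    padded = ndimage.gaussian_filter(padded, 1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, 0.5, spacing=vs)
    verts = verts - 2 * np.asarray(vs)  # undo padding offset
    faces_mask = np.zeros(seg.shape, bool)
    faces_mask[tuple(zone.faces_a.T)] = True
    d_to_patch = ndimage.distance_transform_edt(~faces_mask, sampling=vs)
    centroids = verts[faces].mean(axis=1)
    idx = np.floor(centroids / np.asarray(vs)).astype(int)
    idx = np.clip(idx, 0, np.asarray(seg.shape) - 1)
    corr = float(min(vs))
    keep = d_to_patch[idx[:, 0], idx[:, 1], idx[:, 2]] <= 1.0 * corr
    tri = verts[faces[keep]]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return float(areas.sum()) * 1e-6


def midline_profile(vol: DensityVolume, seg: Segmentation, zone: ContactZone,
                    background_annulus_nm: tuple[float, float] = (10.0, 30.0),
                    n_z: int = 3) -> pd.DataFrame:
    """Normalized intensity along the cleft midline.

    The midline is the locus equidistant from the two membranes within the
    patch; intensities are sampled on ``n_z`` equally spaced z planes (low,
    middle, high through the patch), averaged, and normalized to the mean
    over a flanking background annulus 10-30 nm outside the patch at the
    same midline.  A uniform volume gives a profile identically 1.
    """
    if zone.empty:
        raise EmptyZoneError("contact zone is empty")
    data = _protein_positive(vol, seg)
    vs = zone.voxel_size
    mem_a = _class_mask(seg, zone.comp_a, ["membrane", "AZ_membrane"])
    mem_b = _class_mask(seg, zone.comp_b, ["membrane", "AZ_membrane", "PSD"])
    d_a = ndimage.distance_transform_edt(~mem_a, sampling=vs)
    d_b = ndimage.distance_transform_edt(~mem_b, sampling=vs)
    outside = seg.labels == 0
    mid = outside & (np.abs(d_a - d_b) <= min(vs)) \
        & (d_a + d_b <= 2 * zone.max_sep + 2 * min(vs))
    patch = np.zeros(seg.shape, bool)
    patch[tuple(zone.faces_a.T)] = True
    d_patch = ndimage.distance_transform_edt(~patch, sampling=vs)
    if not np.any(mid):
        raise EmptyZoneError("no equidistant midline voxels between membranes")
    # the midline sits half a cleft away from the patch; larger distances to
    # the patch are lateral excursions outside its footprint
    d_min = float(d_patch[mid].min())
    in_patch = mid & (d_patch <= d_min + 1.5 * min(vs))
    lo_bg, hi_bg = background_annulus_nm
    bg = mid & (d_patch > d_min + lo_bg) & (d_patch <= d_min + hi_bg)
    if not np.any(in_patch):
        raise EmptyZoneError("no midline voxels within the patch")
    if not np.any(bg):  # fall back to non-patch midline, else self-reference
        bg = mid & ~in_patch
        if not np.any(bg):
            bg = in_patch
    zs = np.unique(np.argwhere(in_patch)[:, 0])
    picks = np.unique(np.linspace(0, len(zs) - 1, min(n_z, len(zs))).astype(int))
    rows = []
    bg_mean = float(data[bg].mean()) if np.any(bg) else float("nan")
    for z in zs[picks]:
        sel = in_patch[z]
        ys, xs = np.nonzero(sel)
        for y, x in zip(ys, xs):
            rows.append({"z_nm": (z + 0.5) * vs[0],
                         "pos_nm": (x + 0.5) * vs[2],
                         "intensity": float(data[z, y, x])})
    df = pd.DataFrame(rows)
    df = df.groupby("pos_nm", as_index=False)["intensity"].mean()
    df["normalized"] = df["intensity"] / bg_mean if bg_mean and not \
        math.isnan(bg_mean) and bg_mean != 0 else np.nan
    return df


def cytoplasm_profile(vol: DensityVolume, seg: Segmentation, comp: int,
                      zone: ContactZone | None = None,
                      depth: float = 60.0, start: float = 5.0,
                      stack_nm: float = 40.0) -> pd.DataFrame:
    """Mean intensity vs perpendicular depth into a compartment.

    Starts ``start`` nm inside the facing membrane and proceeds to
    ``depth`` nm in 1-voxel steps, averaging laterally over the patch
    footprint (a stack about ``stack_nm`` across when a zone is given,
    else the whole compartment).  Normalized to the deep-plateau band
    (40-60 nm) so a uniform interior yields a flat profile at 1.  If the
    compartment is thinner than ``depth`` the profile is truncated and
    flagged via the ``truncated`` attribute in ``DataFrame.attrs``.
    """
    data = _protein_positive(vol, seg)
    vs = seg.voxel_size
    mem = _class_mask(seg, comp, ["membrane", "AZ_membrane"])
    if not np.any(mem):
        raise ValueError(f"compartment {comp} has no membrane")
    inside = _class_mask(seg, comp,
                         ["cytoplasm", "vesicle", "PSD", "mitochondrion",
                          "multivesicular_body", "large_organelle"])
    d_mem = ndimage.distance_transform_edt(~mem, sampling=vs)
    region = inside.copy()
    if zone is not None:
        patch = np.zeros(seg.shape, bool)
        faces = zone.faces_b if comp == zone.comp_b else zone.faces_a
        patch[tuple(faces.T)] = True
        half = stack_nm / 2.0
        near_patch = ndimage.distance_transform_edt(
            ~patch, sampling=vs) <= (half + depth)
        region &= near_patch
    step = float(min(vs))
    edges = np.arange(start, depth + step, step)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = region & (d_mem >= lo) & (d_mem < hi)
        rows.append({"depth_nm": (lo + hi) / 2.0,
                     "intensity": float(data[sel].mean())
                     if np.any(sel) else math.nan})
    df = pd.DataFrame(rows)
    truncated = bool(df["intensity"].isna().any())
    plat = df[(df["depth_nm"] >= PSD_PLATEAU_NM[0])
              & (df["depth_nm"] < PSD_PLATEAU_NM[1])]["intensity"].mean()
    df["normalized"] = df["intensity"] / plat if plat and not math.isnan(plat) \
        and plat != 0 else np.nan
    df.attrs["truncated"] = truncated
    return df


def detect_psd(profile: pd.DataFrame, margin: float = 0.10,
               band: tuple[float, float] = PSD_BAND_NM,
               plateau: tuple[float, float] = PSD_PLATEAU_NM
               ) -> tuple[bool | None, tuple[float, float]]:
    """Call a PSD from a normalized cytoplasmic profile.

    Positive when the mean normalized density in the 10-25 nm depth band
    exceeds the 40-60 nm plateau by more than ``margin`` (default 10%).
    The profile must carry protein as *positive* contrast (preprocessed
    convention).  Returns (call, band); call is None when the profile is
    too short to evaluate both bands.
    """
    d = profile["depth_nm"]
    in_band = profile[(d >= band[0]) & (d < band[1])]["normalized"]
    in_plat = profile[(d >= plateau[0]) & (d < plateau[1])]["normalized"]
    if in_band.empty or in_plat.empty or in_band.isna().all() \
            or in_plat.isna().all():
        return None, band
    rise = float(in_band.mean()) / float(in_plat.mean()) - 1.0
    return bool(rise > margin), band
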