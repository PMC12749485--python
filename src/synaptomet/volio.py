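"""Volume and label-map I/O, unit handling, and binning.

All lengths are held internally in nanometres; volumes in nm^3, with
conversion to µm^3 only at reporting time.  Grids use (z, y, x) axis order
with 0-based indices; z is the direction normal to the tomographic tilt
axis plane.

Density volumes and label maps are stored as MRC2014 files.  The header
voxel size is in Ångström (the MRC convention); it is converted to nm on
read.  Density maps are written as mode 2 (float32), label maps as mode 1
(int16).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Recognised object classes for label tables.
SEGMENT_CLASSES = (
    "membrane",
    "vesicle",
    "large_organelle",
    "mitochondrion",
    "multivesicular_body",
    "PSD",
    "AZ_membrane",
    "cytoplasm",
    "extracellular",
)

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32}
_MRC_MODE_OF = {np.dtype(np.int8): 0, np.dtype(np.int16): 1, np.dtype(np.float32): 2}


class VolumeIOError(ValueError):
    """Raised for malformed volume files or invalid volume metadata."""


@dataclass
class DensityVolume:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar values, C-ordered (z slowest).
    voxel_size : tuple of float
        Voxel edge length in nm per axis, ordered (z, y, x).
    origin : tuple of float
        Offset of voxel (0, 0, 0) in nm, ordered (z, y, x).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected a 3D grid, got shape {self.data.shape}")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise VolumeIOError(f"voxel size must be positive, got {vs}")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in np.broadcast_to(self.origin, (3,)))
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise VolumeIOError("volume contains non-finite values (NaN/inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in nm^3."""
        return float(np.prod(self.voxel_size))


@dataclass
class Segmentation:
    """Integer label grid congruent with a :class:`DensityVolume`.

    ``labels`` maps voxels to object ids; ``table`` carries one row per
    label id with its class (one of :data:`SEGMENT_CLASSES`) and the id of
    the compartment (synaptosome) it belongs to.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "klass", "compartment"])
    )
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeIOError(f"expected a 3D label grid, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeIOError("label grid must be integer-typed")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise VolumeIOError(f"voxel size must be positive, got {vs}")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in np.broadcast_to(self.origin, (3,)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def validate(self) -> None:
        """Check that every nonzero voxel's label appears in the table."""
        present = np.unique(self.labels)
        present = set(int(v) for v in present if v != 0)
        known = set(int(v) for v in self.table["label"])
        missing = present - known
        if missing:
            raise VolumeIOError(
                f"labels {sorted(missing)} occur in the grid but not in the table"
            )

    def labels_of_class(self, klass: str) -> list[int]:
        """Return label ids of a given class, sorted."""
        rows = self.table[self.table["klass"] == klass]
        return sorted(int(v) for v in rows["label"])

    def mask(self, klass: str) -> np.ndarray:
        """Boolean mask of all voxels belonging to a class."""
        ids = self.labels_of_class(klass)
        return np.isin(self.labels, ids) if ids else np.zeros(self.shape, bool)


# ---------------------------------------------------------------------------
# MRC2014 reader / writer
# ---------------------------------------------------------------------------
# The 1024-byte MRC2014 header.  Only the words needed for density and label
# volumes are interpreted; the rest are zero-filled on write and ignored on
# read.  Word layout (all little-endian, 4 bytes each):
#   1-3   nx, ny, nz        grid size (columns, rows, sections)
#   4     mode              0=int8, 1=int16, 2=float32
#   5-7   nxstart..         (ignored)
#   8-10  mx, my, mz        sampling grid (== nx, ny, nz here)
#   11-13 cella             cell size in Angstrom
#   14-16 cellb             cell angles (90, 90, 90)
#   17-19 mapc, mapr, maps  axis mapping (1, 2, 3)
#   20-22 dmin, dmax, dmean
#   23    ispg              1 for a volume
#   24    nsymbt            0
#   50-52 origin            in Angstrom
#   53    map               'MAP '
#   54    machst            machine stamp
#   55    rms
#   56    nlabl


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC2014 volume (mode 0, 1 or 2).

    Returns a :class:`DensityVolume` with voxel size converted from the
    header's Ångström cell to nm.  Raises :class:`VolumeIOError` with a
    remediation hint for malformed headers or unit-less voxel sizes.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise VolumeIOError(f"{path}: file shorter than the 1024-byte MRC header")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise VolumeIOError(
            f"{path}: missing 'MAP ' signature at byte 208 — not an MRC2014 file"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    origin = struct.unpack_from("<3f", raw, 196)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MRC_MODES:
        raise VolumeIOError(
            f"{path}: unsupported MRC mode {mode}; only modes 0/1/2 are readable"
        )
    if min(nx, ny, nz) <= 0:
        raise VolumeIOError(f"{path}: non-positive grid dimensions {(nx, ny, nz)}")
    # voxel size in Angstrom = cell / sampling; convert to nm
    samp = (mz or nz, my or ny, mx or nx)
    vs_ang = (cella[2] / samp[0], cella[1] / samp[1], cella[0] / samp[2])
    if min(vs_ang) <= 0:
        raise VolumeIOError(
            f"{path}: header voxel size is {vs_ang} Å — unit-less or corrupt header; "
            "set CELLA to grid-size x voxel-size in Å before reading"
        )
    dtype = _MRC_MODES[mode]
    count = nx * ny * nz
    offset = 1024 + nsymbt
    data = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"), count=count,
                         offset=offset)
    if data.size != count:
        raise VolumeIOError(f"{path}: truncated data section")
    data = data.reshape(nz, ny, nx).astype(dtype)
    vs_nm = tuple(v / 10.0 for v in vs_ang)
    origin_nm = (origin[2] / 10.0, origin[1] / 10.0, origin[0] / 10.0)
    return DensityVolume(data, vs_nm, origin_nm)


def write_volume(vol: DensityVolume, path: str | Path, dtype=None) -> Path:
    """Write a :class:`DensityVolume` as MRC2014.

    Float data is written as mode 2, int8 as mode 0, int16 as mode 1.
    Round-trips preserve values and voxel size exactly.
    """
    path = Path(path)
    data = vol.data
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype not in _MRC_MODE_OF:
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        else:
            data = data.astype(np.int16)
    mode = _MRC_MODE_OF[data.dtype]
    nz, ny, nx = data.shape
    vz, vy, vx = vol.voxel_size
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    struct.pack_into("<3f", header, 40, nx * vx * 10.0, ny * vy * 10.0, nz * vz * 10.0)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    arr = np.asarray(data, dtype=np.float64)
    struct.pack_into("<3f", header, 76, float(arr.min()), float(arr.max()),
                     float(arr.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    oz, oy, ox = vol.origin
    struct.pack_into("<3f", header, 196, ox * 10.0, oy * 10.0, oz * 10.0)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    struct.pack_into("<i", header, 220, 1)
    header[224:224 + 17] = b"synaptomet MRC2014"[:17]
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())
    return path


def write_labels(seg: Segmentation, path: str | Path) -> Path:
    """Write a label map as an MRC mode-1 (int16) volume plus a JSON table."""
    if seg.labels.max(initial=0) > np.iinfo(np.int16).max:
        raise VolumeIOError("label ids exceed int16 range of MRC mode 1")
    vol = DensityVolume(seg.labels.astype(np.int16), seg.voxel_size, seg.origin)
    write_volume(vol, path, dtype=np.int16)
    table_path = Path(path).with_suffix(".labels.json")
    table_path.write_text(seg.table.to_json(orient="records", indent=1))
    return Path(path)


def read_labels(path: str | Path) -> Segmentation:
    """Read a label map written by :func:`write_labels`."""
    vol = read_volume(path)
    if not np.issubdtype(vol.data.dtype, np.integer):
        raise VolumeIOError(f"{path}: label map is not integer-typed (mode 0/1)")
    table_path = Path(path).with_suffix(".labels.json")
    if table_path.exists():
        table = pd.DataFrame(json.loads(table_path.read_text()))
        if table.empty:
            table = pd.DataFrame(columns=["label", "klass", "compartment"])
    else:
        table = pd.DataFrame(columns=["label", "klass", "compartment"])
    return Segmentation(vol.data.astype(np.int32), vol.voxel_size, table, vol.origin)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_volume(vol: DensityVolume, factor: int) -> DensityVolume:
    """Block-mean downsample by an integer factor.

    The voxel size is multiplied by the factor, so e.g. a 3.987 Å raw pixel
    binned by 4 becomes 1.5948 nm (reported as 1.595 at three decimals).
    Dimensions not divisible by the factor are cropped at the high end.
    Block-mean binning conserves the grid mean over the retained region
    exactly.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"binning factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(vol, data=vol.data.copy())
    nz, ny, nx = vol.shape
    cz, cy, cx = (nz // factor) * factor, (ny // factor) * factor, (nx // factor) * factor
    data = vol.data[:cz, :cy, :cx].astype(np.float64)
    data = data.reshape(cz // factor, factor, cy // factor, factor,
                        cx // factor, factor).mean(axis=(1, 3, 5))
    vs = tuple(v * factor for v in vol.voxel_size)
    return DensityVolume(data.astype(np.float32), vs, vol.origin)


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

def export_tables(out_dir: str | Path,
                  vesicles: pd.DataFrame | None = None,
                  filaments: pd.DataFrame | None = None,
                  layers: pd.DataFrame | None = None,
                  synaptosomes: pd.DataFrame | None = None,
                  summary: dict | None = None) -> dict[str, Path]:
    """Write the analysis tables as UTF-8 CSV plus a JSON summary.

    Empty inputs produce headers-only CSV files.  Re-exporting re-imported
    tables is byte-identical (stable column order, no index column).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    defaults = {
        "vesicles": (vesicles, ["label", "compartment", "z_nm", "y_nm", "x_nm",
                                "V_nm3", "S_nm2", "diameter_nm", "wadell",
                                "dist_membrane_nm", "is_SV", "is_large", "is_big",
                                "is_elongated", "proximal", "boundary_clipped",
                                "n_tethers", "n_connectors"]),
        "filaments": (filaments, ["id", "kind", "partner_ids", "length_nm",
                                  "n_voxels", "threshold_level", "branching"]),
        "layers": (layers, ["layer_index", "d_lo_nm", "d_hi_nm", "cyto_voxels",
                            "vesicle_voxels", "occupancy", "region"]),
        "synaptosomes": (synaptosomes, ["compartment", "max_extension_nm",
                                        "visible_volume_um3", "n_vesicles",
                                        "vesicle_density_um3",
                                        "fraction_tethered", "fraction_connected"]),
    }
    for name, (df, cols) in defaults.items():
        if df is None:
            df = pd.DataFrame(columns=cols)
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        written[name] = p
    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary or {}, indent=1, sort_keys=True) + "\n")
    written["summary"] = p
    return written
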