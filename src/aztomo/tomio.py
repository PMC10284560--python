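"""Volume containers, MRC2014 I/O, and on-disk result tables.

Coordinates are voxel-indexed, 0-based, in (z, y, x) order throughout the
package; physical units (nm) appear only in reported quantities. Density
follows the cryo-ET convention that structure is *darker* than background
(lower grayscale values), tracked by ``DensityVolume.structure_low``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DensityVolume",
    "LabelVolume",
    "BACKGROUND",
    "AZ_MEMBRANE",
    "PLASMA_MEMBRANE",
    "POSTSYNAPTIC",
    "VESICLE_ID_START",
    "SEGMENT_ID_START",
    "read_mrc",
    "write_mrc",
    "read_labels",
    "write_labels",
    "write_results",
    "write_manifest",
]

# Reserved label ids
BACKGROUND = 0
AZ_MEMBRANE = 1
PLASMA_MEMBRANE = 2
POSTSYNAPTIC = 3
VESICLE_ID_START = 10
SEGMENT_ID_START = 1000

SCHEMA_VERSION = "1"

_MRC_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}


@dataclasses.dataclass
class DensityVolume:
    """3D grayscale map with voxel size.

    ``data`` is indexed ``[z, y, x]``. ``structure_low`` records the contrast
    convention: True means protein/membrane density has *lower* values than
    background (reconstructed cryo-ET convention); segmentation thresholds
    from below accordingly.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    structure_low: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"not a 3D volume: ndim={self.data.ndim}")
        if not self.voxel_size_nm > 0:
            raise ValueError(f"voxel_size_nm must be > 0, got {self.voxel_size_nm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class LabelVolume:
    """Integer map aligned to a DensityVolume.

    Reserved ids: 0 background, 1 AZ membrane, 2 non-AZ plasma membrane,
    3 postsynaptic/excluded; vesicles occupy ids >= 10 and detected segments
    ids >= 1000.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"not a 3D volume: ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"labels must be integer, got {self.data.dtype}")
        if not self.voxel_size_nm > 0:
            raise ValueError(f"voxel_size_nm must be > 0, got {self.voxel_size_nm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def vesicle_ids(self) -> list[int]:
        ids = np.unique(self.data)
        return [int(i) for i in ids if VESICLE_ID_START <= i < SEGMENT_ID_START]

    def check_aligned(self, density: DensityVolume) -> None:
        if self.data.shape != density.data.shape:
            raise ValueError(
                f"label shape {self.data.shape} does not match density {density.data.shape}"
            )
        if abs(self.voxel_size_nm - density.voxel_size_nm) > 1e-6:
            raise ValueError("label voxel size does not match density")


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

def _build_header(shape_zyx, mode, voxel_size_nm, origin_nm, dmin, dmax, dmean, rms):
    nz, ny, nx = shape_zyx
    h = np.zeros(256, dtype=np.int32)
    hf = h.view(np.float32)
    h[0:3] = (nx, ny, nz)          # NX NY NZ (columns fastest)
    h[3] = mode
    h[7:10] = (nx, ny, nz)         # MX MY MZ
    apix = voxel_size_nm * 10.0    # header cell is in Angstrom
    hf[10:13] = (nx * apix, ny * apix, nz * apix)   # CELLA
    hf[13:16] = (90.0, 90.0, 90.0)                  # CELLB
    h[16:19] = (1, 2, 3)           # MAPC MAPR MAPS
    hf[19:22] = (dmin, dmax, dmean)
    h[22] = 0                      # ISPG (image stack / volume)
    h[23] = 0                      # NSYMBT
    # ORIGIN (words 49-51, 0-based), stored x,y,z in Angstrom
    hf[49:52] = (origin_nm[2] * 10.0, origin_nm[1] * 10.0, origin_nm[0] * 10.0)
    h[52] = int.from_bytes(b"MAP ", "little")
    h[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")  # little-endian stamp
    hf[54] = rms
    h[55] = 0                      # NLABL
    return h


def _write_mrc_array(data: np.ndarray, voxel_size_nm: float, origin_nm, path) -> None:
    if data.dtype == np.float32:
        mode = 2
    elif data.dtype == np.int16:
        mode = 1
    elif data.dtype == np.int8:
        mode = 0
    elif data.dtype == np.uint16:
        mode = 6
    else:
        raise ValueError(f"unsupported dtype for MRC: {data.dtype}")
    stats = data.astype(np.float64)
    header = _build_header(
        data.shape, mode, voxel_size_nm, origin_nm,
        float(stats.min()), float(stats.max()), float(stats.mean()), float(stats.std()),
    )
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(data).tobytes())


def _read_mrc_array(path):
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise ValueError(f"malformed MRC header in {path}: file shorter than 1024 bytes")
    h = np.frombuffer(raw[:1024], dtype=np.int32)
    hf = h.view(np.float32)
    if h[52].tobytes() != b"MAP ":
        raise ValueError(f"malformed MRC header in {path}: missing 'MAP ' stamp")
    nx, ny, nz = int(h[0]), int(h[1]), int(h[2])
    mode = int(h[3])
    if mode not in _MRC_MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode} in {path}")
    if nz < 2 or ny < 2 or nx < 2:
        raise ValueError(f"not a 3D volume: dimensions {(nz, ny, nx)} in {path}")
    mx, my, mz = int(h[7]), int(h[8]), int(h[9])
    if min(mx, my, mz) <= 0:
        raise ValueError(f"malformed MRC header in {path}: non-positive sampling")
    apix = np.array([hf[10] / mx, hf[11] / my, hf[12] / mz])
    if apix.min() <= 0:
        raise ValueError(f"malformed MRC header in {path}: non-positive cell")
    if (apix.max() - apix.min()) / apix.mean() > 1e-3:
        raise ValueError(
            f"anisotropic voxel size {tuple(apix)} A in {path}; only cubic voxels supported"
        )
    dtype = _MRC_MODE_DTYPES[mode]
    nsymbt = int(h[23])
    start = 1024 + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw[start:start + count * dtype.itemsize], dtype=dtype)
    if data.size != count:
        raise ValueError(f"malformed MRC data block in {path}: expected {count} voxels")
    data = data.reshape(nz, ny, nx).copy()
    origin_nm = (float(hf[51]) / 10.0, float(hf[50]) / 10.0, float(hf[49]) / 10.0)
    return data, float(apix.mean()) / 10.0, origin_nm


def read_mrc(path) -> DensityVolume:
    """Read an MRC2014 volume as a DensityVolume (voxel size converted to nm)."""
    data, voxel_size_nm, origin_nm = _read_mrc_array(path)
    return DensityVolume(data.astype(np.float32), voxel_size_nm, origin_nm)


def write_mrc(vol: DensityVolume, path) -> None:
    _write_mrc_array(vol.data.astype(np.float32), vol.voxel_size_nm, vol.origin_nm, path)


def read_labels(path, id_map: dict[int, int] | None = None) -> tuple[LabelVolume, list[int]]:
    """Read an integer MRC label volume, optionally renumbering ids via id_map.

    Returns (labels, unknown_ids): ids present in the file but absent from
    id_map are reported (and kept as-is), never silently dropped. An id_map
    assigning the same target to two sources is rejected.
    """
    data, voxel_size_nm, origin_nm = _read_mrc_array(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.array_equal(data, np.round(data)):
            raise ValueError(f"label volume {path} holds non-integer values")
        data = data.astype(np.int32)
    unknown: list[int] = []
    if id_map is not None:
        targets = list(id_map.values())
        if len(set(targets)) != len(targets):
            raise ValueError(f"id_map assigns a target id twice: {id_map}")
        present = np.unique(data)
        unknown = [int(i) for i in present if i != 0 and int(i) not in id_map]
        out = data.copy()
        for src, dst in id_map.items():
            out[data == src] = dst
        data = out
    return LabelVolume(data.astype(np.int32), voxel_size_nm, origin_nm), unknown


def write_labels(labels: LabelVolume, path) -> None:
    data = labels.data
    if data.max(initial=0) < 2 ** 15 and data.min(initial=0) >= -(2 ** 15):
        out = data.astype(np.int16)
    else:
        raise ValueError("label ids exceed int16 range supported by MRC mode 1")
    _write_mrc_array(out, labels.voxel_size_nm, labels.origin_nm, path)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

VESICLE_COLUMNS = [
    "schema_version", "synapse_id", "vesicle_id",
    "center_z", "center_y", "center_x",
    "radius_nm", "distance_to_az_nm",
    "n_tethers", "n_connectors", "tethered", "multiply_tethered",
    "state", "distance_zone",
]
SEGMENT_COLUMNS = [
    "schema_version", "synapse_id", "segment_id", "kind",
    "validity_threshold", "n_voxels",
    "contacts", "length_nm", "length_class",
]
SYNAPSE_COLUMNS = [
    "schema_version", "synapse_id", "condition", "orientation_deg",
    "az_area_nm2", "n_vesicles", "n_proximal",
    "surface_concentration_per_um2", "n_tethers", "n_connectors",
]
COMPARISON_COLUMNS = [
    "schema_version", "variable", "group_a", "group_b", "test",
    "statistic", "p_value", "stars", "n_a", "n_b", "warning",
]

_TABLE_COLUMNS = {
    "vesicles": VESICLE_COLUMNS,
    "segments": SEGMENT_COLUMNS,
    "synapses": SYNAPSE_COLUMNS,
    "comparisons": COMPARISON_COLUMNS,
}


def _conform(df: pd.DataFrame | None, columns: list[str]) -> pd.DataFrame:
    if df is None or len(df) == 0:
        return pd.DataFrame(columns=columns)
    df = df.copy()
    df["schema_version"] = SCHEMA_VERSION
    for c in columns:
        if c not in df.columns:
            df[c] = np.nan
    return df[columns]


def write_results(outdir, *, vesicles=None, segments=None, synapses=None,
                  comparisons=None) -> dict[str, Path]:
    """Write result tables as CSV with a versioned schema and a fixed column order.

    Empty tables yield header-only files; reruns on identical inputs produce
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in (("vesicles", vesicles), ("segments", segments),
                     ("synapses", synapses), ("comparisons", comparisons)):
        path = outdir / f"{name}.csv"
        _conform(df, _TABLE_COLUMNS[name]).to_csv(path, index=False, float_format="%.6g")
        written[name] = path
    return written


def write_manifest(outdir, config: dict, seeds: dict | None = None,
                   removals: list | None = None) -> Path:
    """JSON run manifest: configuration, package versions, seeds, exclusions."""
    import scipy
    import skimage

    from . import __version__

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": config,
        "seeds": seeds or {},
        "removals": removals or [],
        "versions": {
            "aztomo": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
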