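"""Vesicle geometry and per-structure measurements.

Distances are edge-to-edge between voxel centers: the minimal center-to-center
distance between two voxel objects minus one voxel, clamped at zero, so that
adjacent or overlapping objects are at distance 0. No sub-voxel refinement is
attempted; at the ~1.4-1.8 nm voxel sizes of binned tomograms every distance
carries a +-1 voxel uncertainty.

Bridge length is geodesic: the shortest 26-neighbor path (Euclidean step
weights 1, sqrt2, sqrt3 voxels) through the segment's voxels between its two
boundary-contact voxel sets, so curvature contributes to the length, unlike a
chord measurement.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist

from .hierseg import Segment
from .tomio import AZ_MEMBRANE, LabelVolume, VESICLE_ID_START

__all__ = [
    "VesicleRecord",
    "LayerProfile",
    "ModelEnvelope",
    "disk_to_sphere",
    "distance_to_az",
    "vesicle_distances",
    "segment_length",
    "classify_tether",
    "classify_state",
    "zone_of_distance",
    "count_bridges",
    "layer_profile",
    "surface_concentration",
    "az_area",
    "model_span",
    "tether_accommodates",
]

TETHER_CLASS_BOUNDS_NM = (6.0, 12.0, 24.0)
STATE_BOUNDS_NM = (5.0, 10.0)
ZONE_BOUNDS_NM = (45.0, 75.0, 250.0)

_OFFSETS26 = np.array([(dz, dy, dx)
                       for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                       if (dz, dy, dx) != (0, 0, 0)], dtype=np.int64)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass
class VesicleRecord:
    """Per-vesicle morphometrics; the state label is a pure function of distance."""

    id: int
    center: tuple[float, float, float]
    radius_nm: float
    distance_to_az_nm: float
    n_tethers: int = 0
    n_connectors: int = 0
    state: str = ""
    distance_zone: str = ""


@dataclasses.dataclass
class LayerProfile:
    """Occupancy of 1-voxel-thick distance layers by vesicles, plus zone sums."""

    layers: pd.DataFrame  # layer, dist_lo_nm, dist_hi_nm, layer_voxels, sv_voxels, phi
    zones: pd.DataFrame   # zone, layer_voxels, sv_voxels, phi


@dataclasses.dataclass
class ModelEnvelope:
    """Geometric envelope of an atomic model used for the tether-size screen."""

    span_nm: float
    girth_nm: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.span_nm > 0:
            raise ValueError("span must be > 0")


# ---------------------------------------------------------------------------
# Sphere construction
# ---------------------------------------------------------------------------

def disk_to_sphere(contour_voxels, voxel_size_nm: float, shape):
    """Extend a traced maximum-diameter contour to a sphere.

    The contour must lie in one grid plane; a least-squares (Kasa) circle fit
    gives the center and radius, and the sphere is every voxel of ``shape``
    within that radius of the center.

    Returns (center_voxel_zyx, radius_nm, sphere_voxel_index_tuple).
    """
    pts = np.asarray(contour_voxels, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 6:
        raise ValueError("degenerate contour: need >= 6 voxels in a grid plane")
    spans = pts.max(axis=0) - pts.min(axis=0)
    flat_axes = np.nonzero(spans == 0)[0]
    if len(flat_axes) == 0:
        raise ValueError("contour does not lie in a single grid plane")
    if len(flat_axes) > 1:
        raise ValueError("degenerate contour: collinear trace")
    axis = int(flat_axes[0])
    plane_coord = pts[0, axis]
    in_plane = np.delete(pts, axis, axis=1)
    u, v = in_plane[:, 0], in_plane[:, 1]
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    b = u ** 2 + v ** 2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate contour: collinear trace")
    cu, cv, c0 = sol
    radius_vox = float(np.sqrt(c0 + cu ** 2 + cv ** 2))
    center = np.empty(3)
    center[axis] = plane_coord
    center[np.delete(np.arange(3), axis)] = (cu, cv)
    grid = np.indices(shape, dtype=float)
    dist = np.sqrt(((grid - center[:, None, None, None]) ** 2).sum(axis=0))
    sphere = np.nonzero(dist <= radius_vox)
    return tuple(center), radius_vox * voxel_size_nm, sphere


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _edge_to_edge_nm(min_center_dist_vox: float, voxel_size_nm: float) -> float:
    return max(0.0, float(min_center_dist_vox) - 1.0) * voxel_size_nm


def distance_to_az(vesicle_voxels, az_mask: np.ndarray, voxel_size_nm: float) -> float:
    """Shortest distance between AZ membrane and SV voxels, in nm (edge-to-edge)."""
    if not az_mask.any():
        raise ValueError("empty AZ membrane mask")
    if len(vesicle_voxels[0]) == 0:
        raise ValueError("empty vesicle")
    edt = ndimage.distance_transform_edt(~az_mask)
    return _edge_to_edge_nm(edt[vesicle_voxels].min(), voxel_size_nm)


def vesicle_distances(labels: LabelVolume) -> pd.DataFrame:
    """AZ distance for every vesicle in a label volume (one shared distance map)."""
    az = labels.data == AZ_MEMBRANE
    if not az.any():
        raise ValueError("empty AZ membrane label")
    edt = ndimage.distance_transform_edt(~az)
    rows = []
    for vid in labels.vesicle_ids():
        vox = labels.data == vid
        rows.append({
            "vesicle_id": vid,
            "distance_to_az_nm": _edge_to_edge_nm(edt[vox].min(), labels.voxel_size_nm),
            "n_voxels": int(vox.sum()),
        })
    return pd.DataFrame(rows, columns=["vesicle_id", "distance_to_az_nm", "n_voxels"])


# ---------------------------------------------------------------------------
# Geodesic bridge length
# ---------------------------------------------------------------------------

def _voxel_graph(voxels):
    """Sparse 26-neighbor graph over a voxel set; weights in voxel units."""
    pts = np.stack(voxels, axis=1).astype(np.int64)
    n = len(pts)
    shift = pts.min(axis=0) - 1
    local = pts - shift
    dims = local.max(axis=0) + 2
    keys = np.ravel_multi_index(local.T, dims)
    order = np.argsort(keys)
    sorted_keys = keys[order]
    rows, cols, weights = [], [], []
    for off in _OFFSETS26:
        nb = local + off
        nb_keys = np.ravel_multi_index(nb.T, dims, mode="clip")
        pos = np.searchsorted(sorted_keys, nb_keys)
        pos_c = np.clip(pos, 0, n - 1)
        hit = sorted_keys[pos_c] == nb_keys
        src = np.nonzero(hit)[0]
        dst = order[pos_c[hit]]
        w = np.linalg.norm(off.astype(float))
        rows.append(src)
        cols.append(dst)
        weights.append(np.full(len(src), w))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    index_of = {tuple(p): i for i, p in enumerate(pts)}
    return graph, index_of


def _contact_indices(contact_voxels, index_of):
    return np.array([index_of[tuple(p)] for p in np.stack(contact_voxels, axis=1)],
                    dtype=np.int64)


def _segment_contact_sets(segment: Segment):
    if segment.kind == "tether":
        vid = segment.vesicle_ids[0]
        return segment.contacts[AZ_MEMBRANE], segment.contacts[vid]
    if segment.kind == "connector":
        va, vb = segment.vesicle_ids
        return segment.contacts[va], segment.contacts[vb]
    raise ValueError(f"cannot measure a {segment.kind!r} segment")


def segment_length(segment: Segment, voxel_size_nm: float) -> float:
    """Minimal geodesic path length through the segment between its contact sets, nm."""
    set_a, set_b = _segment_contact_sets(segment)
    a_pts = set(zip(*set_a))
    b_pts = set(zip(*set_b))
    if a_pts & b_pts:
        return 0.0
    graph, index_of = _voxel_graph(segment.voxels)
    ia = _contact_indices(set_a, index_of)
    ib = _contact_indices(set_b, index_of)
    dist = dijkstra(graph, directed=False, indices=ia, min_only=True)
    best = dist[ib].min()
    if not np.isfinite(best):
        raise AssertionError("contact sets disconnected within segment")
    return float(best) * voxel_size_nm


def tether_accommodates(segment: Segment, envelope: ModelEnvelope,
                        voxel_size_nm: float) -> bool:
    """Size screen: can a rod of the envelope's span lie within the bridge?

    True iff some pair of contact voxels (one per boundary) is joined by a
    geodesic of length >= the envelope span. This is a conservative geometric
    screen, not a rigid-body density fit: a curved bridge whose chord is
    shorter than the span can still accommodate the model.
    """
    set_a, set_b = _segment_contact_sets(segment)
    graph, index_of = _voxel_graph(segment.voxels)
    ia = _contact_indices(set_a, index_of)
    ib = _contact_indices(set_b, index_of)
    dist = dijkstra(graph, directed=False, indices=ia)
    reach = dist[:, ib]
    reach = reach[np.isfinite(reach)]
    if reach.size == 0:
        raise AssertionError("contact sets disconnected within segment")
    return bool(reach.max() * voxel_size_nm >= envelope.span_nm)


# ---------------------------------------------------------------------------
# Classification (all bins left-closed / right-open)
# ---------------------------------------------------------------------------

def classify_tether(length_nm: float, bounds=TETHER_CLASS_BOUNDS_NM) -> str:
    """Length classes: [0,6) short, [6,12) intermediate, [12,24) long, >=24 extra."""
    if length_nm < 0:
        raise ValueError("length must be >= 0")
    b1, b2, b3 = bounds
    if length_nm < b1:
        return "short"
    if length_nm < b2:
        return "intermediate"
    if length_nm < b3:
        return "long"
    return "extra"


def classify_state(distance_nm: float, bounds=STATE_BOUNDS_NM) -> str:
    """Tethering states by AZ distance: [0,5) SNAP25-dependent, [5,10)
    intermediate, [10,inf) Munc13-independent."""
    if distance_nm < 0:
        raise ValueError("distance must be >= 0")
    b1, b2 = bounds
    if distance_nm < b1:
        return "SNAP25-dependent"
    if distance_nm < b2:
        return "intermediate"
    return "Munc13-independent"


def zone_of_distance(distance_nm: float, bounds=ZONE_BOUNDS_NM) -> str:
    b1, b2, b3 = bounds
    if distance_nm < b1:
        return "proximal"
    if distance_nm < b2:
        return "intermediate"
    if distance_nm < b3:
        return "distal"
    return "beyond"


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def count_bridges(vesicle_ids, segments: list[Segment]) -> pd.DataFrame:
    """Per-vesicle tether/connector counts and tethering flags.

    Each tether increments exactly one vesicle; each connector increments
    exactly two. ``multiply_tethered`` means three or more tethers.
    """
    counts = {int(v): {"n_tethers": 0, "n_connectors": 0} for v in vesicle_ids}
    for seg in segments:
        if seg.kind == "tether":
            counts[seg.vesicle_ids[0]]["n_tethers"] += 1
        elif seg.kind == "connector":
            for vid in seg.vesicle_ids:
                counts[vid]["n_connectors"] += 1
    rows = []
    for vid in sorted(counts):
        c = counts[vid]
        rows.append({
            "vesicle_id": vid, **c,
            "tethered": c["n_tethers"] >= 1,
            "multiply_tethered": c["n_tethers"] >= 3,
        })
    return pd.DataFrame(rows, columns=["vesicle_id", "n_tethers", "n_connectors",
                                       "tethered", "multiply_tethered"])


# ---------------------------------------------------------------------------
# Layers and AZ surface
# ---------------------------------------------------------------------------

def layer_profile(labels: LabelVolume, max_dist_nm: float = 250.0,
                  zone_bounds=ZONE_BOUNDS_NM, presynaptic_ref=None) -> LayerProfile:
    """Fraction of 1-voxel-thick distance layers occupied by vesicles.

    The presynaptic cytoplasm *including* SV voxels is partitioned into
    layers by distance to the AZ membrane (layer k covers (k-1, k] voxels);
    the per-layer occupied fraction is SV voxels / layer voxels. Summed SV
    voxels over layers equal the total SV voxels in range, exactly.
    """
    from .hierseg import _presynaptic_component

    az = labels.data == AZ_MEMBRANE
    if not az.any():
        raise ValueError("empty AZ membrane label")
    v = labels.voxel_size_nm
    ves = labels.data >= VESICLE_ID_START
    fluid = (labels.data == 0) | ves
    presyn = _presynaptic_component(fluid, labels, presynaptic_ref)
    edt = ndimage.distance_transform_edt(~az)
    k_max = int(np.ceil(max_dist_nm / v))
    layer_idx = np.ceil(edt).astype(np.int64)
    in_range = presyn & (layer_idx >= 1) & (layer_idx <= k_max)
    lay = layer_idx[in_range]
    occ = ves[in_range]
    layer_voxels = np.bincount(lay, minlength=k_max + 1)[1:]
    sv_voxels = np.bincount(lay[occ], minlength=k_max + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(layer_voxels > 0, sv_voxels / np.maximum(layer_voxels, 1), 0.0)
    k = np.arange(1, k_max + 1)
    layers = pd.DataFrame({
        "layer": k,
        "dist_lo_nm": (k - 1) * v,
        "dist_hi_nm": k * v,
        "layer_voxels": layer_voxels,
        "sv_voxels": sv_voxels,
        "phi": phi,
    })
    mid = (k - 0.5) * v
    zone = np.array([zone_of_distance(m, zone_bounds) for m in mid])
    zrows = []
    for zname in ("proximal", "intermediate", "distal"):
        sel = zone == zname
        lv = int(layer_voxels[sel].sum())
        sv = int(sv_voxels[sel].sum())
        zrows.append({"zone": zname, "layer_voxels": lv, "sv_voxels": sv,
                      "phi": sv / lv if lv else 0.0})
    return LayerProfile(layers=layers, zones=pd.DataFrame(zrows))


def surface_concentration(n_proximal: int, az_area_nm2: float) -> float:
    """Proximal SVs per square micrometer of AZ membrane."""
    if not az_area_nm2 > 0:
        raise ValueError("AZ area must be > 0")
    return n_proximal / az_area_nm2 * 1.0e6


def az_area(labels: LabelVolume, method: str = "mesh", corrected: bool = True,
            presynaptic_ref=None) -> float:
    """Surface area of the presynaptic face of the AZ membrane, nm^2.

    method='mesh' (default): marching-cubes mesh of the interface between the
    presynaptic fluid (cytosol + vesicles) and everything else, restricted to
    triangles adjacent to AZ-labeled voxels. Robust for oblique and curved
    membranes, where raw voxel-face counting overestimates area.

    method='faces': count voxel faces between AZ and presynaptic fluid,
    optionally scaled by the stereological correction 2/3 that removes the
    orientation-averaged overestimate of face counting.
    """
    from skimage.measure import marching_cubes

    from .hierseg import _presynaptic_component

    az = labels.data == AZ_MEMBRANE
    if not az.any():
        raise ValueError("empty AZ membrane label")
    v = labels.voxel_size_nm
    fluid = (labels.data == 0) | (labels.data >= VESICLE_ID_START)
    presyn = _presynaptic_component(fluid, labels, presynaptic_ref)
    if method == "faces":
        n_faces = 0
        for axis in range(3):
            a = np.swapaxes(az, 0, axis)
            f = np.swapaxes(presyn, 0, axis)
            n_faces += int((a[:-1] & f[1:]).sum() + (f[:-1] & a[1:]).sum())
        area = n_faces * v ** 2
        return area * (2.0 / 3.0) if corrected else area
    if method != "mesh":
        raise ValueError(f"unknown estimator {method!r}")
    body = (~presyn).astype(np.float32)
    verts, faces, _, _ = marching_cubes(body, level=0.5)
    tri = verts[faces]
    centroids = tri.mean(axis=1)
    edt_az = ndimage.distance_transform_edt(~az)
    d = ndimage.map_coordinates(edt_az, centroids.T, order=1)
    keep = d < 0.9
    t = tri[keep]
    cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum()) * v ** 2


# ---------------------------------------------------------------------------
# Atomic-model span
# ---------------------------------------------------------------------------

def _select_atoms(atoms, selection):
    mask = np.ones(atoms.array_length(), dtype=bool)
    chain = selection.get("chain_id")
    if chain is not None:
        mask &= atoms.chain_id == chain
    res_range = selection.get("res_range")
    if res_range is not None:
        lo, hi = res_range
        mask &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
    res_ids = selection.get("res_ids")
    if res_ids is not None:
        mask &= np.isin(atoms.res_id, np.asarray(res_ids))
    return mask


def model_span(structure, selection_a: dict, selection_b: dict) -> float:
    """Shortest inter-atom distance between two regions of an atomic model, nm.

    ``structure`` is a biotite AtomArray or a PDB/mmCIF path; selections give
    an optional ``chain_id`` plus ``res_range=(lo, hi)`` or ``res_ids=[...]``.
    """
    import biotite.structure as struc

    if not isinstance(structure, struc.AtomArray):
        import biotite.structure.io as strucio

        structure = strucio.load_structure(str(structure))
        if isinstance(structure, struc.AtomArrayStack):
            structure = structure[0]
    ma = _select_atoms(structure, selection_a)
    mb = _select_atoms(structure, selection_b)
    if not ma.any() or not mb.any():
        raise ValueError("empty atom selection for model span")
    d = cdist(structure.coord[ma], structure.coord[mb])
    return float(d.min()) / 10.0  # Angstrom -> nm
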