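"""Hierarchical connectivity segmentation of tethers and connectors.

Density bridges are detected as connected clusters of dark voxels that link
two boundaries (an SV and the AZ membrane, or two SVs) at any threshold of an
increasing threshold series; each bridge is reported as the cluster at the
*lowest* threshold at which it links its boundaries (its "core"), which
removes the arbitrariness of a single-threshold segmentation. Components
found at higher thresholds that contain an already-reported core are that
core's dilations and are not reported again.

Foreground at threshold t is ``density <= t`` (structure-low contrast);
components and boundary contacts use 26-connectivity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .tomio import (
    AZ_MEMBRANE,
    DensityVolume,
    LabelVolume,
    PLASMA_MEMBRANE,
    POSTSYNAPTIC,
    SEGMENT_ID_START,
    VESICLE_ID_START,
)

__all__ = [
    "ThresholdSchedule",
    "Segment",
    "analysis_region",
    "connectivity_segmentation",
    "classify_segment",
    "segments_to_labels",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclasses.dataclass(frozen=True)
class ThresholdSchedule:
    """Strictly increasing grayscale thresholds t1 < ... < tK (K >= 2)."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) < 2:
            raise ValueError("schedule needs at least 2 thresholds")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {t}")
        object.__setattr__(self, "thresholds", t)

    @classmethod
    def absolute(cls, values) -> "ThresholdSchedule":
        return cls(tuple(values))

    @classmethod
    def quantile(cls, density: DensityVolume, region: np.ndarray, k: int = 24,
                 q_min: float = 0.02, q_max: float = 0.5) -> "ThresholdSchedule":
        """Evenly spaced quantiles of the analysis-region density.

        A quantile ladder is invariant to affine changes of volume contrast,
        which absolute thresholds are not.
        """
        vals = density.data[region]
        if vals.size == 0:
            raise ValueError("empty analysis region")
        qs = np.linspace(q_min, q_max, k)
        t = np.unique(np.quantile(vals, qs))
        if len(t) < 2:
            raise ValueError("region density too uniform for a quantile schedule")
        return cls(tuple(float(x) for x in t))

    @classmethod
    def linear(cls, density: DensityVolume, region: np.ndarray,
               k: int = 24) -> "ThresholdSchedule":
        """Evenly spaced thresholds over the region's density range.

        Fallback for near-binary volumes (e.g. noiseless phantoms) where the
        quantile ladder collapses to a single value.
        """
        vals = density.data[region]
        if vals.size == 0:
            raise ValueError("empty analysis region")
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise ValueError("region density is constant; no schedule possible")
        return cls(tuple(np.linspace(lo, hi, k)[:-1]))  # drop hi: full region is not a bridge


@dataclasses.dataclass
class Segment:
    """One detected bridge: its core voxels and boundary contacts.

    ``contacts`` maps each contacted boundary id to the segment voxels
    (arrays of z, y, x indices) 26-adjacent to that boundary. ``kind`` is
    'tether' (one SV + AZ membrane), 'connector' (two SVs, no membrane), or
    'rejected'. ``length_nm`` is filled by the morphometry layer.
    """

    id: int
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    validity_threshold: float
    contacts: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    kind: str
    length_nm: float | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels[0])

    @property
    def contacted_ids(self) -> frozenset[int]:
        return frozenset(self.contacts)

    @property
    def vesicle_ids(self) -> tuple[int, ...]:
        return tuple(sorted(i for i in self.contacts if i >= VESICLE_ID_START))


def classify_segment(contacted_ids) -> str:
    """Classify a boundary-contact signature.

    Exactly {one SV, AZ membrane} -> tether; exactly {two SVs} with no
    membrane -> connector; anything else (>= 3 boundaries, a single boundary,
    SV + non-AZ membrane only, ...) -> rejected. Total function.
    """
    ids = frozenset(int(i) for i in contacted_ids)
    vesicles = {i for i in ids if i >= VESICLE_ID_START}
    membranes = ids & {AZ_MEMBRANE, PLASMA_MEMBRANE, POSTSYNAPTIC}
    if len(vesicles) == 1 and membranes == {AZ_MEMBRANE} and len(ids) == 2:
        return "tether"
    if len(vesicles) == 2 and not membranes and len(ids) == 2:
        return "connector"
    return "rejected"


def _presynaptic_component(free: np.ndarray, labels: LabelVolume,
                           ref_point=None) -> np.ndarray:
    """Connected component of non-boundary space on the presynaptic side.

    The component is chosen by a reference point if given, else as the
    component adjacent to the most vesicle voxels, else (no vesicles) as the
    largest component touching the AZ membrane.
    """
    comp, n = ndimage.label(free, structure=np.array(
        [[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
         [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
         [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool))
    if n == 0:
        raise ValueError("no free space in label volume")
    if ref_point is not None:
        cid = comp[tuple(int(round(c)) for c in ref_point)]
        if cid == 0:
            raise ValueError(f"presynaptic reference point {ref_point} lies on a boundary")
        return comp == cid
    ves = labels.data >= VESICLE_ID_START
    if ves.any():
        ring = ndimage.binary_dilation(ves, structure=_CONN26) & free
        counts = np.bincount(comp[ring], minlength=n + 1)
    else:
        az_ring = ndimage.binary_dilation(labels.data == AZ_MEMBRANE, structure=_CONN26) & free
        counts = np.bincount(comp[az_ring], minlength=n + 1)
    counts[0] = 0
    if counts.max() == 0:
        raise ValueError("could not identify the presynaptic compartment")
    return comp == int(counts.argmax())


def analysis_region(labels: LabelVolume, max_dist_nm: float,
                    presynaptic_ref=None) -> np.ndarray:
    """Presynaptic voxels within max_dist_nm of the AZ membrane.

    Boundary voxels (membranes, vesicles, postsynaptic) are excluded; only
    the presynaptic connected compartment of free space is kept, so the
    synaptic cleft and postsynaptic side never enter the analysis.
    """
    az = labels.data == AZ_MEMBRANE
    if not az.any():
        raise ValueError("empty AZ membrane label")
    if max_dist_nm <= 0:
        return np.zeros(labels.shape, dtype=bool)
    free = labels.data == 0
    presyn = _presynaptic_component(free, labels, presynaptic_ref)
    edt = ndimage.distance_transform_edt(~az) * labels.voxel_size_nm
    return free & presyn & (edt <= max_dist_nm)


def connectivity_segmentation(density: DensityVolume, labels: LabelVolume,
                              region: np.ndarray,
                              schedule: ThresholdSchedule) -> list[Segment]:
    """Detect tether/connector cores over an increasing threshold series.

    At each threshold (ascending) the 26-connected components of
    ``region & (density <= t)`` are examined; a component whose boundary
    contacts form a valid tether or connector signature, and which does not
    contain a core already reported at a lower threshold, is reported with
    that threshold as its validity threshold. Reported segments are mutually
    disjoint and lie entirely within the region.
    """
    labels.check_aligned(density)
    if not region.any():
        raise ValueError("empty analysis region")
    vals = density.data[region]
    lo, hi = float(vals.min()), float(vals.max())
    t_arr = np.asarray(schedule.thresholds)
    if t_arr.max() < lo or t_arr.min() > hi:
        raise ValueError(
            f"threshold schedule {schedule.thresholds} lies outside the region "
            f"density range [{lo:.4g}, {hi:.4g}]"
        )

    lab = labels.data
    boundary_ids = [int(i) for i in np.unique(lab) if i > 0]
    # 26-dilation of each boundary, computed once: a foreground voxel inside
    # one of these halos is a contact voxel of that boundary
    halos = {b: ndimage.binary_dilation(lab == b, structure=_CONN26) & (lab == 0)
             for b in boundary_ids}

    claimed = np.zeros(density.data.shape, dtype=bool)
    segments: list[Segment] = []
    next_id = SEGMENT_ID_START
    for t in schedule.thresholds:
        fg = region & (density.data <= t)
        comp, n = ndimage.label(fg, structure=_CONN26)
        if n == 0:
            continue
        touched_by: dict[int, set[int]] = {}
        for b, halo in halos.items():
            for ci in np.unique(comp[halo]):
                if ci > 0:
                    touched_by.setdefault(int(ci), set()).add(b)
        candidates = [ci for ci, ids in touched_by.items()
                      if classify_segment(ids) != "rejected"]
        if not candidates:
            continue
        objects = ndimage.find_objects(comp)
        for ci in sorted(candidates):
            sl = objects[ci - 1]
            sub = comp[sl] == ci
            if claimed[sl][sub].any():
                continue  # represented by a lower-threshold core
            contacts: dict[int, tuple] = {}
            for b in touched_by[ci]:
                idx = np.nonzero(sub & halos[b][sl])
                contacts[b] = tuple(a + s.start for a, s in zip(idx, sl))
            vox = np.nonzero(sub)
            vox = tuple(a + s.start for a, s in zip(vox, sl))
            claimed[vox] = True
            segments.append(Segment(
                id=next_id, voxels=vox, validity_threshold=float(t),
                contacts=contacts, kind=classify_segment(touched_by[ci]),
            ))
            next_id += 1
    return segments


def segments_to_labels(segments: list[Segment], like: LabelVolume) -> LabelVolume:
    """Render detected segments into a label volume for visualization."""
    out = np.zeros(like.shape, dtype=np.int32)
    for seg in segments:
        out[seg.voxels] = seg.id
    return LabelVolume(out, like.voxel_size_nm, like.origin_nm)
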