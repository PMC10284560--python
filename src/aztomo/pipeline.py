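"""End-to-end orchestration: phantom or real volumes through segmentation,
morphometry, and condition-level statistics.

Stage order per synapse is fixed: analysis region -> hierarchical
segmentation -> contact classification -> geodesic lengths and AZ distances
-> per-vesicle counts -> layer profile -> per-synapse summaries. Study-level
runs first equalize tomogram orientations between conditions; the removed
synapses are excluded from every analysis step that involves tethers or
connectors (their distance and layer data are kept). All randomness is
seeded; a rerun from the manifest reproduces every table bit for bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats, hierseg, morpho, tomio
from .groupstats import ComparisonDesign, SynapseRecord
from .tomio import DensityVolume, LabelVolume

__all__ = ["RunConfig", "run_synapse", "run_study", "StudyResult"]


@dataclasses.dataclass
class RunConfig:
    """Analysis parameters with the published defaults.

    Zone bounds 45/75/250 nm partition the presynaptic space into proximal,
    intermediate and distal shells; tether classes split at 6/12/24 nm;
    tethering states split at 5/10 nm of AZ distance; all features are
    analyzed within 250 nm of the AZ membrane.
    """

    voxel_size_nm: float | None = None          # override volume header if set
    analysis_range_nm: float = 250.0
    zone_bounds_nm: tuple = morpho.ZONE_BOUNDS_NM
    tether_bounds_nm: tuple = morpho.TETHER_CLASS_BOUNDS_NM
    state_bounds_nm: tuple = morpho.STATE_BOUNDS_NM
    schedule_k: int = 24
    schedule_q: tuple = (0.02, 0.5)
    absolute_thresholds: tuple | None = None    # overrides the quantile ladder
    orientation_tolerance_deg: float = 5.0
    cdf_bandwidth_nm: float = 1.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for bounds in (self.zone_bounds_nm, self.tether_bounds_nm, self.state_bounds_nm):
            if any(b <= a for a, b in zip(bounds, bounds[1:])):
                raise ValueError(f"bounds must be strictly increasing: {bounds}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _schedule(config: RunConfig, density: DensityVolume, region) -> hierseg.ThresholdSchedule:
    if config.absolute_thresholds is not None:
        return hierseg.ThresholdSchedule.absolute(config.absolute_thresholds)
    try:
        return hierseg.ThresholdSchedule.quantile(
            density, region, k=config.schedule_k,
            q_min=config.schedule_q[0], q_max=config.schedule_q[1])
    except ValueError:
        # near-binary volume: quantile ladder collapses; fall back to linear
        try:
            return hierseg.ThresholdSchedule.linear(density, region, k=config.schedule_k)
        except ValueError:
            return None  # constant region density: nothing to segment


def run_synapse(density: DensityVolume, labels: LabelVolume, config: RunConfig,
                synapse_id: str = "synapse", condition: str = "",
                orientation_deg: float = 0.0,
                presynaptic_ref=None) -> SynapseRecord:
    """Analyze one synapse volume into a SynapseRecord with child tables."""
    if config.voxel_size_nm is not None:
        density = DensityVolume(density.data, config.voxel_size_nm,
                                density.origin_nm, density.structure_low)
        labels = LabelVolume(labels.data, config.voxel_size_nm, labels.origin_nm)
    labels.check_aligned(density)
    v = labels.voxel_size_nm

    region = hierseg.analysis_region(labels, config.analysis_range_nm, presynaptic_ref)
    schedule = _schedule(config, density, region)
    if schedule is None:
        segments = []
    else:
        segments = hierseg.connectivity_segmentation(density, labels, region, schedule)

    seg_rows = []
    for seg in segments:
        seg.length_nm = morpho.segment_length(seg, v)
        vids = seg.vesicle_ids
        seg_rows.append({
            "synapse_id": synapse_id, "segment_id": seg.id, "kind": seg.kind,
            "validity_threshold": seg.validity_threshold, "n_voxels": seg.n_voxels,
            "contacts": ";".join(str(i) for i in sorted(seg.contacted_ids)),
            "vesicle_a": vids[0] if vids else -1,
            "vesicle_b": vids[1] if len(vids) > 1 else -1,
            "length_nm": seg.length_nm,
            "length_class": (morpho.classify_tether(seg.length_nm, config.tether_bounds_nm)
                             if seg.kind == "tether" else ""),
        })
    seg_df = pd.DataFrame(seg_rows, columns=[
        "synapse_id", "segment_id", "kind", "validity_threshold", "n_voxels",
        "contacts", "vesicle_a", "vesicle_b", "length_nm", "length_class"])

    dist_df = morpho.vesicle_distances(labels)
    counts = morpho.count_bridges(dist_df["vesicle_id"], segments)
    ves = dist_df.merge(counts, on="vesicle_id", how="left")
    centers = []
    for vid in ves["vesicle_id"]:
        idx = np.nonzero(labels.data == vid)
        centers.append([float(a.mean()) for a in idx])
    if len(ves):
        ves[["center_z", "center_y", "center_x"]] = np.array(centers)
        # sphere-equivalent radius from the labeled voxel count
        ves["radius_nm"] = (3.0 * ves["n_voxels"] / (4.0 * np.pi)) ** (1.0 / 3.0) * v
        ves["state"] = ves["distance_to_az_nm"].map(
            lambda d: morpho.classify_state(d, config.state_bounds_nm))
        ves["distance_zone"] = ves["distance_to_az_nm"].map(
            lambda d: morpho.zone_of_distance(d, config.zone_bounds_nm))
    else:
        for col in ("center_z", "center_y", "center_x", "radius_nm", "state",
                    "distance_zone"):
            ves[col] = []
    ves.insert(0, "synapse_id", synapse_id)

    area = morpho.az_area(labels, presynaptic_ref=presynaptic_ref)
    record = SynapseRecord(
        synapse_id=synapse_id, condition=condition,
        orientation_deg=orientation_deg, az_area_nm2=area,
        vesicles=ves, segments=seg_df,
    )

    if config.outdir is not None:
        out = Path(config.outdir) / synapse_id
        profile = morpho.layer_profile(labels, config.analysis_range_nm,
                                       config.zone_bounds_nm, presynaptic_ref)
        out.mkdir(parents=True, exist_ok=True)
        tomio.write_results(out, vesicles=ves, segments=seg_df,
                            synapses=pd.DataFrame([_synapse_row(record)]))
        profile.layers.to_csv(out / "layers.csv", index=False)
        profile.zones.to_csv(out / "zones.csv", index=False)
        tomio.write_manifest(out, config.as_dict(), seeds={"seed": config.seed})
    return record


def _synapse_row(rec: SynapseRecord) -> dict:
    seg = rec.segments if rec.segments is not None else pd.DataFrame()
    return {
        "synapse_id": rec.synapse_id, "condition": rec.condition,
        "orientation_deg": rec.orientation_deg, "az_area_nm2": rec.az_area_nm2,
        "n_vesicles": len(rec.vesicles) if rec.vesicles is not None else 0,
        "n_proximal": rec.n_proximal,
        "surface_concentration_per_um2": rec.surface_concentration_per_um2,
        "n_tethers": int((seg["kind"] == "tether").sum()) if len(seg) else 0,
        "n_connectors": int((seg["kind"] == "connector").sum()) if len(seg) else 0,
    }


@dataclasses.dataclass
class StudyResult:
    synapses: pd.DataFrame
    comparisons: pd.DataFrame
    removals: list[tuple[str, str]]
    summaries: pd.DataFrame


def run_study(records: list[SynapseRecord], design: ComparisonDesign,
              config: RunConfig) -> StudyResult:
    """Study-level analysis over many synapses across conditions.

    Orientation equalization runs first; removed synapses are excluded from
    the tether/connector variables only, not from distance variables.
    """
    groups: dict[str, list[SynapseRecord]] = {}
    for rec in records:
        groups.setdefault(rec.condition, []).append(rec)
    removals = groupstats.equalize_orientation(groups, config.orientation_tolerance_deg)
    removed = set(removals)

    def bridge_recs(cond):
        return [r for r in groups[cond] if (cond, r.synapse_id) not in removed]

    def pooled(recs, table, col, mask_col=None, mask_val=None):
        out = []
        for r in recs:
            child = getattr(r, table)
            if child is None or not len(child):
                continue
            sel = child
            if mask_col is not None:
                sel = child[child[mask_col] == mask_val]
            out.append(np.asarray(sel[col], dtype=float))
        return np.concatenate(out) if out else np.array([])

    results = []
    b1, b2 = config.state_bounds_nm
    for ga, gb in design.pairs:
        da = pooled(groups[ga], "vesicles", "distance_to_az_nm",
                    "distance_zone", "proximal")
        db = pooled(groups[gb], "vesicles", "distance_to_az_nm",
                    "distance_zone", "proximal")
        if len(da) and len(db):
            results.append(groupstats.compare(
                "proximal_sv_distance_nm", ga, gb, da, db, "continuous", design))
            for bound, name in ((b2, "sv_distance_lt_10nm_fraction"),
                                (b1, "sv_distance_lt_5nm_fraction")):
                results.append(groupstats.compare_counts(
                    name, ga, gb,
                    int((da < bound).sum()), len(da),
                    int((db < bound).sum()), len(db), design))
        ra, rb = bridge_recs(ga), bridge_recs(gb)
        la = pooled(ra, "segments", "length_nm", "kind", "tether")
        lb = pooled(rb, "segments", "length_nm", "kind", "tether")
        if len(la) and len(lb):
            results.append(groupstats.compare(
                "tether_length_nm", ga, gb, la, lb, "continuous", design))
        for col in ("n_tethers", "n_connectors"):
            ca = pooled(ra, "vesicles", col, "distance_zone", "proximal")
            cb = pooled(rb, "vesicles", col, "distance_zone", "proximal")
            if len(ca) and len(cb):
                results.append(groupstats.compare(
                    f"{col}_per_proximal_sv", ga, gb, ca, cb, "count", design))

    comp_df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    syn_df = pd.DataFrame([_synapse_row(r) for r in records])
    summaries = groupstats.aggregate(
        records,
        per_structure={
            "proximal_sv_distance_nm": ("vesicles", "distance_to_az_nm"),
        },
        per_synapse_fractions={
            "surface_concentration_per_um2":
                lambda r: (r.surface_concentration_per_um2
                           if r.surface_concentration_per_um2 is not None
                           else float("nan")),
        },
    )
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        tomio.write_results(out, synapses=syn_df, comparisons=comp_df)
        summaries.to_csv(out / "summaries.csv", index=False)
        tomio.write_manifest(out, config.as_dict(),
                             seeds={"seed": config.seed},
                             removals=[list(r) for r in removals])
    return StudyResult(syn_df, comp_df, removals, summaries)
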