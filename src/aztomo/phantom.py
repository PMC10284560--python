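"""Ground-truthed synthetic tomogram phantoms.

Emulates the structures the pipeline measures: a plasma-membrane slab with an
active-zone (AZ) patch, spherical synaptic vesicles (SVs) at prescribed
distances from the AZ, and curved rod-like density bridges (tethers between an
SV and the AZ membrane, connectors between two SVs). Bridges exist only as
grayscale density, as in real tomograms; the label volume carries boundaries
only (membranes and vesicle spheres). Structures are darker (lower values)
than background, matching the cryo-ET contrast convention.

Geometry lives in nm with voxel centers at ``index * voxel_size_nm``; the
membrane slab face at ``membrane_top_nm`` is the AZ surface, and the
presynaptic space is at larger z.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tomio import (
    AZ_MEMBRANE,
    DensityVolume,
    LabelVolume,
    PLASMA_MEMBRANE,
    VESICLE_ID_START,
)

__all__ = [
    "VesicleSpec",
    "BridgeSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "add_noise",
    "apply_missing_wedge",
    "straight_tether",
    "arc_tether",
    "straight_connector",
    "sample_distance_mixture",
]


@dataclasses.dataclass
class VesicleSpec:
    """One planted vesicle: lateral position, radius, and AZ distance (all nm).

    The sphere center is placed at ``z = membrane_top + distance + radius`` so
    the planted surface-to-surface distance to the AZ face is exact by
    construction.
    """

    id: int
    y_nm: float
    x_nm: float
    radius_nm: float
    distance_to_az_nm: float

    def __post_init__(self) -> None:
        if self.id < VESICLE_ID_START:
            raise ValueError(f"vesicle ids start at {VESICLE_ID_START}, got {self.id}")
        if self.radius_nm <= 0:
            raise ValueError("vesicle radius must be > 0")
        if self.distance_to_az_nm < 0:
            raise ValueError("distance_to_AZ must be >= 0")


@dataclasses.dataclass
class BridgeSpec:
    """A rod-like density bridge rasterized as a tube around a polyline.

    ``points_nm`` lists the full polyline in (z, y, x) nm: the attachment
    point on the first surface, any interior waypoints, and the attachment
    point on the second surface. For tethers ``vesicle_ids`` holds one id (the
    other end contacts the AZ face); for connectors, two ids.
    """

    kind: str  # "tether" | "connector"
    vesicle_ids: tuple[int, ...]
    points_nm: np.ndarray
    rod_radius_nm: float

    def __post_init__(self) -> None:
        if self.kind not in ("tether", "connector"):
            raise ValueError(f"unknown bridge kind {self.kind!r}")
        n_expected = 1 if self.kind == "tether" else 2
        if len(self.vesicle_ids) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} vesicle id(s)")
        self.points_nm = np.asarray(self.points_nm, dtype=float)
        if self.points_nm.ndim != 2 or self.points_nm.shape[1] != 3 or len(self.points_nm) < 2:
            raise ValueError("points_nm must be an (n>=2, 3) polyline")

    @property
    def arc_length_nm(self) -> float:
        """True centerline length: polyline arc length between surface contacts."""
        return float(np.linalg.norm(np.diff(self.points_nm, axis=0), axis=1).sum())


@dataclasses.dataclass
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_nm: float = 1.4
    membrane_thickness_nm: float = 4.2
    membrane_top_nm: float = 14.0
    az_extent_nm: float = 100.0
    vesicles: list[VesicleSpec] = dataclasses.field(default_factory=list)
    tethers: list[BridgeSpec] = dataclasses.field(default_factory=list)
    connectors: list[BridgeSpec] = dataclasses.field(default_factory=list)
    density_contrast: float = 1.0      # foreground = background - contrast
    noise_sigma: float = 0.25          # default SNR (contrast/sigma) = 4
    wedge_halfangle_deg: float = 0.0   # 0 = no missing wedge
    rng_seed: int = 0

    @property
    def az_center_nm(self) -> tuple[float, float]:
        nz, ny, nx = self.volume_shape
        return ((ny - 1) * self.voxel_size_nm / 2.0, (nx - 1) * self.voxel_size_nm / 2.0)

    def vesicle(self, vid: int) -> VesicleSpec:
        for v in self.vesicles:
            if v.id == vid:
                return v
        raise KeyError(f"no vesicle with id {vid}")

    def vesicle_center_nm(self, vid: int) -> np.ndarray:
        v = self.vesicle(vid)
        return np.array(
            [self.membrane_top_nm + v.distance_to_az_nm + v.radius_nm, v.y_nm, v.x_nm]
        )

    @property
    def bridges(self) -> list[BridgeSpec]:
        return list(self.tethers) + list(self.connectors)


@dataclasses.dataclass
class GroundTruth:
    """Planted-structure table used to validate recovered measurements."""

    vesicles: pd.DataFrame  # vesicle_id, center_z/y/x_nm, radius_nm, distance_nm
    bridges: pd.DataFrame   # bridge_id, kind, vesicle_a, vesicle_b, length_nm, rod_radius_nm


# ---------------------------------------------------------------------------
# Bridge builders
# ---------------------------------------------------------------------------

def straight_tether(spec: PhantomSpec, vesicle_id: int, rod_radius_nm: float = 1.5) -> BridgeSpec:
    """Shortest straight tether: from the bottom of the SV to the AZ face."""
    c = spec.vesicle_center_nm(vesicle_id)
    r = spec.vesicle(vesicle_id).radius_nm
    p_sv = np.array([c[0] - r, c[1], c[2]])
    p_az = np.array([spec.membrane_top_nm, c[1], c[2]])
    return BridgeSpec("tether", (vesicle_id,), np.vstack([p_sv, p_az]), rod_radius_nm)


def arc_tether(spec: PhantomSpec, vesicle_id: int, rod_radius_nm: float = 1.5,
               bulge_axis: str = "x", n_points: int = 33) -> BridgeSpec:
    """Semicircular tether: arc length = pi/2 * chord, so geodesic > chord."""
    c = spec.vesicle_center_nm(vesicle_id)
    r = spec.vesicle(vesicle_id).radius_nm
    a = np.array([c[0] - r, c[1], c[2]])               # on SV surface
    b = np.array([spec.membrane_top_nm, c[1], c[2]])   # on AZ face
    mid = (a + b) / 2.0
    h = np.linalg.norm(b - a) / 2.0
    u = (b - a) / (2.0 * h)
    w = np.array([0.0, 1.0, 0.0]) if bulge_axis == "y" else np.array([0.0, 0.0, 1.0])
    t = np.linspace(0.0, np.pi, n_points)
    pts = mid[None, :] - h * np.cos(t)[:, None] * u[None, :] + h * np.sin(t)[:, None] * w[None, :]
    return BridgeSpec("tether", (vesicle_id,), pts, rod_radius_nm)


def oblique_tether(spec: PhantomSpec, vesicle_id: int, az_offset_nm=(0.0, 0.0),
                   rod_radius_nm: float = 1.5) -> BridgeSpec:
    """Straight tether to an AZ point laterally offset from the SV axis.

    Lets several tethers attach one vesicle at separated points, as multiply
    tethered vesicles do.
    """
    c = spec.vesicle_center_nm(vesicle_id)
    r = spec.vesicle(vesicle_id).radius_nm
    p_az = np.array([spec.membrane_top_nm, c[1] + az_offset_nm[0], c[2] + az_offset_nm[1]])
    u = p_az - c
    p_sv = c + r * u / np.linalg.norm(u)
    return BridgeSpec("tether", (vesicle_id,), np.vstack([p_sv, p_az]), rod_radius_nm)


def side_tether(spec: PhantomSpec, vesicle_id: int, offset_nm=(0.0, 8.0),
                rod_radius_nm: float = 1.5) -> BridgeSpec:
    """Vertical tether dropping from an off-axis point of the SV surface.

    Lets several tethers attach one vesicle at laterally separated points.
    """
    c = spec.vesicle_center_nm(vesicle_id)
    r = spec.vesicle(vesicle_id).radius_nm
    dy, dx = offset_nm
    lat = float(np.hypot(dy, dx))
    if lat >= r:
        raise ValueError("side tether offset must be smaller than the SV radius")
    p_sv = np.array([c[0] - np.sqrt(r ** 2 - lat ** 2), c[1] + dy, c[2] + dx])
    p_az = np.array([spec.membrane_top_nm, p_sv[1], p_sv[2]])
    return BridgeSpec("tether", (vesicle_id,), np.vstack([p_sv, p_az]), rod_radius_nm)


def bent_tether(spec: PhantomSpec, vesicle_id: int, corner_offset_nm=(7.0, 0.0, 10.0),
                rod_radius_nm: float = 1.5) -> BridgeSpec:
    """L-shaped tether through a corner waypoint: curved in the sense that its
    geodesic length exceeds its end-to-end chord.

    The corner sits at ``(membrane_top + dz, sv_y + dy, sv_x + dx)``; one leg
    drops vertically to the AZ face, the other runs to the nearest point of
    the SV surface.
    """
    c = spec.vesicle_center_nm(vesicle_id)
    r = spec.vesicle(vesicle_id).radius_nm
    dz, dy, dx = corner_offset_nm
    corner = np.array([spec.membrane_top_nm + dz, c[1] + dy, c[2] + dx])
    p_az = np.array([spec.membrane_top_nm, corner[1], corner[2]])
    u = corner - c
    p_sv = c + r * u / np.linalg.norm(u)
    return BridgeSpec("tether", (vesicle_id,), np.vstack([p_sv, corner, p_az]),
                      rod_radius_nm)


def straight_connector(spec: PhantomSpec, id_a: int, id_b: int,
                       rod_radius_nm: float = 1.5) -> BridgeSpec:
    """Straight connector along the line of centers, surface to surface."""
    ca, cb = spec.vesicle_center_nm(id_a), spec.vesicle_center_nm(id_b)
    ra, rb = spec.vesicle(id_a).radius_nm, spec.vesicle(id_b).radius_nm
    u = cb - ca
    d = np.linalg.norm(u)
    if d <= ra + rb:
        raise ValueError(f"vesicles {id_a} and {id_b} touch; no connector gap")
    u = u / d
    return BridgeSpec("connector", (id_a, id_b),
                      np.vstack([ca + ra * u, cb - rb * u]), rod_radius_nm)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _coordinate_grids(shape, voxel_size_nm):
    nz, ny, nx = shape
    z = np.arange(nz)[:, None, None] * voxel_size_nm
    y = np.arange(ny)[None, :, None] * voxel_size_nm
    x = np.arange(nx)[None, None, :] * voxel_size_nm
    return z, y, x


def _rasterize_tube(mask: np.ndarray, points_nm: np.ndarray, radius_nm: float,
                    voxel_size_nm: float) -> None:
    """OR into ``mask`` all voxels within radius of the polyline (spherical brush)."""
    v = voxel_size_nm
    for a, b in zip(points_nm[:-1], points_nm[1:]):
        lo = np.floor((np.minimum(a, b) - radius_nm) / v).astype(int)
        hi = np.ceil((np.maximum(a, b) + radius_nm) / v).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, mask.shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(l, h) * v for l, h in zip(lo, hi)),
                                 indexing="ij")
        p = np.stack([zz, yy, xx], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            dist = np.linalg.norm(p - a, axis=-1)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            dist = np.linalg.norm(p - proj, axis=-1)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= dist <= radius_nm


def _validate(spec: PhantomSpec) -> None:
    v = spec.voxel_size_nm
    if v <= 0:
        raise ValueError("voxel size must be > 0")
    # vesicle pairwise overlap
    for i, a in enumerate(spec.vesicles):
        for b in spec.vesicles[i + 1:]:
            ca, cb = spec.vesicle_center_nm(a.id), spec.vesicle_center_nm(b.id)
            if np.linalg.norm(cb - ca) < a.radius_nm + b.radius_nm:
                raise ValueError(
                    f"vesicles overlap: ids ({a.id}, {b.id}) at centers {ca} / {cb}"
                )
    # vesicles above membrane by construction (distance >= 0 enforced in VesicleSpec)
    for br in spec.bridges:
        if br.rod_radius_nm < v:
            raise ValueError(
                f"bridge rod radius {br.rod_radius_nm} nm < 1 voxel ({v} nm)"
            )
        ends = [br.points_nm[0], br.points_nm[-1]]
        if br.kind == "tether":
            vid = br.vesicle_ids[0]
            c = spec.vesicle_center_nm(vid)
            r = spec.vesicle(vid).radius_nm
            on_sv = [abs(np.linalg.norm(e - c) - r) <= v for e in ends]
            on_az = [abs(e[0] - spec.membrane_top_nm) <= v for e in ends]
            if not ((on_sv[0] and on_az[1]) or (on_sv[1] and on_az[0])):
                raise ValueError(
                    f"tether endpoints not on SV {vid} surface and AZ face "
                    f"(beyond 1 voxel): {ends}"
                )
        else:
            for e, vid in zip(ends, br.vesicle_ids):
                c = spec.vesicle_center_nm(vid)
                r = spec.vesicle(vid).radius_nm
                if abs(np.linalg.norm(e - c) - r) > v:
                    raise ValueError(
                        f"connector endpoint {e} not on vesicle {vid} surface"
                    )


def generate_phantom(spec: PhantomSpec) -> tuple[DensityVolume, LabelVolume, GroundTruth]:
    """Rasterize a PhantomSpec into (density, labels, ground truth).

    The label volume holds boundaries only (AZ membrane 1, other plasma
    membrane 2, vesicles >= 10); bridges appear only in the density.
    Identical specs (including seed) give bit-identical output.
    """
    _validate(spec)
    shape = tuple(spec.volume_shape)
    v = spec.voxel_size_nm
    z, y, x = _coordinate_grids(shape, v)

    labels = np.zeros(shape, dtype=np.int32)
    mem = (z > spec.membrane_top_nm - spec.membrane_thickness_nm) & (z <= spec.membrane_top_nm)
    mem = np.broadcast_to(mem, shape) & np.ones(shape, bool)
    cy, cx = spec.az_center_nm
    az_lateral = (np.abs(y - cy) <= spec.az_extent_nm / 2.0) & \
                 (np.abs(x - cx) <= spec.az_extent_nm / 2.0)
    az_lateral = np.broadcast_to(az_lateral, shape)
    labels[mem & az_lateral] = AZ_MEMBRANE
    labels[mem & ~az_lateral] = PLASMA_MEMBRANE

    foreground = mem.copy()
    shell_th = spec.membrane_thickness_nm
    vrows = []
    for ves in spec.vesicles:
        c = spec.vesicle_center_nm(ves.id)
        dist = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
        sphere = dist <= ves.radius_nm
        if not sphere.any():
            raise ValueError(f"vesicle {ves.id} rasterizes to zero voxels")
        labels[sphere] = ves.id
        foreground |= sphere & (dist >= ves.radius_nm - shell_th)
        vrows.append({
            "vesicle_id": ves.id,
            "center_z_nm": c[0], "center_y_nm": c[1], "center_x_nm": c[2],
            "radius_nm": ves.radius_nm, "distance_nm": ves.distance_to_az_nm,
        })

    brows = []
    for k, br in enumerate(spec.bridges):
        _rasterize_tube(foreground, br.points_nm, br.rod_radius_nm, v)
        ids = br.vesicle_ids
        brows.append({
            "bridge_id": k, "kind": br.kind,
            "vesicle_a": ids[0], "vesicle_b": ids[1] if len(ids) > 1 else -1,
            "length_nm": br.arc_length_nm, "rod_radius_nm": br.rod_radius_nm,
        })

    background_value = 1.0
    density = np.full(shape, background_value, dtype=np.float32)
    density[foreground] = background_value - spec.density_contrast

    vol = DensityVolume(density, v, structure_low=True)
    if spec.noise_sigma > 0:
        vol = add_noise(vol, spec.noise_sigma, spec.rng_seed)
    if spec.wedge_halfangle_deg > 0:
        vol = apply_missing_wedge(vol, spec.wedge_halfangle_deg)

    gt = GroundTruth(
        vesicles=pd.DataFrame(vrows, columns=["vesicle_id", "center_z_nm", "center_y_nm",
                                              "center_x_nm", "radius_nm", "distance_nm"]),
        bridges=pd.DataFrame(brows, columns=["bridge_id", "kind", "vesicle_a", "vesicle_b",
                                             "length_nm", "rod_radius_nm"]),
    )
    return vol, LabelVolume(labels, v), gt


# ---------------------------------------------------------------------------
# Degradations
# ---------------------------------------------------------------------------

def add_noise(vol: DensityVolume, sigma: float, seed: int) -> DensityVolume:
    """Additive Gaussian noise with a fixed seed; sigma=0 returns the input unchanged."""
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return vol
    rng = np.random.default_rng(seed)
    noisy = vol.data.astype(np.float32) + rng.normal(0.0, sigma, vol.data.shape).astype(np.float32)
    return DensityVolume(noisy, vol.voxel_size_nm, vol.origin_nm, vol.structure_low)


def apply_missing_wedge(vol: DensityVolume, halfangle_deg: float,
                        tilt_axis: str = "y") -> DensityVolume:
    """Zero Fourier coefficients in the missing wedge of a +-halfangle tilt range.

    With the beam along z and the tilt axis in-plane, a tilt series covering
    +-halfangle leaves unmeasured the wedge of directions closer than
    (90 - halfangle) degrees to the z frequency axis (DC excluded). halfangle
    is clamped at 90 (full coverage: volume unchanged).
    """
    if not 0 < halfangle_deg:
        raise ValueError("halfangle must be in (0, 90]")
    halfangle_deg = min(halfangle_deg, 90.0)
    if tilt_axis not in ("x", "y"):
        raise ValueError(f"degenerate tilt axis {tilt_axis!r}: must be 'x' or 'y' (beam is z)")
    nz, ny, nx = vol.data.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    if tilt_axis == "y":
        kp = np.fft.fftfreq(nx)[None, None, :]
    else:
        kp = np.fft.fftfreq(ny)[None, :, None]
    wedge_half = np.deg2rad(90.0 - halfangle_deg)
    ang = np.arctan2(np.abs(kp), np.abs(kz))  # 0 on the kz axis
    missing = ang < wedge_half - 1e-12
    missing &= ~((np.abs(kz) == 0) & (np.abs(kp) == 0))  # keep DC plane line
    ft = np.fft.fftn(vol.data)
    ft[np.broadcast_to(missing, ft.shape)] = 0.0
    out = np.fft.ifftn(ft).real.astype(np.float32)
    return DensityVolume(out, vol.voxel_size_nm, vol.origin_nm, vol.structure_low)


# ---------------------------------------------------------------------------
# Reference phantom
# ---------------------------------------------------------------------------

def validation_phantom(noise_sigma: float = 0.0, seed: int = 0,
                       wedge_halfangle_deg: float = 0.0) -> PhantomSpec:
    """A full-featured phantom exercising every measured quantity.

    128^3 voxels at 1.4 nm: six vesicles spanning AZ distances 3.6-17.4 nm
    (covering all three tethering states), eight tethers — one vesicle
    multiply tethered, one tether L-shaped so its geodesic exceeds its chord
    — and four connectors. Membrane and vesicle surfaces are placed between
    voxel centers, keeping voxelization bias in planted distances and lengths
    near half a voxel.
    """
    spec = PhantomSpec(
        volume_shape=(128, 128, 128), voxel_size_nm=1.4,
        membrane_top_nm=13.3, membrane_thickness_nm=4.2, az_extent_nm=140.0,
        noise_sigma=noise_sigma, wedge_halfangle_deg=wedge_halfangle_deg,
        rng_seed=seed,
    )
    r = 15.0
    placements = [  # (id, y_nm, x_nm, distance_nm)
        (10, 50.0, 45.0, 3.6),
        (11, 50.0, 90.0, 5.0),
        (12, 50.0, 135.0, 7.8),
        (13, 125.0, 45.0, 9.9),
        (14, 125.0, 90.0, 14.1),
        (15, 125.0, 135.0, 17.4),
    ]
    for vid, y, x, d in placements:
        spec.vesicles.append(VesicleSpec(vid, y, x, r, d))
    spec.tethers.append(straight_tether(spec, 10))
    spec.tethers.append(straight_tether(spec, 11))
    spec.tethers.append(oblique_tether(spec, 12, az_offset_nm=(4.0, -5.0)))
    spec.tethers.append(straight_tether(spec, 13))
    spec.tethers.append(bent_tether(spec, 13, corner_offset_nm=(8.0, 0.0, -16.0)))
    spec.tethers.append(straight_tether(spec, 14))
    # bent tether: its geodesic strictly exceeds its end-to-end chord
    spec.tethers.append(bent_tether(spec, 14, corner_offset_nm=(8.0, 0.0, 14.0)))
    spec.tethers.append(oblique_tether(spec, 15, az_offset_nm=(-8.0, 6.0)))
    spec.connectors.append(straight_connector(spec, 10, 11))
    spec.connectors.append(straight_connector(spec, 11, 12))
    spec.connectors.append(straight_connector(spec, 13, 14))
    spec.connectors.append(straight_connector(spec, 14, 15))
    return spec


# ---------------------------------------------------------------------------
# Condition-level distance sampling
# ---------------------------------------------------------------------------

def sample_distance_mixture(n: int, peaks_nm, weights=None, sd_nm: float = 2.0,
                            rng=None) -> np.ndarray:
    """Sample SV-to-AZ distances from a Gaussian mixture truncated at zero.

    Emulates condition-level distance distributions whose histograms peak at
    the given modes (e.g. ~6 nm for a tethering-competent condition, ~16 nm
    for a tethering-deficient one), without rasterizing volumes.
    """
    rng = np.random.default_rng(rng)
    peaks = np.atleast_1d(np.asarray(peaks_nm, dtype=float))
    if weights is None:
        weights = np.full(len(peaks), 1.0 / len(peaks))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(peaks), size=n, p=weights)
    out = rng.normal(peaks[comp], sd_nm)
    while np.any(out < 0):  # resample below-zero draws (distances are nonnegative)
        bad = out < 0
        out[bad] = rng.normal(peaks[comp[bad]], sd_nm)
    return out
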