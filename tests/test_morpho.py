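import numpy as np
import pytest

from aztomo import morpho, tomio
from aztomo.hierseg import Segment
from aztomo.morpho import (
    ModelEnvelope,
    az_area,
    classify_state,
    classify_tether,
    count_bridges,
    disk_to_sphere,
    distance_to_az,
    layer_profile,
    model_span,
    segment_length,
    surface_concentration,
    tether_accommodates,
    zone_of_distance,
)

from oracles import geodesic_oracle


def digital_circle(radius, center=(16.0, 16.0), z=5, jitter=None, n=64, rng=None):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    y = center[0] + radius * np.sin(t)
    x = center[1] + radius * np.cos(t)
    if jitter is not None:
        y = y + rng.uniform(-jitter, jitter, n)
        x = x + rng.uniform(-jitter, jitter, n)
    return np.column_stack([np.full(n, z), np.round(y), np.round(x)]).astype(int)


def rod_segment(gap, axis_len=None, contact_width=1):
    """A straight 1-voxel rod spanning a gap between two boundary slabs."""
    n = gap if axis_len is None else axis_len
    vox = tuple(np.array(a) for a in zip(*[(z, 5, 5) for z in range(1, n + 1)]))
    contacts = {
        1: tuple(np.array(a) for a in zip(*[(1, 5, 5)])),
        10: tuple(np.array(a) for a in zip(*[(n, 5, 5)])),
    }
    return Segment(id=1000, voxels=vox, validity_threshold=0.5,
                   contacts=contacts, kind="tether")


class TestDiskToSphere:
    def test_perfect_circle_recovered(self):
        contour = digital_circle(10.0)
        center, radius_nm, sphere = disk_to_sphere(contour, 1.0, (12, 32, 32))
        assert radius_nm == pytest.approx(10.0, abs=0.5)
        assert center[1] == pytest.approx(16.0, abs=0.2)
        assert center[2] == pytest.approx(16.0, abs=0.2)
        assert center[0] == 5

    def test_jittered_contour_within_one_voxel(self):
        rng = np.random.default_rng(0)
        contour = digital_circle(8.0, jitter=1.0, rng=rng)
        _, radius_nm, _ = disk_to_sphere(contour, 1.0, (12, 32, 32))
        assert radius_nm == pytest.approx(8.0, abs=1.0)

    def test_collinear_trace_rejected(self):
        pts = np.array([[5, 10, x] for x in range(10, 20)])
        with pytest.raises(ValueError, match="collinear"):
            disk_to_sphere(pts, 1.0, (12, 32, 32))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            disk_to_sphere(np.array([[5, 1, 1], [5, 2, 2]]), 1.0, (8, 8, 8))

    def test_radius_scales_with_voxel_size(self):
        contour = digital_circle(10.0)
        _, radius_nm, _ = disk_to_sphere(contour, 1.4, (12, 32, 32))
        assert radius_nm == pytest.approx(14.0, abs=0.7)


class TestDistanceToAz:
    def test_touching_sphere_is_zero(self):
        az = np.zeros((20, 16, 16), bool)
        az[5] = True
        ves = (np.array([6]), np.array([8]), np.array([8]))
        assert distance_to_az(ves, az, 1.0) == 0.0

    def test_planar_gap_within_one_voxel_diagonal(self):
        """Sphere surface 4 nm above a plane at 1 nm voxels."""
        az = np.zeros((24, 20, 20), bool)
        az[5] = True
        z, y, x = np.indices((24, 20, 20))
        sphere = (z - 15.0) ** 2 + (y - 10.0) ** 2 + (x - 10.0) ** 2 <= 36.0
        d = distance_to_az(np.nonzero(sphere), az, 1.0)
        assert d == pytest.approx(4.0, abs=np.sqrt(3))

    def test_phantom_planted_distances_recovered(self, small_spec):
        from aztomo.phantom import generate_phantom

        _, labels, gt = generate_phantom(small_spec)
        df = morpho.vesicle_distances(labels)
        merged = df.merge(gt.vesicles, on="vesicle_id")
        err = (merged["distance_to_az_nm"] - merged["distance_nm"]).abs()
        assert (err <= 1.4 * np.sqrt(3)).all()


class TestSegmentLength:
    def test_straight_rod_matches_contact_span(self):
        """10-voxel rod at 1 nm voxels: contact-center to contact-center = 9."""
        seg = rod_segment(10)
        assert segment_length(seg, 1.0) == pytest.approx(9.0)

    def test_shared_contact_voxel_gives_zero(self):
        vox = (np.array([3]), np.array([5]), np.array([5]))
        seg = Segment(1000, vox, 0.5, {1: vox, 10: vox}, "tether")
        assert segment_length(seg, 1.0) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dijkstra_oracle_on_random_blobs(self, seed):
        """Geodesic equals an independent networkx Dijkstra on irregular segments."""
        rng = np.random.default_rng(seed)
        blob = {(0, 0, 0)}
        while len(blob) < 60:
            z, y, x = rng.integers(0, 8, 3)
            if any((abs(z - b[0]) <= 1 and abs(y - b[1]) <= 1 and abs(x - b[2]) <= 1)
                   for b in blob):
                blob.add((int(z), int(y), int(x)))
        pts = sorted(blob)
        vox = tuple(np.array(a) for a in zip(*pts))
        a_pts = pts[:3]
        b_pts = pts[-3:]
        contacts = {1: tuple(np.array(a) for a in zip(*a_pts)),
                    10: tuple(np.array(a) for a in zip(*b_pts))}
        seg = Segment(1000, vox, 0.5, contacts, "tether")
        expected = geodesic_oracle(vox, contacts[1], contacts[10], 1.0)
        assert segment_length(seg, 1.0) == pytest.approx(expected, abs=1e-9)

    def test_curved_segment_longer_than_chord(self, noiseless_phantom):
        """The phantom's bent tether: geodesic strictly exceeds the straight
        distance between its contact sets (curvature contributes to length)."""
        from aztomo import hierseg, pipeline
        from scipy.spatial.distance import cdist

        spec, density, labels, gt = noiseless_phantom
        region = hierseg.analysis_region(labels, 250.0)
        schedule = pipeline._schedule(pipeline.RunConfig(), density, region)
        segs = hierseg.connectivity_segmentation(density, labels, region, schedule)
        v13 = [s for s in segs if s.kind == "tether" and s.vesicle_ids[0] == 13]
        lengths = {segment_length(s, 1.4): s for s in v13}
        bent = lengths[max(lengths)]
        a, b = morpho._segment_contact_sets(bent)
        chord = cdist(np.stack(a, 1) * 1.4, np.stack(b, 1) * 1.4).min()
        assert max(lengths) > chord


class TestClassification:
    @pytest.mark.parametrize("length,expected", [
        (0.0, "short"), (5.5, "short"),
        (6.0, "intermediate"), (11.99, "intermediate"),
        (12.0, "long"), (23.99, "long"),
        (24.0, "extra"), (30.0, "extra"),
    ])
    def test_tether_length_classes_left_closed(self, length, expected):
        assert classify_tether(length) == expected

    @pytest.mark.parametrize("d,expected", [
        (0.0, "SNAP25-dependent"), (4.0, "SNAP25-dependent"),
        (5.0, "intermediate"), (7.0, "intermediate"), (9.99, "intermediate"),
        (10.0, "Munc13-independent"), (40.0, "Munc13-independent"),
    ])
    def test_state_classes_left_closed(self, d, expected):
        assert classify_state(d) == expected

    @pytest.mark.parametrize("d,expected", [
        (0.0, "proximal"), (44.9, "proximal"), (45.0, "intermediate"),
        (74.9, "intermediate"), (75.0, "distal"), (249.0, "distal"),
        (250.0, "beyond"),
    ])
    def test_zone_classes(self, d, expected):
        assert zone_of_distance(d) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_tether(-1.0)
        with pytest.raises(ValueError):
            classify_state(-0.1)


class TestCountBridges:
    def _seg(self, kind, *vids):
        contacts = {v: (np.array([0]), np.array([0]), np.array([0])) for v in vids}
        if kind == "tether":
            contacts[1] = (np.array([0]), np.array([0]), np.array([0]))
        return Segment(1000, (np.array([0]), np.array([0]), np.array([0])),
                       0.5, contacts, kind)

    def test_three_tethers_marks_multiply_tethered(self):
        segs = [self._seg("tether", 10)] * 3
        df = count_bridges([10, 11], segs).set_index("vesicle_id")
        assert df.loc[10, "n_tethers"] == 3
        assert bool(df.loc[10, "multiply_tethered"])
        assert not bool(df.loc[11, "tethered"])

    def test_connector_increments_both_vesicles(self):
        df = count_bridges([10, 11], [self._seg("connector", 10, 11)])
        assert df["n_connectors"].tolist() == [1, 1]

    def test_no_segments_all_zero(self):
        df = count_bridges([10, 11, 12], [])
        assert (df[["n_tethers", "n_connectors"]].to_numpy() == 0).all()


class TestLayerProfile:
    def test_no_vesicles_phi_zero(self):
        labels = np.zeros((30, 12, 12), np.int32)
        labels[5] = tomio.AZ_MEMBRANE
        lv = tomio.LabelVolume(labels, 1.0)
        prof = layer_profile(lv, 20.0, presynaptic_ref=(20, 6, 6))
        assert (prof.layers["phi"] == 0).all()

    def test_conservation_exact(self, small_spec):
        from aztomo.phantom import generate_phantom

        _, labels, _ = generate_phantom(small_spec)
        prof = layer_profile(labels, 250.0)
        total_sv = int((labels.data >= tomio.VESICLE_ID_START).sum())
        assert int(prof.layers["sv_voxels"].sum()) == total_sv
        assert int(prof.zones["sv_voxels"].sum()) == total_sv
        assert ((prof.layers["phi"] >= 0) & (prof.layers["phi"] <= 1)).all()

    def test_sphere_straddling_zone_boundary_splits(self):
        """A sphere across the 45 nm bound: proximal+intermediate counts sum
        to the whole sphere."""
        labels = np.zeros((80, 40, 40), np.int32)
        labels[5] = tomio.AZ_MEMBRANE
        z, y, x = np.indices((80, 40, 40))
        sphere = (z - 50) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 100
        labels[sphere] = 10
        lv = tomio.LabelVolume(labels, 1.0)
        prof = layer_profile(lv, 250.0)
        zones = prof.zones.set_index("zone")
        assert zones.loc["proximal", "sv_voxels"] > 0
        assert zones.loc["intermediate", "sv_voxels"] > 0
        assert int(prof.zones["sv_voxels"].sum()) == int(sphere.sum())


class TestAzArea:
    def test_surface_concentration_arithmetic(self):
        assert surface_concentration(5, 0.05 * 1e6) == pytest.approx(100.0)
        assert surface_concentration(0, 1e4) == 0.0
        with pytest.raises(ValueError):
            surface_concentration(1, 0.0)

    def test_planar_patch_area(self, small_spec):
        from aztomo.phantom import generate_phantom

        _, labels, _ = generate_phantom(small_spec)
        area = az_area(labels)
        expected = small_spec.az_extent_nm ** 2
        assert area == pytest.approx(expected, rel=0.05)

    def test_face_counting_fallback_planar(self, small_spec):
        from aztomo.phantom import generate_phantom

        _, labels, _ = generate_phantom(small_spec)
        area = az_area(labels, method="faces", corrected=False)
        assert area == pytest.approx(small_spec.az_extent_nm ** 2, rel=0.05)

    def test_spherical_cap_area(self):
        """Curved AZ: marching-cubes estimate within 10% of the analytic cap."""
        shape = (60, 60, 60)
        z, y, x = np.indices(shape, dtype=float)
        r_out = 25.0
        c = (-10.0, 30.0, 30.0)
        rad = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
        shell = (rad >= r_out - 3) & (rad <= r_out)
        labels = np.zeros(shape, np.int32)
        labels[shell] = tomio.AZ_MEMBRANE
        lv = tomio.LabelVolume(labels, 1.0)
        area = az_area(lv, presynaptic_ref=(50, 30, 30))
        # cap above z=0 plane: height h = r_out + c_z
        h = r_out + c[0]
        analytic = 2 * np.pi * r_out * h
        assert area == pytest.approx(analytic, rel=0.10)


class TestModelSpan:
    def _two_atom_structure(self, d_angstrom):
        import biotite.structure as struc

        atoms = struc.AtomArray(2)
        atoms.coord = np.array([[0, 0, 0], [d_angstrom, 0, 0]], np.float32)
        atoms.chain_id = np.array(["A", "A"])
        atoms.res_id = np.array([1, 2])
        atoms.res_name = np.array(["ALA", "ALA"])
        atoms.atom_name = np.array(["CA", "CA"])
        atoms.element = np.array(["C", "C"])
        return atoms

    def test_two_atoms_13_angstrom_apart(self):
        atoms = self._two_atom_structure(13.0)
        span = model_span(atoms, {"res_ids": [1]}, {"res_ids": [2]})
        assert span == pytest.approx(1.3)

    def test_identical_selections_zero(self):
        atoms = self._two_atom_structure(13.0)
        assert model_span(atoms, {"res_ids": [1]}, {"res_ids": [1]}) == 0.0

    def test_empty_selection_rejected(self):
        atoms = self._two_atom_structure(13.0)
        with pytest.raises(ValueError, match="empty"):
            model_span(atoms, {"res_ids": [99]}, {"res_ids": [1]})

    def test_synthetic_rod_model_span_matches_bruteforce(self):
        """Span of the synthetic stand-in equals a brute-force pairwise
        minimum computed here from the same coordinates."""
        from aztomo.structures import (
            SYNTHETIC_C2B_RANGE,
            SYNTHETIC_CTERM_RANGE,
            synthetic_munc13_like_model,
        )

        atoms = synthetic_munc13_like_model()
        span = model_span(atoms, {"res_range": SYNTHETIC_C2B_RANGE},
                          {"res_range": SYNTHETIC_CTERM_RANGE})
        a = atoms.coord[(atoms.res_id >= SYNTHETIC_C2B_RANGE[0])
                        & (atoms.res_id <= SYNTHETIC_C2B_RANGE[1])]
        b = atoms.coord[(atoms.res_id >= SYNTHETIC_CTERM_RANGE[0])
                        & (atoms.res_id <= SYNTHETIC_CTERM_RANGE[1])]
        best = min(float(np.linalg.norm(p - q)) for p in a for q in b)
        assert span == pytest.approx(best / 10.0, abs=1e-5)

    def test_pdb_file_round_trip(self, tmp_path):
        import biotite.structure.io.pdb as pdb

        atoms = self._two_atom_structure(26.0)
        f = pdb.PDBFile()
        f.set_structure(atoms)
        f.write(str(tmp_path / "m.pdb"))
        span = model_span(tmp_path / "m.pdb", {"res_ids": [1]}, {"res_ids": [2]})
        assert span == pytest.approx(2.6)


class TestTetherAccommodates:
    def test_short_straight_tether_rejects_13nm_span(self):
        seg = rod_segment(6)
        assert not tether_accommodates(seg, ModelEnvelope(13.0), 1.0)

    def test_long_tether_accepts(self):
        seg = rod_segment(16)
        assert tether_accommodates(seg, ModelEnvelope(13.0), 1.0)

    def test_l_shaped_tether_curvature_permits(self):
        """~15 nm geodesic but ~12 nm chord: the screen passes on geodesic
        length even though the end-to-end chord is below the model span."""
        leg1 = [(z, 2, 2) for z in range(1, 8)]
        leg2 = [(7, y, 2) for y in range(3, 13)]
        pts = leg1 + leg2
        vox = tuple(np.array(a) for a in zip(*pts))
        contacts = {1: tuple(np.array(a) for a in zip(*[(1, 2, 2)])),
                    10: tuple(np.array(a) for a in zip(*[(7, 12, 2)]))}
        seg = Segment(1000, vox, 0.5, contacts, "tether")
        geo = segment_length(seg, 1.0)
        chord = np.linalg.norm(np.array([1, 2, 2]) - np.array([7, 12, 2]))
        assert geo == pytest.approx(5 + 9 + np.sqrt(2))
        assert chord < 13.0 <= geo
        assert tether_accommodates(seg, ModelEnvelope(13.0), 1.0)
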