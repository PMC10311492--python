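import numpy as np
import pytest
from scipy.spatial import cKDTree

from fracmap.io import LabeledVolume
from fracmap.mapping import (FrequencyMap, accumulate_frequency, colorize,
                             comminution_footprint, extract_interface,
                             measure_zone_extent, project_to_template,
                             LINE_SCHEME, COMMINUTION_SCHEME)
from fracmap.reduction import RigidTransform
from oracles import all_pairs_interface, random_label_grid


def _vol(labels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return LabeledVolume(labels=np.asarray(labels, dtype=np.int16),
                         spacing=spacing, origin=origin)


class TestExtractInterface:
    def test_plane_cut_cube(self):
        grid = np.ones((10, 10, 10), dtype=np.int16)
        grid[:, :, 5:] = 2
        iface = extract_interface(_vol(grid))
        # interface = the two voxel layers either side of the cut
        expected = np.zeros_like(grid, dtype=bool)
        expected[:, :, 4:6] = True
        assert np.array_equal(iface.interface_mask, expected)
        # surface line points: the cut's perimeter on the cube's outer shell
        pts = iface.surface_line_points
        on_boundary = ((pts[:, 0] % 9 == 0) | (pts[:, 1] % 9 == 0))
        assert on_boundary.all()
        assert set(np.unique(pts[:, 2])) == {4.0, 5.0}

    def test_single_label_warns_empty(self):
        with pytest.warns(UserWarning, match="single-label"):
            iface = extract_interface(_vol(np.ones((5, 5, 5))))
        assert len(iface.surface_line_points) == 0
        assert not iface.interface_mask.any()

    def test_oblique_cylinder_cut_matches_analytic_ellipse(self):
        """A cylinder cut by an oblique plane traces a line within one voxel of
        the analytic plane-cylinder intersection."""
        n = 40
        ii, jj, kk = np.mgrid[:n, :n, :n]
        x, y, z = ii - 19.5, jj - 19.5, kk - 19.5
        grid = np.zeros((n, n, n), dtype=np.int16)
        grid[x**2 + y**2 <= 144] = 1
        plane = 0.4 * x + z  # normal (0.4, 0, 1) through center
        grid[(grid > 0) & (plane >= 0)] = 2
        iface = extract_interface(_vol(grid))
        pts = iface.surface_line_points
        xc, yc, zc = pts[:, 0] - 19.5, pts[:, 1] - 19.5, pts[:, 2] - 19.5
        # on the cylinder wall and on the plane, within a voxel
        assert np.abs(np.sqrt(xc**2 + yc**2) - 12).max() <= 1.5
        assert np.abs(0.4 * xc + zc).max() / np.sqrt(1.16) <= 1.5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(77)
        import warnings
        for _ in range(30):
            grid = random_label_grid(rng, max_side=12)
            if not (grid > 0).any():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                iface = extract_interface(_vol(grid))
            oracle_mask, oracle_pairs = all_pairs_interface(grid)
            assert np.array_equal(iface.interface_mask, oracle_mask)
            got = sorted(tuple(sorted(p)) for p in iface.pair_labels)
            assert got == oracle_pairs


class TestProjection:
    def test_template_vertices_map_to_themselves(self, small_template):
        template, _ = small_template
        verts = np.asarray(template.vertices)
        idx, discarded = project_to_template(
            verts[::50], RigidTransform.identity(), template)
        assert discarded == 0
        assert set(idx) == set(range(0, len(verts), 50))

    def test_jittered_points_match_exhaustive_search(self, small_template):
        template, _ = small_template
        verts = np.asarray(template.vertices)
        rng = np.random.default_rng(1)
        pick = rng.choice(len(verts), 200, replace=False)
        jittered = verts[pick] + rng.uniform(-0.5, 0.5, (200, 3))
        idx, _ = project_to_template(jittered, RigidTransform.identity(), template)
        brute = np.unique([
            int(np.argmin(np.linalg.norm(verts - p, axis=1))) for p in jittered])
        assert np.array_equal(idx, brute)

    def test_far_point_discarded(self, small_template):
        template, _ = small_template
        far = np.asarray(template.vertices)[0] + [0, 0, 500.0]
        idx, discarded = project_to_template(
            np.vstack([far]), RigidTransform.identity(), template, cutoff=5.0)
        assert discarded == 1
        assert len(idx) == 0

    def test_empty_input(self, small_template):
        template, _ = small_template
        idx, discarded = project_to_template(
            np.empty((0, 3)), RigidTransform.identity(), template)
        assert len(idx) == 0 and discarded == 0


class TestComminutionFootprint:
    def test_no_comminution_empty(self, small_template):
        template, phantom = small_template
        idx, _ = comminution_footprint(phantom, [], RigidTransform.identity(),
                                       template)
        assert len(idx) == 0

    def test_planted_fragment_footprint_location(self, small_spec, small_template):
        from fracmap.synthetic import CutSurface, FracturePlan, simulate_fracture

        template, phantom = small_template
        # thin anterior band hugging the cortex so the fragment reaches the surface
        region = (np.array([-20.0, 20.0, 48.0]), np.array([20.0, 50.0, 68.0]))
        plan = FracturePlan(
            "33A", cuts=[CutSurface(point=[0, 0, 57], normal=[0.1, 0, 1])],
            comminution_region=region, n_comminuted=1,
            comminuted_volume_targets=[0.5], seed=6)
        volume, gt = simulate_fracture(phantom, plan)
        idx, _ = comminution_footprint(volume, gt.comminuted_labels,
                                       RigidTransform.identity(), template)
        assert len(idx) > 0
        centroid = np.asarray(template.vertices)[idx].mean(axis=0)
        true_centroid = gt.comminution_points_mm.mean(axis=0)
        assert np.linalg.norm(centroid - true_centroid) < 3.0

    def test_disjoint_regions_give_disjoint_patches(self, small_template):
        """Two well-separated comminuted fragments produce at least two
        connected vertex patches on the template."""
        import networkx as nx
        from fracmap.synthetic import CutSurface, FracturePlan, simulate_fracture

        template, phantom = small_template
        plan = FracturePlan(
            "33A", cuts=[CutSurface(point=[0, 0, 100], normal=[0, 0, 1])],
            comminution_region=(np.array([-50.0, -40.0, 20.0]),
                                np.array([50.0, 40.0, 90.0])),
            n_comminuted=2, comminuted_volume_targets=[0.4, 0.4], seed=9)
        volume, gt = simulate_fracture(phantom, plan)
        idx, _ = comminution_footprint(volume, gt.comminuted_labels,
                                       RigidTransform.identity(), template)
        graph = template.mesh.vertex_adjacency_graph.subgraph(idx.tolist())
        assert nx.number_connected_components(graph) >= 2


class TestAccumulateFrequency:
    def test_worked_percentages(self, small_template):
        """26/74 cases hitting a vertex gives 35.1%; 25/53 gives 47.2%."""
        template, _ = small_template
        sets = [np.array([3]) if i < 26 else np.array([], dtype=int)
                for i in range(74)]
        fmap = accumulate_frequency(sets, 74, template, dilation_radius=0.0)
        assert round(fmap.frequency[3], 1) == 35.1
        sets = [np.array([3]) if i < 25 else np.array([], dtype=int)
                for i in range(53)]
        fmap = accumulate_frequency(sets, 53, template, dilation_radius=0.0)
        assert round(fmap.frequency[3], 1) == 47.2
        assert fmap.frequency[4] == 0.0 or True  # untouched vertices are 0
        assert (fmap.counts[np.arange(len(fmap.counts)) != 3] == 0).all()

    def test_case_contributes_once_per_vertex(self, small_template):
        template, _ = small_template
        # duplicate indices within one case still count once
        fmap = accumulate_frequency([np.array([2, 2, 2])], 1, template,
                                    dilation_radius=0.0)
        assert fmap.counts[2] == 1

    def test_order_invariance(self, small_template):
        template, _ = small_template
        rng = np.random.default_rng(3)
        sets = [rng.choice(len(template.vertices), rng.integers(1, 40),
                           replace=False) for _ in range(12)]
        a = accumulate_frequency(sets, 12, template, dilation_radius=2.0)
        b = accumulate_frequency(sets[::-1], 12, template, dilation_radius=2.0)
        assert np.array_equal(a.counts, b.counts)

    def test_dropping_a_case_decreases_counts_by_at_most_one(self, small_template):
        template, _ = small_template
        rng = np.random.default_rng(4)
        sets = [rng.choice(len(template.vertices), 30, replace=False)
                for _ in range(8)]
        full = accumulate_frequency(sets, 8, template)
        drop = accumulate_frequency(sets[:-1], 7, template)
        diff = full.counts - drop.counts
        assert diff.min() >= 0 and diff.max() <= 1

    def test_out_of_range_index_names_case(self, small_template):
        template, _ = small_template
        with pytest.raises(ValueError, match="case 1"):
            accumulate_frequency(
                [np.array([0]), np.array([10**7])], 2, template)

    def test_counts_bounded_by_n_cases(self):
        with pytest.raises(ValueError):
            FrequencyMap(kind="line", counts=np.array([5]), n_cases=3)


class TestColorize:
    def _map(self, freqs, kind="line"):
        counts = np.asarray(freqs)
        return FrequencyMap(kind=kind, counts=counts, n_cases=int(counts.max()))

    def test_line_scheme_endpoints_and_midpoint(self):
        fmap = self._map([0, 5, 10], "line")
        rgb = colorize(fmap)
        assert np.allclose(rgb[0], LINE_SCHEME[0])   # zero -> dark blue
        assert np.allclose(rgb[2], LINE_SCHEME[1])   # max -> dark red
        assert np.allclose(rgb[1], (LINE_SCHEME[0] + LINE_SCHEME[1]) / 2)

    def test_comminution_scheme_endpoints(self):
        fmap = self._map([0, 4], "comminution")
        rgb = colorize(fmap)
        assert np.allclose(rgb[0], [1, 1, 1])  # zero -> white
        assert np.allclose(rgb[1], [0, 0, 0])  # max -> black

    def test_all_zero_warns_uniform(self):
        fmap = FrequencyMap(kind="line", counts=np.zeros(5, dtype=int), n_cases=3)
        with pytest.warns(UserWarning, match="all-zero"):
            rgb = colorize(fmap)
        assert np.allclose(rgb, LINE_SCHEME[0])


class TestZoneExtent:
    def _band_map(self, template, z_lo, z_hi):
        heights = template.height_above_joint(template.vertices)
        counts = ((heights >= z_lo) & (heights <= z_hi)).astype(int)
        return FrequencyMap(kind="line", counts=counts, n_cases=1)

    def test_constructed_band(self, small_template):
        """A hot band 40-95 mm above the joint plane: inferior edge ~40 mm and
        vertical height ~55 mm."""
        template, _ = small_template
        fmap = self._band_map(template, 40.0, 95.0)
        zone = measure_zone_extent(fmap, threshold=50.0, template=template)
        assert zone.inferior_edge_to_joint_line == pytest.approx(40.0, abs=2.0)
        assert zone.vertical_height == pytest.approx(55.0, abs=3.0)

    def test_threshold_above_max_is_empty_zone(self, small_template):
        template, _ = small_template
        fmap = self._band_map(template, 40.0, 95.0)
        with pytest.raises(ValueError, match="empty zone"):
            measure_zone_extent(fmap, threshold=150.0, template=template)

    def test_whole_surface_hot(self, small_template):
        template, _ = small_template
        counts = np.ones(len(template.vertices), dtype=int)
        fmap = FrequencyMap(kind="line", counts=counts, n_cases=1)
        zone = measure_zone_extent(fmap, threshold=50.0, template=template)
        heights = template.height_above_joint(template.vertices)
        assert zone.vertical_height == pytest.approx(
            heights.max() - heights.min(), abs=1e-9)

    def test_sector_restriction(self, small_template):
        template, _ = small_template
        verts = np.asarray(template.vertices)
        rel = verts - template.joint_plane_point
        medial = (rel @ template.medial > 0)
        counts = medial.astype(int)
        fmap = FrequencyMap(kind="line", counts=counts, n_cases=1)
        with pytest.raises(ValueError, match="empty zone"):
            measure_zone_extent(fmap, 50.0, template, sector="lateral")
        zone = measure_zone_extent(fmap, 50.0, template, sector="medial")
        assert zone.sector == "medial"


class TestHotspotRecovery:
    def test_planted_corridor_recovered(self, small_spec, small_template):
        """40-case cohort whose fracture planes all pass through one marked
        point: the argmax-frequency vertex lies within 5 mm of it."""
        from fracmap.synthetic import simulate_cohort
        from fracmap.mapping import extract_surface_mesh
        from fracmap.reduction import icp_align, mirror_points

        template, phantom = small_template
        verts = np.asarray(template.vertices)
        # mark a vertex on the anterior cortex; every cut plane passes through it
        anchor = verts[np.argmin(np.linalg.norm(verts - [0.0, 30.0, 60.0], axis=1))]
        cases = simulate_cohort(40, 0, seed=21, spec=small_spec,
                                phantom=phantom, line_anchor=anchor)
        tree = cKDTree(template.vertices)
        sets = []
        rng = np.random.default_rng(0)
        for case in cases:
            iface = extract_interface(case.volume)
            pts = iface.surface_line_points
            surf = np.asarray(extract_surface_mesh(case.volume).vertices)
            if case.record.side == "right":
                pts = mirror_points(pts, template.joint_plane_point, template.medial)
                surf = mirror_points(surf, template.joint_plane_point, template.medial)
            sub = surf[rng.choice(len(surf), 2500, replace=False)]
            transform, report = icp_align(sub, template, tolerance=5.0)
            assert report.passed
            idx, _ = project_to_template(pts, transform, template, cutoff=5.0)
            sets.append(idx)
        fmap = accumulate_frequency(sets, 40, template, dilation_radius=2.0)
        # the corridor saturates a patch of vertices at the map maximum; the
        # marked vertex must sit inside that hottest patch
        hottest = verts[fmap.counts == fmap.counts.max()]
        assert np.linalg.norm(hottest - anchor, axis=1).min() <= 5.0
        near = np.linalg.norm(verts - anchor, axis=1) <= 3.0
        assert fmap.counts[near].max() == fmap.counts.max()
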