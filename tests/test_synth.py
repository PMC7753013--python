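import math

import numpy as np
import pytest

from dvn.synth import (
    GeometryError,
    SynthConfig,
    VesselTree,
    bifurcation_angles,
    bifurcation_mask,
    class_fractions,
    generate_dataset,
    generate_volume,
    murray_split,
    rasterize_centerline,
    render_intensities,
    sample_tree,
    validate_tree,
    voxelize,
)


class TestMurraySplit:
    def test_symmetric_split(self):
        r_l, r_r = murray_split(1.0, 1.0, gamma=3.0)
        assert r_l == pytest.approx(2 ** (-1 / 3), abs=1e-12)
        assert r_r == pytest.approx(2 ** (-1 / 3), abs=1e-12)

    def test_vanishing_daughter(self):
        r_l, r_r = murray_split(1.0, 1e-6, gamma=3.0)
        assert r_l == pytest.approx(1.0, abs=1e-9)
        assert r_r == pytest.approx(1e-6, rel=1e-6)

    @pytest.mark.parametrize("r_p", [0.5, 1.0, 3.7])
    @pytest.mark.parametrize("asym", [0.2, 0.66, 1.0])
    @pytest.mark.parametrize("gamma", [2.0, 3.0, 3.5])
    def test_construction_identity(self, r_p, asym, gamma):
        r_l, r_r = murray_split(r_p, asym, gamma)
        assert abs(r_p**gamma - r_l**gamma - r_r**gamma) < 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            murray_split(-1.0, 0.5)
        with pytest.raises(ValueError):
            murray_split(1.0, 0.0)
        with pytest.raises(ValueError):
            murray_split(1.0, 0.5, gamma=0)


class TestBifurcationAngles:
    def test_symmetric_murray_triple(self):
        r = 2 ** (-1 / 3)
        phi_l, phi_r = bifurcation_angles(1.0, r, r)
        assert math.cos(phi_l) == pytest.approx(2 ** (-1 / 3), abs=1e-12)
        assert phi_l == pytest.approx(math.acos(2 ** (-1 / 3)), abs=1e-12)
        assert phi_l == pytest.approx(phi_r, abs=1e-12)
        assert math.degrees(phi_l) == pytest.approx(37.47, abs=0.01)

    def test_straight_continuation_limit(self):
        phi_l, _ = bifurcation_angles(1.0, 1.0, 1e-4)
        assert phi_l == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_triples_equal_angles(self):
        # symmetric triples are only geometrically valid for r >= 2**-0.5
        for r in (0.72, 2 ** (-1 / 3), 0.95):
            phi_l, phi_r = bifurcation_angles(1.0, r, r)
            assert phi_l == pytest.approx(phi_r, abs=1e-12)

    def test_invalid_triple_raises(self):
        with pytest.raises(GeometryError):
            bifurcation_angles(1.0, 3.0, 0.1)


class TestSampleTree:
    def test_determinism(self):
        cfg = SynthConfig()
        t1 = sample_tree(cfg, seed=11)
        t2 = sample_tree(cfg, seed=11)
        assert len(t1) == len(t2)
        for a, b in zip(t1.nodes.values(), t2.nodes.values()):
            assert a.node_type == b.node_type
            np.testing.assert_array_equal(a.position, b.position)
        for sa, sb in zip(t1.segments, t2.segments):
            assert (sa.parent, sa.child, sa.radius) == (sb.parent, sb.child, sb.radius)

    def test_fifty_seeded_trees_satisfy_constraints(self):
        cfg = SynthConfig()
        for seed in range(50):
            tree = sample_tree(cfg, seed=seed)
            report = validate_tree(tree, cfg.gamma, cfg.volume_shape)
            assert report.ok, f"seed {seed}: {report.violations[:3]}"

    def test_immediate_termination(self):
        cfg = SynthConfig(root_radius=(1.0, 1.0), min_terminal_radius=2.0)
        tree = sample_tree(cfg, seed=0)
        types = sorted(n.node_type for n in tree.nodes.values())
        assert types == ["leaf", "root"]
        assert len(tree.segments) == 1

    def test_node_types_match_out_degree(self):
        tree = sample_tree(SynthConfig(), seed=3)
        for node in tree.nodes.values():
            deg = len(tree.children(node.id))
            expected = {"root": 1, "inter": 1, "bifurcation": 2, "leaf": 0}
            assert deg == expected[node.node_type]


class TestValidateTree:
    def test_perturbed_radius_flags_one_murray_violation(self):
        cfg = SynthConfig()
        tree = sample_tree(cfg, seed=5)
        # pick a daughter edge ending in a leaf so only one bifurcation
        # shares the perturbed radius
        seg = next(
            s
            for n in tree.bifurcation_nodes()
            for s in tree.children(n.id)
            if tree.nodes[s.child].node_type == "leaf"
        )
        seg.radius *= 1.1
        report = validate_tree(tree, cfg.gamma, cfg.volume_shape)
        assert len(report.of_kind("murray")) == 1

    def test_duplicated_edge_flags_topology(self):
        cfg = SynthConfig()
        tree = sample_tree(cfg, seed=5)
        tree.segments.append(tree.segments[-1])
        report = validate_tree(tree, cfg.gamma)
        assert report.of_kind("topology")

    def test_out_of_bounds_node_flagged(self):
        cfg = SynthConfig()
        tree = sample_tree(cfg, seed=5)
        leaf = next(n for n in tree.nodes.values() if n.node_type == "leaf")
        leaf.position = leaf.position + 1000.0
        report = validate_tree(tree, cfg.gamma, cfg.volume_shape)
        assert report.of_kind("bounds")


class TestVoxelize:
    def test_single_segment_matches_distance_oracle(self):
        tree = VesselTree()
        a = tree.add_node((10.0, 16.0, 16.0), "root")
        b = tree.add_node((20.0, 16.0, 16.0), "leaf")
        tree.add_segment(a, b, radius=2.0)
        mask = voxelize(tree, (32, 32, 32))

        # brute force: per-voxel point-to-segment distance
        p0 = np.array([10.0, 16.0, 16.0])
        p1 = np.array([20.0, 16.0, 16.0])
        v = p1 - p0
        count = 0
        for idx in np.ndindex(32, 32, 32):
            x = np.array(idx, dtype=float)
            t = np.clip(np.dot(x - p0, v) / np.dot(v, v), 0, 1)
            if np.linalg.norm(x - (p0 + t * v)) <= 2.0:
                count += 1
        assert mask.sum() == count

    def test_empty_tree(self):
        assert voxelize(VesselTree(), (8, 8, 8)).sum() == 0

    def test_radius_monotonicity(self):
        cfg = SynthConfig()
        tree = sample_tree(cfg, seed=9)
        big = voxelize(tree, cfg.volume_shape)
        for seg in tree.segments:
            seg.radius *= 0.5
        small = voxelize(tree, cfg.volume_shape)
        assert not np.any(small & ~big)


class TestCenterline:
    def test_axis_aligned_segment_count(self):
        tree = VesselTree()
        a = tree.add_node((2.0, 2.0, 2.0), "root")
        b = tree.add_node((2.0, 2.0, 12.0), "leaf")
        tree.add_segment(a, b, 1.0)
        mask = rasterize_centerline(tree, (16, 16, 16))
        assert mask.sum() == 11
        assert np.all(mask[2, 2, 2:13])

    def test_containment_in_vessel_mask(self):
        # terminal daughters can undershoot min_terminal_radius by the
        # asymmetric split factor, so pick it high enough that radii stay >= 1
        cfg = SynthConfig(min_terminal_radius=1.8, root_radius=(2.5, 3.0))
        for seed in range(5):
            tree = sample_tree(cfg, seed=seed)
            assert min(s.radius for s in tree.segments) >= 1.0
            vessel = voxelize(tree, cfg.volume_shape)
            center = rasterize_centerline(tree, cfg.volume_shape)
            assert not np.any(center & ~vessel), f"seed {seed}"

    def test_empty_tree(self):
        assert rasterize_centerline(VesselTree(), (8, 8, 8)).sum() == 0

    def test_line_is_26_connected(self):
        tree = VesselTree()
        a = tree.add_node((1.0, 2.0, 3.0), "root")
        b = tree.add_node((14.0, 9.0, 11.0), "leaf")
        tree.add_segment(a, b, 1.0)
        mask = rasterize_centerline(tree, (16, 16, 16))
        coords = np.argwhere(mask)
        order = np.argsort(coords[:, 0])
        steps = np.abs(np.diff(coords[order], axis=0))
        assert np.all(steps <= 1)


class TestBifurcationMask:
    def test_interior_node_full_cube(self):
        tree = VesselTree()
        r = tree.add_node((2.0, 2.0, 2.0), "root")
        m = tree.add_node((10.0, 10.0, 10.0), "bifurcation")
        l1 = tree.add_node((15.0, 12.0, 10.0), "leaf")
        l2 = tree.add_node((15.0, 8.0, 10.0), "leaf")
        tree.add_segment(r, m, 1.0)
        tree.add_segment(m, l1, 0.8)
        tree.add_segment(m, l2, 0.8)
        mask = bifurcation_mask(tree, (21, 21, 21), cube=5)
        assert mask.sum() == 125

    def test_corner_node_clipped(self):
        tree = VesselTree()
        tree.add_node((0.0, 0.0, 0.0), "bifurcation")
        mask = bifurcation_mask(tree, (16, 16, 16), cube=5)
        assert mask.sum() == 27

    def test_no_bifurcations(self):
        tree = VesselTree()
        a = tree.add_node((1.0, 1.0, 1.0), "root")
        b = tree.add_node((5.0, 5.0, 5.0), "leaf")
        tree.add_segment(a, b, 1.0)
        assert bifurcation_mask(tree, (8, 8, 8)).sum() == 0

    def test_even_cube_rejected(self):
        with pytest.raises(ValueError):
            bifurcation_mask(VesselTree(), (8, 8, 8), cube=4)


class TestRenderIntensities:
    def test_noise_disabled_two_valued(self):
        cfg = SynthConfig(noise=False)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        img = render_intensities(mask, cfg, seed=0)
        assert len(np.unique(img)) == 2
        assert img[mask].min() >= 128
        assert img[~mask].max() <= 100

    def test_determinism(self):
        cfg = SynthConfig()
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3] = True
        a = render_intensities(mask, cfg, seed=4)
        b = render_intensities(mask, cfg, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_foreground_brighter_in_expectation(self):
        cfg = SynthConfig()
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[4:8] = True
        gaps = []
        for seed in range(100):
            img = render_intensities(mask, cfg, seed=seed)
            gaps.append(img[mask].mean() - img[~mask].mean())
        assert np.mean(gaps) >= 28 - 5  # interval gap minus sampling slack


class TestGenerateDataset:
    def test_reproducibility(self):
        cfg = SynthConfig()
        a = generate_dataset(cfg, 3, seed=21)
        b = generate_dataset(cfg, 3, seed=21)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.image.data, vb.image.data)
            np.testing.assert_array_equal(va.vessel_mask.data, vb.vessel_mask.data)

    def test_vessel_fraction_bracket(self):
        cfg = SynthConfig()
        vols = generate_dataset(cfg, 20, seed=2)
        fracs = [class_fractions(v)["vessel"] for v in vols]
        assert 0.005 <= np.mean(fracs) <= 0.05
        assert all(0.001 <= f <= 0.10 for f in fracs)

    def test_fraction_ordering(self):
        vol = generate_volume(SynthConfig(), seed=8)
        fr = class_fractions(vol)
        assert fr["centerline"] < fr["vessel"] < 1.0

    def test_mask_hierarchy_and_cube_centers(self):
        cfg = SynthConfig()
        vol = generate_volume(cfg, seed=13)
        center = vol.centerline_mask.data.astype(bool)
        vessel = vol.vessel_mask.data.astype(bool)
        assert not np.any(center & ~vessel)
        # every bifurcation-cube center lies on the centerline
        for tree in vol.trees:
            for node in tree.bifurcation_nodes():
                c = np.rint(node.position).astype(int)
                if np.all(c >= 0) and np.all(c < np.array(cfg.volume_shape)):
                    assert center[tuple(c)]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_dataset(SynthConfig(), 0, seed=1)


class TestSynthConfig:
    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError, match="well-ordered"):
            SynthConfig(root_radius=(3.0, 2.0))

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(volume_shape=(0, 4, 4))
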