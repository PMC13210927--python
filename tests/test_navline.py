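"""Row clustering, anchor extraction, gap repair, RANSAC and the full
mask-to-lines pipeline, checked against constructed and synthetic truth."""

import dataclasses

import numpy as np
import pytest

from croprow import navline, synthfield
from croprow.navline import (AnchorPoint, ClusterConfig, LineModel,
                             RansacConfig, RowInstance, cluster_rows,
                             consistency_filter, extract_anchors,
                             extract_navigation_lines, ransac_fit,
                             repair_anchors)


def _bar_mask(h=200, w=200, bars=((90, 110),)):
    m = np.zeros((h, w), dtype=np.uint8)
    for x0, x1 in bars:
        m[:, x0:x1] = 1
    return m


def _instance_from_mask(mask):
    instances = cluster_rows(mask, ClusterConfig())
    assert len(instances) == 1
    return instances[0]


class TestClusterRows:
    def test_empty_mask_gives_empty_list(self):
        assert cluster_rows(np.zeros((64, 64), dtype=np.uint8)) == []

    def test_single_bar_single_instance_with_all_pixels(self):
        mask = _bar_mask()
        instances = cluster_rows(mask)
        assert len(instances) == 1
        assert len(instances[0].pixels) == mask.sum()

    def test_bars_closer_than_eps_merge(self):
        # bars 10 px wide, 20 px apart edge-to-edge (centers 30 px): one
        # cluster at eps = 30
        mask = _bar_mask(bars=((80, 90), (110, 120)))
        assert len(cluster_rows(mask, ClusterConfig(eps=30))) == 1

    def test_synthetic_rows_match_ground_truth_membership(self, small_scene):
        """Each instance's pixel set equals the generating row's blob union."""
        instances = cluster_rows(small_scene.mask, ClusterConfig())
        assert len(instances) == 3
        for inst in instances:
            labels = small_scene.row_labels[inst.pixels[:, 1], inst.pixels[:, 0]]
            assert len(set(labels.tolist())) == 1
            row_id = labels[0]
            assert len(inst.pixels) == int((small_scene.row_labels == row_id).sum())

    def test_instances_disjoint_and_subset_of_foreground(self, small_scene):
        instances = cluster_rows(small_scene.mask)
        seen = np.zeros_like(small_scene.mask, dtype=bool)
        for inst in instances:
            xs, ys = inst.pixels[:, 0], inst.pixels[:, 1]
            assert small_scene.mask[ys, xs].all()
            assert not seen[ys, xs].any()
            seen[ys, xs] = True


class TestExtractAnchors:
    def test_solid_bar_centroids_exact(self):
        inst = _instance_from_mask(_bar_mask(bars=((90, 110),)))
        anchors = extract_anchors(inst, ClusterConfig(n_anchor_rows=10))
        assert len(anchors) == 10
        for a in anchors:
            assert a.x == pytest.approx((90 + 109) / 2)
            assert a.source == "detected"

    def test_gap_band_yields_no_anchor(self):
        mask = _bar_mask(h=200)
        mask[60:80, :] = 0  # empties band 3 of 10 (y in [60, 80))
        inst = RowInstance(instance_id=0,
                           pixels=np.argwhere(mask)[:, ::-1],
                           repaired_mask=mask.astype(bool))
        cfg = ClusterConfig(n_anchor_rows=10)
        anchors = extract_anchors(inst, cfg)
        assert len(anchors) == 9
        ys = {a.y for a in anchors}
        assert 70.0 not in ys

    def test_asymmetric_slice_matches_brute_force_moment(self):
        """Anchor x of an L-shaped band equals the exhaustive pixel-mean x."""
        mask = np.zeros((40, 60), dtype=bool)
        mask[0:4, 10:30] = True   # horizontal arm
        mask[0:20, 10:14] = True  # vertical arm
        inst = RowInstance(instance_id=0, pixels=np.argwhere(mask)[:, ::-1],
                           repaired_mask=mask)
        cfg = ClusterConfig(n_anchor_rows=2)
        anchors = extract_anchors(inst, cfg)
        band = mask[0:20]
        total, acc = 0, 0.0
        for yy in range(band.shape[0]):
            for xx in range(band.shape[1]):
                if band[yy, xx]:
                    total += 1
                    acc += xx
        assert anchors[0].x == pytest.approx(acc / total, rel=1e-12)


class TestRepairAnchors:
    def _make_instance(self, h=200, w=100):
        mask = np.zeros((h, w), dtype=bool)
        mask[:, 40:60] = True
        return RowInstance(instance_id=0, pixels=np.argwhere(mask)[:, ::-1],
                           repaired_mask=mask)

    def test_no_missing_heights_is_identity(self):
        inst = self._make_instance()
        cfg = ClusterConfig(n_anchor_rows=10)
        anchors = extract_anchors(inst, cfg)
        assert repair_anchors(anchors, inst, cfg) == anchors

    def test_missing_bottom_copies_second_to_bottom(self):
        cfg = ClusterConfig(n_anchor_rows=5)
        heights = navline.anchor_heights(200, 5)
        inst = self._make_instance()
        detected = [AnchorPoint(x=50.0 + i, y=float(heights[i]), row_id=0,
                                source="detected") for i in range(4)]
        out = repair_anchors(detected, inst, cfg)
        assert len(out) == 5
        assert out[-1].source == "repaired"
        assert out[-1].x == detected[3].x

    def test_equidistant_tie_resolves_to_smaller_y(self):
        cfg = ClusterConfig(n_anchor_rows=5)
        heights = navline.anchor_heights(200, 5)
        inst = self._make_instance()
        # detected at indices 1 and 3 with different x; index 2 is equidistant
        detected = [
            AnchorPoint(x=41.0, y=float(heights[1]), row_id=0, source="detected"),
            AnchorPoint(x=59.0, y=float(heights[3]), row_id=0, source="detected"),
        ]
        out = repair_anchors(detected, inst, cfg)
        middle = [a for a in out if a.y == pytest.approx(heights[2])][0]
        assert middle.source == "repaired"
        assert middle.x == 41.0  # tie broken toward smaller y

    def test_zero_detected_anchors_raises(self):
        inst = self._make_instance()
        with pytest.raises(ValueError):
            repair_anchors([], inst, ClusterConfig())


def _collinear_anchors(n, x0=40.0):
    return [AnchorPoint(x=x0, y=10.0 * i, row_id=0, source="detected")
            for i in range(n)]


class TestRansac:
    def test_twelve_collinear_vertical_anchors(self):
        line = ransac_fit(_collinear_anchors(12), RansacConfig(), seed=0)
        assert line is not None
        assert abs(line.a) == pytest.approx(1.0)
        assert line.b == pytest.approx(0.0, abs=1e-12)
        assert line.c == pytest.approx(-40.0 * np.sign(line.a))
        assert line.inlier_count == 12

    def test_nine_collinear_below_min_returns_none(self):
        assert ransac_fit(_collinear_anchors(9), RansacConfig(min_inliers=10),
                          seed=0) is None

    def test_constructed_outlier_rejection_and_refit_slope(self):
        """20 anchors on y = 2x + 5 plus 8 outliers >= 10 px off: the inlier
        set is exactly the 20 true points and the refit slope is 2."""
        truth = [AnchorPoint(x=float(k), y=2.0 * k + 5.0, row_id=0,
                             source="detected") for k in range(20)]
        rng = np.random.default_rng(3)
        outliers = []
        for k in range(8):
            x = rng.uniform(0, 19)
            y_on = 2 * x + 5
            # perpendicular offset >= 10 px
            off = rng.uniform(10, 40) * rng.choice([-1, 1])
            nx, ny = 2 / np.sqrt(5), -1 / np.sqrt(5)
            outliers.append(AnchorPoint(x=x + off * nx, y=y_on + off * ny,
                                        row_id=0, source="outlier"))
        line = ransac_fit(truth + outliers, RansacConfig(), seed=7)
        assert line is not None
        assert {id(a) for a in line.inliers} == {id(a) for a in truth}
        slope = -line.a / line.b
        assert slope == pytest.approx(2.0, abs=1e-6)

    def test_fixed_seed_is_fully_deterministic(self):
        anchors = _collinear_anchors(15)
        anchors += [AnchorPoint(x=90.0, y=33.0, row_id=0, source="detected")]
        l1 = ransac_fit(anchors, seed=5)
        l2 = ransac_fit(anchors, seed=5)
        assert (l1.a, l1.b, l1.c) == (l2.a, l2.b, l2.c)
        assert [id(a) for a in l1.inliers] == [id(a) for a in l2.inliers]

    def test_adding_collinear_anchors_never_decreases_inliers(self):
        base = _collinear_anchors(12)
        count12 = ransac_fit(base, seed=2).inlier_count
        more = base + _collinear_anchors(4, x0=40.0)
        count16 = ransac_fit(more, seed=2).inlier_count
        assert count16 >= count12

    def test_fewer_than_two_anchors_rejected(self):
        with pytest.raises(ValueError):
            ransac_fit(_collinear_anchors(1), seed=0)

    def test_inliers_satisfy_distance_bound_and_normalisation(self):
        rng = np.random.default_rng(11)
        anchors = [AnchorPoint(x=100 + rng.normal(0, 2), y=float(20 * i),
                               row_id=0, source="detected") for i in range(12)]
        cfg = RansacConfig()
        line = ransac_fit(anchors, cfg, seed=1)
        assert line.a ** 2 + line.b ** 2 == pytest.approx(1.0, abs=1e-9)
        xs = np.array([p.x for p in line.inliers])
        ys = np.array([p.y for p in line.inliers])
        assert (line.distance(xs, ys) <= cfg.inlier_threshold + 1e-9).all()


class TestConsistencyFilter:
    def _line_through(self, xs_ys):
        pts = np.asarray(xs_ys, dtype=float)
        anchors = [AnchorPoint(x=x, y=y, row_id=0, source="detected")
                   for x, y in pts]
        return ransac_fit(anchors, RansacConfig(min_inliers=2), seed=0)

    def test_uniform_spacing_unchanged(self):
        line = self._line_through([(50.0, 10.0 * i) for i in range(12)])
        out = consistency_filter(line)
        assert out is line

    def test_isolated_point_removed_and_refit(self):
        pts = [(50.0, 10.0 * i) for i in range(10)] + [(50.0, 190.0)]
        line = self._line_through(pts)
        assert line.inlier_count == 11
        out = consistency_filter(line)
        assert out.inlier_count == 10
        assert max(p.y for p in out.inliers) == 90.0

    def test_two_inliers_degenerate_unchanged(self):
        line = LineModel(a=1.0, b=0.0, c=-50.0, inliers=[
            AnchorPoint(x=50.0, y=0.0, row_id=0, source="detected"),
            AnchorPoint(x=50.0, y=100.0, row_id=0, source="detected")])
        assert consistency_filter(line) is line


class TestFullPipeline:
    def test_empty_mask_gives_empty_output(self):
        assert extract_navigation_lines(np.zeros((64, 64), dtype=np.uint8)) == []

    def test_five_row_scene_returns_middle_three_labelled(self):
        cfg = synthfield.SceneConfig(
            image_height=384, image_width=640, n_rows=5, row_spacing=110,
            plant_spacing=48, plant_radius_range=(10, 16), weed_density=0.0,
            row_slope_range=(-0.03, 0.03), seed=21)
        scene = synthfield.generate_scene(cfg)
        lines = extract_navigation_lines(scene.mask, seed=0)
        assert [nl.label for nl in lines] == ["left", "middle", "right"]
        xs = [nl.line.x_at([192.0])[0] for nl in lines]
        assert xs == sorted(xs)
        # the 3 returned lines correspond to the middle rows 1, 2, 3
        from croprow import naveval
        for nl in lines:
            best = min(scene.rows,
                       key=lambda r: abs(r.x_at(np.array([192.0]))[0]
                                         - nl.line.x_at([192.0])[0]))
            assert best.row_index in (1, 2, 3)
            truth = LineModel(*best.centerline)
            assert naveval.angle_deviation(nl.line, truth) < 0.5

    def test_forty_percent_omission_still_recovers_line(self):
        from croprow import naveval

        errs = []
        for seed in range(5):
            cfg = synthfield.SceneConfig(
                image_height=384, image_width=384, n_rows=3, row_spacing=110,
                plant_spacing=48, plant_radius_range=(10, 16),
                gap_probability=0.4, weed_density=0.0,
                row_slope_range=(-0.03, 0.03), seed=3000 + seed)
            scene = synthfield.generate_scene(cfg)
            lines = extract_navigation_lines(scene.mask, seed=seed)
            for nl in lines:
                best = min(scene.rows,
                           key=lambda r: abs(r.x_at(np.array([192.0]))[0]
                                             - nl.line.x_at([192.0])[0]))
                errs.append(naveval.angle_deviation(
                    nl.line, LineModel(*best.centerline)))
        assert errs and float(np.mean(errs)) < 1.0
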