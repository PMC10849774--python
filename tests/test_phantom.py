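import math

import numpy as np
import pytest
from scipy import stats
from skimage.draw import disk as draw_disk

from sproutgraph import phantom as ph
from sproutgraph import segment_image, skeletonize, build_graph, prune
from sproutgraph.morphometry import generation_number
from sproutgraph.phantom import (
    GeometryError,
    GroundTruthNetwork,
    GroundTruthSegment,
    PhantomSpec,
    generate_logistic_series,
    generate_network,
    ground_truth_mask,
    render_image,
)

from conftest import acceptance_phantom_spec


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"bead_radius_um": 0},
            {"sprout_width_um": -1},
            {"mean_segment_length_um": 0},
            {"n_primary": -1},
            {"resolution_um_per_px": 0},
            {"logistic_params": (0.0, 1.0, 5.0)},
            {"logistic_params": (100.0, 0.0, 5.0)},
            {"primary_placement": "spiral"},
            {"tip_speed_um_per_day": 0},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            PhantomSpec(**kw)

    def test_geometry_error(self):
        with pytest.raises(GeometryError):
            generate_network(PhantomSpec(bead_radius_um=400.0, image_size_px=512))


class TestGenerateNetwork:
    def test_no_branching(self):
        spec = PhantomSpec(
            n_primary=3,
            mean_segment_length_um=math.inf,
            n_days=10,
            logistic_params=(600.0, 1.0, 4.0),
            rng_seed=1,
        )
        net = generate_network(spec)
        assert len(net.segments) == 3
        n_tip, n_pb = net.counts(10)
        assert n_tip == 3 and n_pb == 3
        assert generation_number(n_tip, n_pb) == pytest.approx(1.0)

    def test_determinism(self):
        spec = acceptance_phantom_spec(9)
        a = generate_network(spec)
        b = generate_network(spec)
        assert a.to_json_dict() == b.to_json_dict()

    def test_branch_length_primitive_mean(self):
        # arclength-to-bifurcation demand, free of growth-horizon censoring
        spec = PhantomSpec(mean_segment_length_um=100.0, rng_seed=5)
        lengths = ph.sample_branch_lengths(spec, 600)
        se = lengths.std(ddof=1) / math.sqrt(lengths.size)
        assert abs(lengths.mean() - 100.0) <= 3 * se

    def test_branch_length_primitive_exponential_ks(self):
        spec = PhantomSpec(mean_segment_length_um=100.0, rng_seed=7)
        lengths = ph.sample_branch_lengths(spec, 600)
        res = stats.kstest(lengths, "expon", args=(0, 100.0))
        assert res.pvalue > 0.01

    def test_poisson_event_rate(self):
        # bifurcation count over the whole network matches L_total / l*
        spec = PhantomSpec(
            n_primary=10,
            mean_segment_length_um=100.0,
            logistic_params=(30000.0, 1.5, 5.0),
            n_days=12,
            image_size_px=2048,
            branch_angle_sd_deg=10.0,
            rng_seed=5,
        )
        net = generate_network(spec)
        events = len(net.completed_segment_lengths_um())
        expected = net.total_length_um(12) / 100.0
        assert abs(events - expected) <= 3 * math.sqrt(expected)

    def test_tree_accounting(self):
        spec = acceptance_phantom_spec(17)
        net = generate_network(spec)
        day = spec.n_days
        vis = net.visible(day)
        n_tip, n_pb = net.counts(day)
        n_junctions = sum(
            1 for sid in vis if any(c in vis for c in net.segments[sid].children)
        )
        assert n_junctions == n_tip - n_pb
        assert len(vis) == 2 * n_tip - n_pb

    def test_snapshot_monotonicity(self):
        spec = acceptance_phantom_spec(18)
        net = generate_network(spec)
        days = net.days
        lengths = [net.total_length_um(d) for d in days]
        tips = [net.counts(d)[0] for d in days]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))
        assert all(b >= a for a, b in zip(tips, tips[1:]))

    def test_generation_indexing(self):
        spec = acceptance_phantom_spec(19)
        net = generate_network(spec)
        for sid, seg in net.segments.items():
            if seg.parent is None:
                assert seg.generation == 1
            else:
                parent = net.segments[seg.parent]
                assert seg.generation == parent.generation + 1
                # child's first point is the parent's branch point
                np.testing.assert_allclose(seg.points[0], parent.points[-1])

    def test_json_round_trip(self, tmp_path):
        spec = acceptance_phantom_spec(20)
        net = generate_network(spec)
        p = tmp_path / "net.json"
        net.save_json(p)
        back = GroundTruthNetwork.from_json(p)
        assert back.bead_radius_px == net.bead_radius_px
        assert set(back.segments) == set(net.segments)
        assert back.snapshots == net.snapshots


class TestRenderImage:
    def test_bead_only_area(self):
        spec = PhantomSpec(n_primary=0, noise_sd=0.0, rng_seed=0)
        net = generate_network(spec)
        img = render_image(net, spec, 0)
        fg = img.pixels > spec.background_level
        rr, cc = draw_disk(net.bead_center_px, net.bead_radius_px, shape=img.shape)
        assert fg.sum() == len(rr)
        analytic = math.pi * net.bead_radius_px**2
        assert abs(fg.sum() - analytic) <= 2 * math.pi * net.bead_radius_px + 1

    def test_single_straight_sprout_round_trip(self):
        spec = PhantomSpec(n_primary=1, noise_sd=0.0, sprout_width_um=10.0, rng_seed=0)
        size = spec.image_size_px
        center = (size / 2.0, size / 2.0)
        net = GroundTruthNetwork(
            bead_center_px=center,
            bead_radius_px=spec.bead_radius_px,
            resolution_um_per_px=spec.resolution_um_per_px,
        )
        start_col = center[1] + spec.bead_radius_px
        n_pts = int(400.0 / spec.resolution_um_per_px) + 1  # 400 μm horizontal
        pts = [(center[0], start_col + i) for i in range(n_pts)]
        net.segments[0] = GroundTruthSegment(points=pts, parent=None, generation=1)
        net.snapshots = {0: {0: len(pts)}}
        img = render_image(net, spec, 0)
        seg = segment_image(img)
        graph = prune(build_graph(skeletonize(seg.sprout_mask), seg.bead, img.resolution_um_per_px))
        assert abs(graph.total_length_um - 400.0) / 400.0 < 0.05

    def test_noise_seed_changes_image_not_truth(self):
        spec = acceptance_phantom_spec(30)
        net = generate_network(spec)
        img1 = render_image(net, spec, 8, noise_seed=1)
        img2 = render_image(net, spec, 8, noise_seed=2)
        assert not np.array_equal(img1.pixels, img2.pixels)
        assert generate_network(spec).to_json_dict() == net.to_json_dict()

    def test_render_deterministic(self):
        spec = acceptance_phantom_spec(31)
        net = generate_network(spec)
        a = render_image(net, spec, 6)
        b = render_image(net, spec, 6)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_missing_day(self):
        spec = acceptance_phantom_spec(32)
        net = generate_network(spec)
        with pytest.raises(KeyError):
            render_image(net, spec, 99)

    def test_clamped_to_uint16_range(self):
        spec = ph.replace_spec(acceptance_phantom_spec(33), noise_sd=50000.0)
        net = generate_network(spec)
        img = render_image(net, spec, 5)
        assert img.pixels.min() >= 0 and img.pixels.max() <= 65535


class TestMeasuredCounts:
    def test_pruning_merges(self):
        net = GroundTruthNetwork(
            bead_center_px=(0.0, 0.0), bead_radius_px=10.0, resolution_um_per_px=1.0
        )
        # primary → junction with one long and one short daughter
        net.segments[0] = GroundTruthSegment(
            points=[(0, 10 + i) for i in range(101)], parent=None, generation=1, children=[1, 2]
        )
        net.segments[1] = GroundTruthSegment(
            points=[(0, 110 + i) for i in range(101)], parent=0, generation=2
        )
        net.segments[2] = GroundTruthSegment(
            points=[(i, 110) for i in range(21)], parent=0, generation=2
        )
        net.snapshots = {0: {0: 101, 1: 101, 2: 21}}
        n_tip, n_pb, total = net.measured_counts(0, min_tip_len_um=62.5)
        assert (n_tip, n_pb) == (1, 1)
        assert total == pytest.approx(200.0)

    def test_primary_exempt(self):
        net = GroundTruthNetwork(
            bead_center_px=(0.0, 0.0), bead_radius_px=10.0, resolution_um_per_px=1.0
        )
        net.segments[0] = GroundTruthSegment(
            points=[(0, 10 + i) for i in range(21)], parent=None, generation=1
        )
        net.snapshots = {0: {0: 21}}
        n_tip, n_pb, total = net.measured_counts(0, min_tip_len_um=62.5)
        assert (n_tip, n_pb) == (1, 1)


class TestLogisticSeries:
    def test_midpoint(self):
        ts = generate_logistic_series(4000.0, 1.2, 7.0, [7.0])
        assert ts.values[0] == pytest.approx(2000.0)

    def test_asymptotes(self):
        ts = generate_logistic_series(4000.0, 1.2, 7.0, [-1000.0, 1000.0])
        assert ts.values[0] == pytest.approx(0.0, abs=1e-12)
        assert ts.values[1] == pytest.approx(4000.0)

    def test_closed_form(self):
        days = np.arange(0, 15)
        ts = generate_logistic_series(4000.0, 1.2, 7.0, days)
        np.testing.assert_allclose(
            ts.values, 4000.0 / (1.0 + np.exp(-1.2 * (days - 7.0))), rtol=1e-15
        )

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            generate_logistic_series(1.0, 1.0, 0.0, [])

    def test_k_positive(self):
        with pytest.raises(ValueError):
            generate_logistic_series(1.0, 0.0, 0.0, [1.0])

    def test_noise_seeded(self):
        a = generate_logistic_series(100.0, 1.0, 5.0, np.arange(10), noise_sd=5.0, rng_seed=1)
        b = generate_logistic_series(100.0, 1.0, 5.0, np.arange(10), noise_sd=5.0, rng_seed=1)
        np.testing.assert_array_equal(a.values, b.values)


class TestAnastomosisMode:
    def test_fused_tips_marked(self):
        spec = ph.replace_spec(
            acceptance_phantom_spec(40),
            anastomosis=True,
            min_clearance_px=8.0,
            n_primary=8,
            direction_noise_deg=6.0,
            logistic_params=(4000.0, 1.4, 5.0),
        )
        net = generate_network(spec)
        # with crowded growth, at least some tips stop (fused or frame-bound)
        assert len(net.segments) >= 8
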