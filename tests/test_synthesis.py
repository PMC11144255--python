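"""Synthetic tree generator, waveform construction, and shift-error machinery."""

import numpy as np
import pytest

from pulstrans import (
    ValidationError,
    build_tree,
    collect_samples,
    compute_ppi,
    compute_profiles,
    fit_transmission,
    inject_shift_errors,
    make_flow_traces,
    make_tree,
    path_distance,
    run_shift_experiment,
)
from pulstrans.synthesis import SyntheticSpec, corrupt_for_quality, solve_amplitude

from conftest import assert_segments_equal


class TestMakeTree:
    def test_depth_zero_single_segment(self):
        spec = SyntheticSpec(depth=0, points_per_segment=12, step_mm=1.5, seed=4)
        tree = make_tree(spec)
        assert tree.segment_ids == ["S0"]
        np.testing.assert_allclose(
            tree.true_distances["S0"], 1.5 * np.arange(12), atol=1e-9
        )

    def test_depth_two_segment_count(self):
        spec = SyntheticSpec(depth=2, branch_factor=2, points_per_segment=6, seed=4)
        tree = make_tree(spec)
        assert len(tree.segment_ids) == 7  # 1 + 2 + 4

    def test_true_distances_agree_with_path_distance(self):
        """Cross-module consistency: stored ground truth equals path_distance."""
        spec = SyntheticSpec(depth=3, points_per_segment=9, gap_mm=4.0, seed=17)
        tree = make_tree(spec)
        net = tree.network
        for sid in tree.segment_ids:
            for c in net.segments[sid].cross_sections:
                assert path_distance(net, c) == pytest.approx(
                    tree.true_distances[sid][c.order_index], abs=1e-9
                )

    def test_seeded_determinism(self):
        spec = SyntheticSpec(depth=2, points_per_segment=8, seed=99)
        a = make_flow_traces(spec, make_tree(spec))
        b = make_flow_traces(spec, make_tree(spec))
        assert a.true_parent == b.true_parent
        for sid in a.segment_ids:
            assert_segments_equal(a.network.segments[sid], b.network.segments[sid])
            np.testing.assert_array_equal(a.true_distances[sid], b.true_distances[sid])


class TestMakeFlowTraces:
    def test_noiseless_ppi_matches_linear_law_exactly(self):
        spec = SyntheticSpec(depth=1, points_per_segment=25, seed=6)
        tree = make_flow_traces(spec, make_tree(spec))
        for sid in tree.segment_ids:
            seg = tree.network.segments[sid]
            d = tree.true_distances[sid]
            target = spec.true_offset + spec.true_slope * d / 1000.0
            got = np.array([compute_ppi(c.trace) for c in seg.cross_sections])
            np.testing.assert_allclose(got, target, atol=1e-12)

    def test_zero_slope_uniform_ppi(self):
        spec = SyntheticSpec(depth=1, points_per_segment=10, true_slope=0.0, seed=6)
        tree = make_flow_traces(spec, make_tree(spec))
        for sid in tree.segment_ids:
            for c in tree.network.segments[sid].cross_sections:
                assert compute_ppi(c.trace) == pytest.approx(spec.true_offset, abs=1e-12)

    def test_noise_variance_matches_sigma(self):
        """Residual p_pi about the linear law has variance ~ sigma^2."""
        spec = SyntheticSpec(
            depth=4, points_per_segment=40, ppi_noise_sd=0.1, seed=23
        )
        tree = make_flow_traces(spec, make_tree(spec))
        residuals = []
        for sid in tree.segment_ids:
            d = tree.true_distances[sid]
            law = spec.true_offset + spec.true_slope * d / 1000.0
            got = np.array(
                [compute_ppi(c.trace) for c in tree.network.segments[sid].cross_sections]
            )
            residuals.append(got - law)
        residuals = np.concatenate(residuals)
        assert len(residuals) >= 1000
        assert np.var(residuals) == pytest.approx(0.01, rel=0.2)

    def test_nonpositive_target_is_error(self):
        spec = SyntheticSpec(depth=2, points_per_segment=80, true_slope=-5.0,
                             true_offset=0.5, seed=6)
        with pytest.raises(ValidationError):
            make_flow_traces(spec, make_tree(spec))

    def test_amplitude_solver_rejects_overlarge_target(self):
        with pytest.raises(ValidationError):
            solve_amplitude(2.5, 20)  # raised sinusoid cannot exceed p_pi = 2


class _ConstantRng:
    """Stub generator returning a fixed value from uniform draws."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low, high, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


class TestInjectShiftErrors:
    def test_zero_scale_leaves_tree_unchanged(self):
        spec = SyntheticSpec(depth=2, points_per_segment=8, shift_scale_mm=0.0, seed=3)
        tree = make_tree(spec)
        shifted = inject_shift_errors(tree, spec)
        for a, b in zip(tree.network.connections, shifted.network.connections):
            assert a.gap_length == b.gap_length

    def test_single_junction_shift_propagates_downstream(self):
        spec = SyntheticSpec(depth=1, branch_factor=1, points_per_segment=8, seed=3)
        tree = make_tree(spec)
        shifted = inject_shift_errors(tree, spec, rng=_ConstantRng(3.0))
        d0 = tree.network.point_distances()
        d1 = shifted.network.point_distances()
        np.testing.assert_array_equal(d1["S0"], d0["S0"])
        np.testing.assert_allclose(d1["S1"], d0["S1"] + 3.0, atol=1e-12)

    def test_random_shifts_equal_cumulative_path_sums(self):
        """Downstream distance deltas are the summed junction perturbations."""
        spec = SyntheticSpec(depth=3, points_per_segment=6, gap_mm=8.0, seed=31)
        tree = make_tree(spec)
        shifted = inject_shift_errors(tree, spec)
        d0 = tree.network.point_distances()
        d1 = shifted.network.point_distances()
        for sid in tree.segment_ids:
            cum = 0.0
            node = sid
            while node in tree.true_parent:
                cum += shifted.shifts[node]
                node = tree.true_parent[node]
            np.testing.assert_allclose(d1[sid] - d0[sid], cum, atol=1e-10)

    def test_gap_stays_nonnegative(self):
        spec = SyntheticSpec(depth=2, points_per_segment=6, gap_mm=1.0,
                             shift_scale_mm=20.0, seed=5)
        shifted = inject_shift_errors(make_tree(spec), spec)
        assert all(c.gap_length >= 0 for c in shifted.network.connections)


class TestShiftExperiment:
    def test_no_shift_no_noise_recovers_slope_exactly(self):
        spec = SyntheticSpec(depth=2, points_per_segment=20, shift_scale_mm=0.0, seed=1)
        res = run_shift_experiment(spec, n_cases=5)
        np.testing.assert_allclose(res.slopes, spec.true_slope, atol=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_doubling_shift_scale_widens_spread_not_mean(self):
        # long segments keep the errors-in-variables attenuation negligible,
        # so only the spread should respond to the shift scale
        small = SyntheticSpec(depth=3, points_per_segment=200, shift_scale_mm=4.0, seed=2)
        large = SyntheticSpec(depth=3, points_per_segment=200, shift_scale_mm=8.0, seed=2)
        r_small = run_shift_experiment(small, n_cases=400)
        r_large = run_shift_experiment(large, n_cases=400)
        assert r_large.sd > r_small.sd
        se = r_large.sd / np.sqrt(400)
        assert abs(r_large.mean - r_small.mean) < 3 * (se + r_small.sd / np.sqrt(400))

    def test_deterministic_given_spec(self):
        spec = SyntheticSpec(depth=2, points_per_segment=30, seed=12)
        a = run_shift_experiment(spec, n_cases=50)
        b = run_shift_experiment(spec, n_cases=50)
        np.testing.assert_array_equal(a.slopes, b.slopes)


class TestCorruptForQuality:
    def test_corruption_off_preserves_perfect_quality(self):
        spec = SyntheticSpec(depth=1, points_per_segment=12, true_slope=0.0, seed=14)
        tree = make_flow_traces(spec, make_tree(spec))
        clean = corrupt_for_quality(tree, end_fraction=0.0)
        _, q = compute_profiles(clean.network)
        for arr in q.values():
            np.testing.assert_allclose(arr, 4.0, atol=1e-12)
        for sid in tree.segment_ids:
            assert_segments_equal(
                tree.network.segments[sid], clean.network.segments[sid]
            )

    def test_strong_end_corruption_fails_threshold_only_at_ends(self):
        spec = SyntheticSpec(depth=0, points_per_segment=40, true_slope=0.0, seed=14)
        tree = make_flow_traces(spec, make_tree(spec))
        corrupted = corrupt_for_quality(tree)
        _, q = compute_profiles(corrupted.network)
        arr = q["S0"]
        assert arr[0] < 2.5 and arr[-1] < 2.5
        assert arr[20] > 2.5  # deep interior untouched

    def test_thresholding_improves_slope_recovery(self):
        """Discarding low-Q points brings the fit closer to the true slope."""
        wins = 0
        for seed in range(10):
            spec = SyntheticSpec(depth=2, points_per_segment=40,
                                 ppi_noise_sd=0.02, seed=100 + seed)
            tree = corrupt_for_quality(make_flow_traces(spec, make_tree(spec)))
            ppi, q = compute_profiles(tree.network)
            samples = collect_samples(tree.network, ppi, q)
            thr = fit_transmission(samples, mode="unweighted")
            raw = fit_transmission(samples, mode="unthresholded")
            if abs(thr.p_tc - spec.true_slope) < abs(raw.p_tc - spec.true_slope):
                wins += 1
        assert wins >= 8
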