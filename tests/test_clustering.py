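import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centroclust.clustering import (
    ClusteringSummary,
    build_heatmap,
    clustering_fold_change,
    pairwise_distances,
    short_distance_percentage,
)
from centroclust.errors import GridError
from centroclust.sim import SimConfig, SimRecord

# ---------------------------------------------------------------------- #
# independent brute-force oracles


def brute_pairwise(points):
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.hypot(points[i][0] - points[j][0], points[i][1] - points[j][1])
    return d


def brute_short_pct(points, threshold):
    n = len(points)
    hits = 0
    for i in range(n):
        for j in range(n):
            if i != j and np.hypot(
                points[i][0] - points[j][0], points[i][1] - points[j][1]
            ) < threshold:
                hits += 1
                break
    return 100.0 * hits / n


def brute_pair_pct(points, threshold):
    n = len(points)
    close = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if np.hypot(points[i][0] - points[j][0], points[i][1] - points[j][1]) < threshold:
                close += 1
    return 100.0 * close / total


# ---------------------------------------------------------------------- #


class TestPairwiseDistances:
    def test_3_4_5_triangle(self):
        d = pairwise_distances([(0, 0), (3, 4)])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_single_point(self):
        assert pairwise_distances([(2.0, 3.0)]).tolist() == [[0.0]]

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(-10, 10, size=(10, 2))
        assert np.allclose(pairwise_distances(pts), brute_pairwise(pts), atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.empty((0, 2)))


class TestShortDistancePercentage:
    def test_all_coincident(self):
        pts = np.zeros((7, 2))
        assert short_distance_percentage(pts, 3.0) == 100.0

    def test_two_far_points(self):
        assert short_distance_percentage([(0, 0), (10, 0)], 3.0) == 0.0

    def test_blob_plus_isolated_is_50pct(self, rng):
        # 10 points in a 1 µm-radius blob, 10 isolated ones >= 5 µm apart
        blob = rng.uniform(-0.5, 0.5, size=(10, 2))
        isolated = np.array([(20.0 + 6.0 * k, 0.0) for k in range(10)])
        pts = np.vstack([blob, isolated])
        assert short_distance_percentage(pts, 3.0) == pytest.approx(50.0)
        assert brute_short_pct(pts, 3.0) == pytest.approx(50.0)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 8, size=(rng.integers(2, 50), 2))
            thr = float(rng.uniform(0.5, 5))
            assert short_distance_percentage(pts, thr) == pytest.approx(
                brute_short_pct(pts, thr)
            )
            assert short_distance_percentage(pts, thr, per_pair=True) == pytest.approx(
                brute_pair_pct(pts, thr)
            )

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            short_distance_percentage([(0, 0)], 3.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
            ),
            min_size=2,
            max_size=30,
        ),
        st.floats(0.1, 10.0),
        st.floats(-3.0, 3.0),
        st.floats(0, 2 * np.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_rigid_motion_invariance(self, pts, threshold, shift, angle):
        pts = np.asarray(pts)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + shift
        assert short_distance_percentage(moved, threshold) == pytest.approx(
            short_distance_percentage(pts, threshold), abs=1e-9
        )

    @given(
        st.lists(
            st.tuples(st.floats(-20, 20, allow_nan=False), st.floats(-20, 20, allow_nan=False)),
            min_size=2,
            max_size=25,
        ),
        st.floats(0.1, 5.0),
        st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, pts, t1, t2):
        lo, hi = sorted([t1, t2])
        assert short_distance_percentage(pts, lo) <= short_distance_percentage(pts, hi)


# ---------------------------------------------------------------------- #


def make_record(start_pts, end_pts, t_bundle=100.0, t_total=500.0, provenance=None):
    cfg = SimConfig(t_bundle=t_bundle, t_total=t_total, n_filaments=0, n_hset=0,
                    n_complexes=len(start_pts))
    rec = SimRecord(config=cfg, seed=0, provenance=provenance or {})
    rec.add_snapshot(t_bundle, np.asarray(start_pts, float), np.empty((0, 2)))
    if t_total > t_bundle:
        rec.add_snapshot(t_total, np.asarray(end_pts, float), np.empty((0, 2)))
    return rec


class TestFoldChange:
    def test_identical_snapshots_give_one(self, rng):
        pts = rng.uniform(0, 5, size=(12, 2))
        rec = make_record(pts, pts)
        assert clustering_fold_change(rec, 3.0).fold_change == pytest.approx(1.0)

    def test_constructed_10_to_40_pct(self):
        # start: 2/20 close (10%); end: 8/20 close (40%) -> fold 4.0
        far = [(10.0 * k, 100.0) for k in range(18)]
        start = np.array([(0, 0), (1, 0)] + far[:18])
        end_close = [(0, 0), (1, 0), (30, 0), (31, 0), (60, 0), (61, 0), (90, 0), (91, 0)]
        end = np.array(end_close + far[:12])
        rec = make_record(start, end)
        s = clustering_fold_change(rec, 3.0)
        assert s.pct_short_t_start == pytest.approx(10.0)
        assert s.pct_short_t_end == pytest.approx(40.0)
        assert s.fold_change == pytest.approx(4.0)

    def test_zero_baseline_flagged_not_raised(self):
        start = np.array([(10.0 * k, 0.0) for k in range(10)])
        end = np.zeros((10, 2))
        s = clustering_fold_change(make_record(start, end), 3.0)
        assert s.undefined
        assert np.isnan(s.fold_change)

    def test_missing_snapshot_named(self, rng):
        pts = rng.uniform(0, 5, size=(5, 2))
        rec = make_record(pts, pts)
        rec.config = rec.config.replace(t_total=999.0)
        with pytest.raises(KeyError, match="999"):
            clustering_fold_change(rec, 3.0)

    def test_equal_phase_times_single_snapshot_fold_one(self, rng):
        pts = rng.uniform(0, 5, size=(8, 2))
        rec = make_record(pts, pts, t_bundle=100.0, t_total=100.0)
        assert len(rec.times) == 1
        assert clustering_fold_change(rec, 3.0).fold_change == pytest.approx(1.0)


class TestHeatmap:
    def test_1x1_grid_equals_record_fold(self, rng):
        pts = rng.uniform(0, 5, size=(10, 2))
        rec = make_record(pts, pts, provenance={"cell_index": 0, "rate": 0.1, "n": 50})
        grid = build_heatmap([rec], "rate", "n")
        assert grid.mean_fold_change.shape == (1, 1)
        assert grid.mean_fold_change[0, 0] == pytest.approx(
            clustering_fold_change(rec, 3.0).fold_change
        )

    def test_2x2_grid_3_seeds_means(self, rng):
        records, expected = [], {}
        idx = 0
        for rate in (0.1, 1.0):
            for n in (10, 20):
                folds = []
                for _ in range(3):
                    start = rng.uniform(0, 30, size=(15, 2))
                    end = rng.uniform(0, 30, size=(15, 2))
                    rec = make_record(
                        start, end, provenance={"cell_index": idx, "rate": rate, "n": n}
                    )
                    records.append(rec)
                    folds.append(clustering_fold_change(rec, 3.0).fold_change)
                    idx += 1
                expected[(rate, n)] = np.nanmean(folds)
        grid = build_heatmap(records, "rate", "n")
        assert grid.mean_fold_change.shape == (2, 2)
        for i, rate in enumerate((0.1, 1.0)):
            for j, n in enumerate((10, 20)):
                assert grid.mean_fold_change[i, j] == pytest.approx(expected[(rate, n)])
                assert grid.n_replicates[i, j] == 3

    def test_incomplete_grid_lists_missing(self, rng):
        pts = rng.uniform(0, 5, size=(6, 2))
        recs = [
            make_record(pts, pts, provenance={"rate": 0.1, "n": 10}),
            make_record(pts, pts, provenance={"rate": 1.0, "n": 20}),
        ]
        with pytest.raises(GridError, match="missing"):
            build_heatmap(recs, "rate", "n")

    def test_save_outputs(self, rng, tmp_path):
        pts = rng.uniform(0, 5, size=(10, 2))
        rec = make_record(pts, pts, provenance={"rate": 0.1, "n": 10})
        grid = build_heatmap([rec], "rate", "n")
        grid.save(tmp_path)
        assert (tmp_path / "heatmap.csv").exists()
        assert (tmp_path / "heatmap.png").exists()
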