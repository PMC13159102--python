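import numpy as np
import pytest

from centroclust.clustering import clustering_fold_change, short_distance_percentage
from centroclust.errors import ConfigurationError
from centroclust.frap import fit_trace
from centroclust.motility import PROCESSIVE, STATIC, segment_events
from centroclust.synth import (
    DropletImageSpec,
    FRAPSpec,
    PointSetSpec,
    TrackSpec,
    gen_droplet_image,
    gen_frap_traces,
    gen_point_set,
    gen_tracks,
    make_fixtures,
)


class TestReproducibility:
    def test_frap_pure_function_of_spec(self):
        a, _ = gen_frap_traces(FRAPSpec(n_traces=3, seed=5))
        b, _ = gen_frap_traces(FRAPSpec(n_traces=3, seed=5))
        c, _ = gen_frap_traces(FRAPSpec(n_traces=3, seed=6))
        assert all(np.array_equal(x.roi_intensity, y.roi_intensity) for x, y in zip(a, b))
        assert not np.array_equal(a[0].roi_intensity, c[0].roi_intensity)

    def test_tracks_pure_function_of_spec(self):
        a, ta = gen_tracks(TrackSpec(n_tracks=4, seed=2))
        b, tb = gen_tracks(TrackSpec(n_tracks=4, seed=2))
        assert all(np.array_equal(x.x, y.x) for x, y in zip(a, b))
        assert ta.equals(tb)

    def test_droplet_image_pure_function_of_spec(self):
        ia, _ = gen_droplet_image(DropletImageSpec(n_disks=5, seed=3))
        ib, _ = gen_droplet_image(DropletImageSpec(n_disks=5, seed=3))
        assert np.array_equal(ia, ib)

    def test_point_set_pure_function_of_spec(self):
        pa, la = gen_point_set(PointSetSpec(seed=4))
        pb, lb = gen_point_set(PointSetSpec(seed=4))
        assert np.array_equal(pa, pb) and np.array_equal(la, lb)


class TestFRAPGenerator:
    def test_noiseless_round_trip_exact(self):
        spec = FRAPSpec(t_half_s=9.92, immobile_fraction=0.70, sigma=0.0, n_traces=2, seed=0)
        traces, truth = gen_frap_traces(spec)
        for trace in traces:
            fit = fit_trace(trace)
            assert fit.t_half == pytest.approx(9.92, abs=1e-6)
            assert fit.immobile_fraction == pytest.approx(0.70, abs=1e-6)
            assert fit.F0 == pytest.approx(spec.F0, abs=1e-6)

    def test_fully_immobile_gives_flat_trace(self):
        spec = FRAPSpec(immobile_fraction=1.0, sigma=0.0, n_traces=1, seed=0)
        traces, _ = gen_frap_traces(spec)
        fit = fit_trace(traces[0])
        assert fit.flat
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-9)

    def test_invalid_parameters_error(self):
        with pytest.raises(ConfigurationError):
            FRAPSpec(t_half_s=-1.0).k
            gen_frap_traces(FRAPSpec(t_half_s=-1.0))
        with pytest.raises(ConfigurationError):
            gen_frap_traces(FRAPSpec(immobile_fraction=1.5))

    def test_truth_table_carries_parameters(self):
        spec = FRAPSpec(t_half_s=12.5, immobile_fraction=0.938, n_traces=5, seed=1)
        _, truth = gen_frap_traces(spec)
        assert len(truth) == 5
        assert np.allclose(truth["t_half_s"], 12.5)
        assert np.allclose(truth["immobile_fraction"], 0.938)


class TestTrackGenerator:
    def test_pure_drift_labels_processive(self):
        spec = TrackSpec(n_tracks=3, fractions=(1.0, 0.0, 0.0), sigma_loc=0.0,
                         speed_sd=0.0, n_frames=12, seed=1)
        tracks, truth = gen_tracks(spec)
        for _, row in truth.iterrows():
            labels = row["labels"].split(",")
            # drift may end before the last frame; all moving frames processive
            assert labels[0] == PROCESSIVE
        for tr in tracks:
            events = segment_events(tr)
            assert events[0].cls == PROCESSIVE

    def test_zero_speed_labeled_static(self):
        spec = TrackSpec(n_tracks=3, fractions=(0.0, 0.0, 1.0), seed=1)
        tracks, truth = gen_tracks(spec)
        assert set(truth["kind"]) == {STATIC}
        for tr in tracks:
            events = segment_events(tr)
            assert all(e.cls == STATIC for e in events)

    def test_classifier_recovers_generator_labels_mostly(self):
        spec = TrackSpec(n_tracks=30, fractions=(0.5, 0.2, 0.3), seed=3,
                         run_mean_um=5.0, run_sd_um=1.0, n_frames=30)
        tracks, truth = gen_tracks(spec)
        agree = 0
        for tr, (_, row) in zip(tracks, truth.iterrows()):
            events = segment_events(tr)
            has_proc = any(e.cls == PROCESSIVE for e in events)
            agree += has_proc == (row["kind"] == PROCESSIVE)
        assert agree / len(tracks) >= 0.9

    def test_run_distance_truth_realized(self):
        spec = TrackSpec(n_tracks=50, run_mean_um=7.4, run_sd_um=1.9,
                         speed_mean=0.087, speed_sd=0.015, n_frames=40, seed=5)
        _, truth = gen_tracks(spec)
        proc = truth[truth["kind"] == PROCESSIVE]
        assert proc["run_um"].mean() == pytest.approx(7.4, abs=0.4)


class TestDropletGenerator:
    def test_zero_disks_pure_noise(self):
        spec = DropletImageSpec(n_disks=0, seed=1)
        img, truth = gen_droplet_image(spec)
        assert len(truth) == 0
        from centroclust.droplets import detect_droplets

        assert detect_droplets(img, 0.1).count <= 2  # noise specks only

    def test_contrast_free_image_finds_nothing(self):
        spec = DropletImageSpec(n_disks=10, partition=1.0, seed=2)
        img, _ = gen_droplet_image(spec)
        from centroclust.droplets import detect_droplets

        assert detect_droplets(img, 0.1).count <= 3

    def test_overcrowded_request_errors(self):
        with pytest.raises(ConfigurationError, match="non-overlapping"):
            gen_droplet_image(DropletImageSpec(shape=(32, 32), n_disks=50,
                                               radius_mean_px=6, seed=0))

    def test_truth_matches_rendered_disks(self):
        spec = DropletImageSpec(n_disks=8, poisson_noise=False, readout_sigma=0.0, seed=4)
        img, truth = gen_droplet_image(spec)
        for _, row in truth.iterrows():
            cy, cx = int(round(row["center_y_px"])), int(round(row["center_x_px"]))
            assert img[cy, cx] == pytest.approx(spec.dilute_level * spec.partition, rel=0.01)


class TestPointSetGenerator:
    def test_single_tight_blob_fully_clustered(self):
        spec = PointSetSpec(n_clusters=1, points_per_cluster=20, cluster_sd_um=0.1,
                            n_background=0, seed=1)
        pts, labels = gen_point_set(spec)
        assert short_distance_percentage(pts, 3.0) == 100.0
        assert set(labels) == {0}

    def test_sparse_poisson_points_mostly_unclustered(self):
        # expected nearest-neighbor distance for a Poisson process is
        # 0.5/sqrt(lambda); with 15 points in a 120 µm-radius arena that is
        # ~27 µm >> 3 µm, so the short-distance percentage is ~0
        spec = PointSetSpec(n_clusters=0, points_per_cluster=0, n_background=15,
                            arena_radius_um=120.0, seed=7)
        pts, labels = gen_point_set(spec)
        lam = 15 / (np.pi * 120.0**2)
        assert 0.5 / np.sqrt(lam) > 5 * 3.0
        assert short_distance_percentage(pts, 3.0) <= 15.0
        assert set(labels) == {-1}

    def test_dispersed_then_clustered_fold_above_one(self):
        from centroclust.sim import SimConfig, SimRecord

        disp_spec = PointSetSpec(n_clusters=0, points_per_cluster=0, n_background=30,
                                 arena_radius_um=40.0, seed=2)
        clus_spec = PointSetSpec(n_clusters=3, points_per_cluster=10, cluster_sd_um=0.5,
                                 n_background=0, arena_radius_um=40.0, seed=2)
        start, _ = gen_point_set(disp_spec)
        end, _ = gen_point_set(clus_spec)
        cfg = SimConfig(t_bundle=100.0, t_total=500.0, n_complexes=30)
        rec = SimRecord(config=cfg, seed=0)
        rec.add_snapshot(100.0, start, np.empty((0, 2)))
        rec.add_snapshot(500.0, end, np.empty((0, 2)))
        assert clustering_fold_change(rec, 3.0).fold_change > 1.0


class TestMakeFixtures:
    @pytest.mark.parametrize("kind,files", [
        ("frap", ["frap_traces.csv", "truth.csv"]),
        ("tracks", ["tracks.csv", "truth.csv", "filament_lengths.csv"]),
        ("droplet_image", ["droplets.tif", "truth.csv"]),
        ("point_set", ["points.csv"]),
    ])
    def test_writes_fixture_and_spec(self, tmp_path, kind, files):
        overrides = {"seed": 1}
        if kind == "frap":
            overrides["n_traces"] = 2
        if kind == "tracks":
            overrides["n_tracks"] = 2
        if kind == "droplet_image":
            overrides["n_disks"] = 3
        out = make_fixtures(kind, overrides, tmp_path / kind)
        assert (out / "spec.json").exists()
        for f in files:
            assert (out / f).exists()

    def test_unknown_kind_and_keys(self, tmp_path):
        with pytest.raises(ConfigurationError, match="unknown fixture kind"):
            make_fixtures("nope", {}, tmp_path)
        with pytest.raises(ConfigurationError, match="spec keys"):
            make_fixtures("frap", {"bogus": 1}, tmp_path)
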