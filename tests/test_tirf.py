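import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

from vesiscope.imgmodel import Frame2D, Movie, PipelineParams
from vesiscope.synthetic import TirfSceneSpec, generate_tirf_movie
from vesiscope.tirf import (
    MarginClassifier,
    ParticleDetection,
    Track,
    classify_events,
    compute_roi,
    detect_blurred_frames,
    detect_particles,
    focus_features,
    insertion_rate,
    line_scan_profile,
    merge_duplicate_events,
    synthesize_blur_training,
    track_feature_vector,
    track_particles,
    train_event_classifier,
    wavelet_smooth,
)


class TestBlurDetection:
    @pytest.fixture(scope="class")
    def blur_clf(self):
        X, y = synthesize_blur_training(n_movies=6, seed=0)
        return MarginClassifier().fit(X, np.where(y, "blurred", "sharp"))

    def test_cv_selected_with_ten_folds(self, blur_clf):
        assert blur_clf.cv_report["n_folds"] == 10
        assert blur_clf.cv_report["cv_accuracy"] >= 0.9

    def test_longest_sharp_run_retained(self, blur_clf):
        spec = TirfSceneSpec.random(
            n_insertion=4, shape=(21, 96, 96), min_separation_px=24.0,
            footprint_radius_px=40.0, blurred_frames=(5,), blur_sigma_px=3.0,
            onset_range=(0, 2), seed=21,
        )
        movie, _ = generate_tirf_movie(spec)
        start, stop = detect_blurred_frames(movie, blur_clf)
        assert (start, stop) == (6, 21)

    def test_no_blur_full_range(self, blur_clf):
        spec = TirfSceneSpec.random(
            n_insertion=3, shape=(12, 96, 96), min_separation_px=24.0,
            footprint_radius_px=40.0, seed=22,
        )
        movie, _ = generate_tirf_movie(spec)
        assert detect_blurred_frames(movie, blur_clf) == (0, 12)

    def test_all_blurred_flagged(self, blur_clf):
        spec = TirfSceneSpec.random(
            n_insertion=2, shape=(6, 96, 96), min_separation_px=24.0,
            footprint_radius_px=40.0, blurred_frames=tuple(range(6)),
            blur_sigma_px=3.0, onset_range=(0, 1), seed=23,
        )
        movie, _ = generate_tirf_movie(spec)
        with pytest.warns(UserWarning):
            start, stop = detect_blurred_frames(movie, blur_clf)
        assert stop <= start

    def test_focus_features_finite_and_ordered(self):
        rng = np.random.default_rng(0)
        f = focus_features(rng.uniform(0, 100, (64, 64)))
        assert f.shape == (6,)
        assert np.all(np.isfinite(f))


class TestROI:
    def test_bright_disk_on_background(self):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
        base = ndi.gaussian_filter(np.where(disk, 200.0, 50.0), 2.0)
        frames = np.clip(base + rng.normal(0, 5, (4, 64, 64)), 0, None)
        movie = Movie.from_array(frames, 0.333)
        roi = compute_roi(movie, (0, 4), 0.90)
        core = (yy - 32) ** 2 + (xx - 32) ** 2 <= 11**2
        far = (yy - 32) ** 2 + (xx - 32) ** 2 >= 22**2
        assert np.all(roi.labels[core] == 1)
        assert roi.labels[far].sum() == 0

    def test_scale_applied_below_otsu(self):
        # pixels between 0.9*T and T are inside the ROI only because of the
        # 0.9 scaling
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(1)
        img = np.concatenate(
            [rng.normal(50, 2, 2000), rng.normal(200, 5, 2000)]
        ).reshape(40, 100)
        img = np.clip(img, 0, None)
        t = threshold_otsu(img)
        img_with_margin = img.copy()
        img_with_margin[0, :10] = 0.95 * t
        movie = Movie.from_array(img_with_margin[None], 0.333)
        roi = compute_roi(movie, (0, 1), 0.90)
        assert np.all(roi.labels[0, :10] == 1)

    def test_constant_movie_flagged_empty(self):
        movie = Movie.from_array(np.full((3, 32, 32), 7.0), 0.333)
        with pytest.warns(UserWarning):
            roi = compute_roi(movie, (0, 3), 0.90)
        assert roi.labels.sum() == 0


class TestWaveletSmooth:
    def test_constant_frame_unchanged(self):
        img = np.full((64, 64), 42.0)
        np.testing.assert_allclose(wavelet_smooth(img), img, atol=1e-8)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (128, 128))
        assert wavelet_smooth(img).var() < img.var()

    def test_blob_peak_location_preserved(self):
        rng = np.random.default_rng(1)
        yy, xx = np.mgrid[0:96, 0:96]
        img = 100 + 80 * np.exp(-((yy - 40) ** 2 + (xx - 57) ** 2) / (2 * 2.0**2))
        img = img + rng.normal(0, 3, img.shape)
        sm = wavelet_smooth(img)
        peak = np.unravel_index(np.argmax(sm), sm.shape)
        assert abs(peak[0] - 40) <= 1 and abs(peak[1] - 57) <= 1

    def test_small_frame_rejected(self):
        with pytest.raises(ValueError):
            wavelet_smooth(np.ones((4, 4)))


def make_spot_frame(seed=0, amp=50.0, pos=(32, 32), noise=2.0, bg=100.0, sigma=1.5):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:64, 0:64]
    clean = bg + amp * np.exp(-((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / (2 * sigma**2))
    return clean + rng.normal(0, noise, (64, 64))


class TestDetectParticles:
    def test_bright_spot_detected_below_threshold(self, params):
        frame = make_spot_frame()
        dets = detect_particles(frame, np.ones((64, 64), bool), params)
        assert any(
            np.hypot(d.position[0] - 32, d.position[1] - 32) <= 2 and d.p_value < 1e-3
            for d in dets
        )

    def test_p_values_match_independent_welch_oracle(self, params):
        # every recorded detection must reproduce the textbook Welch t-test
        # on its stored samples
        rng = np.random.default_rng(3)
        checked = 0
        for trial in range(5):
            frame = make_spot_frame(seed=trial, amp=60.0, pos=(20 + 5 * trial, 40))
            for d in detect_particles(frame, np.ones((64, 64), bool), params):
                shifted = d.xp - params.xp_sigma_l_coeff * d.sigma_l - params.xp_sigma_g_coeff * d.sigma_g
                oracle = stats.ttest_ind(
                    shifted, d.xm, equal_var=False, alternative="greater"
                ).pvalue
                assert d.p_value == pytest.approx(oracle, abs=1e-10)
                checked += 1
        assert checked > 0

    def test_threshold_rejects_intermediate_p(self):
        # tightening the threshold strictly filters the candidate set, and
        # everything reported respects the configured cut
        loose = PipelineParams(particle_p_threshold=0.5)
        strict = PipelineParams(particle_p_threshold=0.001)
        frame = make_spot_frame(seed=9, amp=18.0)
        d_loose = detect_particles(frame, np.ones((64, 64), bool), loose)
        d_strict = detect_particles(frame, np.ones((64, 64), bool), strict)
        assert all(d.p_value < 0.5 for d in d_loose)
        assert all(d.p_value < 0.001 for d in d_strict)
        rejected = {d.position for d in d_loose if d.p_value >= 0.001}
        assert rejected.isdisjoint({d.position for d in d_strict})

    def test_pure_noise_false_positives_below_half_per_frame(self, params):
        rng = np.random.default_rng(0)
        fp = 0
        for _ in range(100):
            frame = 100 + rng.normal(0, 2, (64, 64))
            fp += len(detect_particles(frame, np.ones((64, 64), bool), params))
        assert fp / 100 < 0.5

    def test_detection_count_invariant_under_global_scaling(self, params):
        frame = make_spot_frame(seed=5)
        d1 = detect_particles(frame, np.ones((64, 64), bool), params)
        d2 = detect_particles(frame * 5.0, np.ones((64, 64), bool), params)
        assert {d.position for d in d1} == {d.position for d in d2}

    def test_too_few_minima_skipped(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frame = np.zeros((16, 16))
            frame[8, 8] = 10.0
            out = detect_particles(frame, np.ones((16, 16), bool), params)
        assert out == [] or all(isinstance(d, ParticleDetection) for d in out)


def _det(t, y, x, p=1e-5):
    return ParticleDetection(
        frame=t, position=(float(y), float(x)), p_value=p,
        xp=np.zeros(5), xm=np.zeros(15), sigma_l=0.0, sigma_g=0.0,
    )


class TestTracking:
    def test_drifting_particle_single_track(self):
        dets = {t: [_det(t, 10 + 2 * t, 10)] for t in range(10)}
        tracks = track_particles(dets, 22.0, 3)
        assert len(tracks) == 1 and len(tracks[0].detections) == 10

    def test_linkage_threshold_splits_far_detections(self):
        dets = {0: [_det(0, 10, 10)], 1: [_det(1, 10, 40)]}
        assert len(track_particles(dets, 22.0, 3)) == 2
        dets = {0: [_det(0, 10, 10)], 1: [_det(1, 10, 30)]}
        assert len(track_particles(dets, 22.0, 3)) == 1

    def test_gap_closing_boundary(self):
        # missing 3 frames bridged, 4 frames not
        dets = {0: [_det(0, 20, 20)], 4: [_det(4, 20, 20)]}
        assert len(track_particles(dets, 22.0, 3)) == 1
        dets = {0: [_det(0, 20, 20)], 5: [_det(5, 20, 20)]}
        assert len(track_particles(dets, 22.0, 3)) == 2

    def test_greedy_matches_exhaustive_assignment(self):
        # <= 3 particles per frame, unambiguous geometry: greedy equals the
        # minimum-total-distance assignment computed by brute force
        rng = np.random.default_rng(7)
        base = np.array([[10.0, 10.0], [40.0, 40.0], [15.0, 50.0]])
        frames = {}
        positions = [base]
        for t in range(6):
            positions.append(positions[-1] + rng.uniform(-3, 3, base.shape))
        for t, pos in enumerate(positions):
            frames[t] = [_det(t, y, x) for y, x in pos]
        tracks = track_particles(frames, 22.0, 3)
        assert len(tracks) == 3
        # oracle: per-transition optimal assignment by enumeration
        for t in range(6):
            prev = positions[t]
            cur = positions[t + 1]
            best = min(
                itertools.permutations(range(3)),
                key=lambda per: sum(
                    np.hypot(*(cur[per[i]] - prev[i])) for i in range(3)
                ),
            )
            assert best == (0, 1, 2)  # geometry keeps identity optimal
        for tr in tracks:
            start = np.asarray(tr.detections[0].position)
            idx = int(np.argmin(np.hypot(*(base - start).T)))
            for t, d in enumerate(tr.detections):
                np.testing.assert_allclose(d.position, positions[t][idx], atol=1e-9)

    def test_track_requires_strict_time_order(self):
        with pytest.raises(ValueError):
            Track(detections=[_det(3, 1, 1), _det(3, 2, 2)])

    def test_stitch_joins_colocated_fragments(self):
        from vesiscope.tirf import stitch_tracks

        a = Track(detections=[_det(0, 10, 10), _det(2, 10, 11)])
        b = Track(detections=[_det(8, 11, 10), _det(9, 11, 10)])   # 6-frame gap
        c = Track(detections=[_det(8, 80, 80)])                    # far away
        out = stitch_tracks([a, b, c], distance_px=22.0, window_frames=10)
        assert len(out) == 2
        assert max(len(t.detections) for t in out) == 4


class TestClassification:
    def test_feature_vector_alignment_and_padding(self):
        tr = Track(detections=[_det(5, 1, 1, p=1e-4), _det(7, 1, 1, p=1e-2)])
        v = track_feature_vector(tr, length=10)
        assert v[0] == pytest.approx(-4.0)
        assert v[1] == 0.0
        assert v[2] == pytest.approx(-2.0)
        assert np.all(v[3:] == 0.0)

    def test_held_out_accuracy_on_separable_tracks(self, separable_tracks):
        from sklearn.model_selection import train_test_split

        tracks, labels = separable_tracks
        X = np.arange(len(tracks))
        tr_idx, te_idx = train_test_split(
            X, test_size=0.3, random_state=0, stratify=labels
        )
        clf = train_event_classifier(
            [tracks[i] for i in tr_idx], [labels[i] for i in tr_idx]
        )
        feats = np.stack([track_feature_vector(tracks[i]) for i in te_idx])
        pred = clf.predict(feats)
        acc = np.mean([p == labels[i] for p, i in zip(pred, te_idx)])
        assert acc >= 0.95

    def test_empty_track_list(self, event_classifier):
        assert classify_events([], event_classifier) == []

    def test_untrained_classifier_rejected(self):
        with pytest.raises(ValueError):
            MarginClassifier().predict(np.zeros((1, 30)))

    def test_json_roundtrip_preserves_predictions(self, event_classifier, tmp_path):
        path = event_classifier.to_json(tmp_path / "clf.json")
        loaded = MarginClassifier.from_json(path)
        rng = np.random.default_rng(0)
        X = -rng.uniform(0, 10, (20, 30))
        np.testing.assert_array_equal(
            event_classifier.predict(X), loaded.predict(X)
        )

    def test_merge_duplicate_events(self):
        from vesiscope.tirf import InsertionEvent

        evs = [
            InsertionEvent(10, 3.33, 4, (50.0, 50.0), "insertion"),
            InsertionEvent(18, 6.0, 3, (52.0, 51.0), "insertion"),
            InsertionEvent(12, 4.0, 2, (120.0, 120.0), "insertion"),
        ]
        merged = merge_duplicate_events(evs, 22.0, 30)
        assert len(merged) == 2
        host = [e for e in merged if e.position == (50.0, 50.0)][0]
        assert host.onset_frame == 10 and host.duration_frames == 11


class TestRates:
    def _ev(self, onset, cls="insertion"):
        from vesiscope.tirf import InsertionEvent

        return InsertionEvent(onset, onset * 0.333, 3, (10.0, 10.0), cls)

    def test_window_arithmetic(self):
        events = [self._ev(k) for k in (0, 10, 50, 80, 99)]
        table = insertion_rate(events, cell_area_um2=50.0, n_frames=100).table
        assert len(table) == 1
        assert table.loc[0, "count"] == 5
        assert table.loc[0, "rate_per_um2"] == pytest.approx(0.1)

    def test_empty_events_all_zero(self):
        table = insertion_rate([], 50.0, 300).table
        assert len(table) == 3
        assert (table["count"] == 0).all()

    def test_total_conserved_and_microclusters_excluded(self):
        events = [self._ev(k) for k in (5, 105, 205)] + [self._ev(7, "microcluster")]
        rt = insertion_rate(events, 10.0, 300)
        assert rt.total_events() == 3
        rt_all = insertion_rate(events, 10.0, 300, include_microclusters=True)
        assert rt_all.total_events() == 4

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            insertion_rate([], 0.0, 100)


class TestLineScan:
    def test_uniform_frame_all_ones(self):
        prof = line_scan_profile(np.full((64, 64), 9.0), (32, 5), (32, 58), 20, 10)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_symmetric_frame_palindromic(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 100 + 50 * np.exp(-((xx - 31.5) ** 2) / (2 * 8.0**2))
        prof = line_scan_profile(img, (32.0, 1.5), (32.0, 61.5), 20, 10)
        np.testing.assert_allclose(prof.values, prof.values[::-1], atol=0.02)

    def test_gaussian_spot_oracle(self):
        # brute-force oracle: integer-pixel band membership and plain means
        yy, xx = np.mgrid[0:64, 0:64]
        img = 10 + 100 * np.exp(-((yy - 32) ** 2 + (xx - 35) ** 2) / (2 * 6.0**2))
        start, end = np.array([32.0, 2.0]), np.array([32.0, 62.0])
        prof = line_scan_profile(img, tuple(start), tuple(end), 20, 10)
        u = (end - start) / np.linalg.norm(end - start)
        v = np.array([-u[1], u[0]])
        rel = np.stack([yy - start[0], xx - start[1]], axis=-1)
        t = rel @ u
        wdist = rel @ v
        L = np.linalg.norm(end - start)
        oracle = []
        for s in range(10):
            sel = (t >= s * L / 10) & (t < (s + 1) * L / 10) & (np.abs(wdist) <= 10)
            oracle.append(img[sel].mean())
        oracle = np.asarray(oracle) / max(oracle)
        assert np.argmax(prof.values) in (4, 5)
        np.testing.assert_allclose(prof.values, oracle, atol=0.05)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            line_scan_profile(np.ones((32, 32)), (5, 5), (5, 5), 20, 10)
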