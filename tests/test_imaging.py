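"""Movie hygiene, nuclear segmentation, trace extraction and mapping."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import fouriermotion as fm


def blob_image(shape, centers, sigma=2.0, amplitude=100.0, background=5.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    for r0, c0 in centers:
        img += amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    return img


@pytest.fixture
def clean_movie(rng):
    """Stable blobs plus mild noise."""
    base = blob_image((64, 64), [(20, 20), (40, 45), (15, 50)])
    frames = base[None] + rng.normal(0, 1.0, (60, 64, 64))
    return fm.MovieStack(np.clip(frames, 0, None), frame_rate=3.91)


class TestFlagArtifacts:
    def test_identical_frames_unflagged(self):
        movie = fm.MovieStack(np.ones((10, 8, 8)) * 5)
        mask = fm.flag_artifacts(movie)
        assert not mask.flagged.any()

    def test_clean_movie_flag_rate_below_one_percent(self, clean_movie):
        mask = fm.flag_artifacts(clean_movie)
        assert mask.fraction_flagged < 0.01

    def test_planted_shift_frame_is_flagged(self, clean_movie):
        frames = clean_movie.frames.copy()
        frames[30] = np.roll(frames[30], (20, 20), axis=(0, 1))
        mask = fm.flag_artifacts(fm.MovieStack(frames, 3.91))
        assert mask.flagged[30]
        assert mask.zscores[30] < -3


class TestRegisterXY:
    def test_identical_frames_zero_shift(self):
        movie = fm.MovieStack(blob_image((32, 32), [(10, 10)])[None].repeat(5, axis=0))
        _, shifts, rejected = fm.register_xy(movie)
        assert not shifts.any()
        assert not rejected.any()

    def test_planted_drift_recovered_exactly(self, clean_movie):
        frames = clean_movie.frames.copy()
        half = len(frames) // 2
        frames[half:] = np.roll(frames[half:], (3, -2), axis=(1, 2))
        drifted = fm.MovieStack(frames, 3.91)
        _, shifts, rejected = fm.register_xy(drifted, template=clean_movie.frames[0])
        assert not rejected.any()
        np.testing.assert_array_equal(shifts[half:], np.tile([-3, 2], (half, 1)))

    def test_registration_then_flagging_clears_drift_artifacts(self, clean_movie):
        frames = clean_movie.frames.copy()
        half = len(frames) // 2
        frames[half:] = np.roll(frames[half:], (6, 6), axis=(1, 2))
        registered, _, _ = fm.register_xy(
            fm.MovieStack(frames, 3.91), template=clean_movie.frames[0]
        )
        mask = fm.flag_artifacts(registered)
        assert not mask.flagged.any()

    def test_excessive_shift_rejected_not_applied(self, clean_movie):
        frames = clean_movie.frames.copy()
        frames[10] = np.roll(frames[10], (25, 0), axis=(0, 1))
        _, shifts, rejected = fm.register_xy(
            fm.MovieStack(frames, 3.91), template=clean_movie.frames[0], max_shift=20
        )
        assert rejected[10]
        assert not shifts[10].any()


class TestSegmentNuclei:
    def test_two_separated_blobs(self):
        img = blob_image((64, 64), [(30, 25), (30, 35)], sigma=2.0)
        rois = fm.segment_nuclei(
            img,
            smoothing=1.0,
            min_distance=4.0,
            area_bounds=(3, 500),
            intensity_percentile=95.0,
        )
        assert rois.n_rois == 2
        d, _ = cKDTree(rois.centroids).query([(30, 25), (30, 35)])
        assert np.all(d <= 1.0)

    def test_overlapping_blobs_split_by_watershed(self):
        # 30% overlap: centers 1.4 sigma*2 apart
        img = blob_image((48, 48), [(24, 20), (24, 27)], sigma=2.5)
        rois = fm.segment_nuclei(
            img,
            smoothing=1.0,
            min_distance=3.0,
            area_bounds=(3, 500),
            intensity_percentile=90.0,
        )
        assert rois.n_rois == 2

    def test_synthetic_field_recall_and_precision(self):
        proto = fm.build_protocol(
            reps_per_direction=1,
            conditions=["square"],
            timing={"black_s": 10.0},
            seed=0,
        )
        cfg = fm.SynthConfig(
            n_neurons=100, movie_size=128, seed=3, min_spacing=8.0, nucleus_radius=3.0
        )
        raw, truth = fm.simulate_traces(cfg, proto)
        movie, _, _ = fm.render_movie(raw, truth.positions, cfg)
        rois = fm.segment_nuclei(
            movie.mean_image(), smoothing=1.5, min_distance=4.0, area_bounds=(5, 200)
        )
        d, idx = cKDTree(truth.positions).query(rois.centroids)
        matched = d <= cfg.nucleus_radius
        precision = matched.mean()
        recall = len(set(idx[matched])) / cfg.n_neurons
        assert precision >= 0.9
        assert recall >= 0.9

    def test_translation_equivariance(self):
        img = blob_image((64, 64), [(20, 20), (40, 40)])
        rois_a = fm.segment_nuclei(img, smoothing=1.0, min_distance=4.0, area_bounds=(3, 500))
        rois_b = fm.segment_nuclei(
            np.roll(img, (5, 7), axis=(0, 1)),
            smoothing=1.0,
            min_distance=4.0,
            area_bounds=(3, 500),
        )
        a = rois_a.centroids[np.lexsort(rois_a.centroids.T)]
        b = rois_b.centroids[np.lexsort(rois_b.centroids.T)] - [5, 7]
        np.testing.assert_allclose(a, b, atol=0.5)

    def test_flat_image_yields_empty_map_with_warning(self):
        with pytest.warns(UserWarning, match="no local maxima"):
            rois = fm.segment_nuclei(np.zeros((32, 32)))
        assert rois.n_rois == 0


class TestExtractTraces:
    def roi_of_pixels(self, shape, pixels):
        labels = np.zeros(shape, dtype=np.int32)
        for i, (r, c) in enumerate(pixels, start=1):
            labels[r, c] = i
        centroids = np.asarray(pixels, dtype=float)
        return fm.ROIMap(labels, centroids, np.ones(len(pixels), dtype=int))

    def test_uniform_frames_give_constant_traces(self):
        frames = np.full((5, 8, 8), 3.5)
        movie = fm.MovieStack(frames)
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 1
        rois = fm.ROIMap(labels, np.array([[2.5, 2.5]]), np.array([4]))
        traces = fm.extract_traces(movie, rois)
        np.testing.assert_allclose(traces, 3.5)

    def test_single_pixel_roi_equals_pixel_series(self, rng):
        frames = rng.uniform(0, 10, (20, 8, 8))
        movie = fm.MovieStack(frames)
        rois = self.roi_of_pixels((8, 8), [(3, 4)])
        traces = fm.extract_traces(movie, rois)
        np.testing.assert_allclose(traces[:, 0], frames[:, 3, 4])

    def test_artifact_frames_become_nan(self, rng):
        frames = rng.uniform(1, 10, (20, 8, 8))
        movie = fm.MovieStack(frames)
        rois = self.roi_of_pixels((8, 8), [(3, 4)])
        flagged = np.zeros(20, dtype=bool)
        flagged[[2, 9]] = True
        mask = fm.ArtifactMask(flagged, np.zeros(20))
        traces = fm.extract_traces(movie, rois, mask)
        assert np.isnan(traces[2, 0]) and np.isnan(traces[9, 0])
        assert np.isfinite(traces).sum() == 18

    def test_empty_roi_rejected(self):
        movie = fm.MovieStack(np.ones((5, 8, 8)))
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[1, 1] = 1  # label 2 missing entirely
        rois = fm.ROIMap(labels, np.array([[1, 1], [5, 5]]), np.array([1, 0]))
        with pytest.raises(ValueError, match="empty ROI"):
            fm.extract_traces(movie, rois)


class TestAffine:
    def test_identity_on_identical_landmarks(self, rng):
        pts = rng.uniform(0, 100, (6, 2))
        amap = fm.fit_affine(pts, pts)
        np.testing.assert_allclose(amap.linear, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(amap.translation, 0.0, atol=1e-7)
        assert amap.residual < 1e-9

    def test_known_transform_recovered(self, rng):
        src = rng.uniform(0, 100, (8, 2))
        th = np.deg2rad(10.0)
        linear = 1.1 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        ref = src @ linear.T + [5.0, -3.0]
        amap = fm.fit_affine(src, ref)
        np.testing.assert_allclose(amap.linear, linear, atol=1e-9)
        np.testing.assert_allclose(amap.translation, [5.0, -3.0], atol=1e-7)
        assert amap.residual < 1e-9
        np.testing.assert_allclose(amap.apply(src), ref, atol=1e-7)

    def test_noisy_landmarks_residual_tracks_noise(self, rng):
        src = rng.uniform(0, 100, (6, 2))
        ref = src @ np.array([[1.05, 0.02], [-0.02, 1.05]]).T + [2.0, 1.0]
        noisy_ref = ref + rng.normal(0, 0.5, ref.shape)
        amap = fm.fit_affine(src, noisy_ref)
        assert 0.05 < amap.residual < 2.0
        np.testing.assert_allclose(amap.linear, [[1.05, 0.02], [-0.02, 1.05]], atol=0.05)

    def test_collinear_landmarks_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            fm.fit_affine(src, src)


class TestQuadrants:
    frame = fm.RegionFrame(
        midline=(0.0, 1.0, -50.0),
        region="pretectum",
        rostrocaudal_divide=(1.0, 0.0, -50.0),
    )

    def test_mirrored_point_switches_hemisphere(self):
        labels = fm.assign_quadrants([[10.0, 30.0], [10.0, 70.0]], self.frame)
        assert list(labels["hemisphere"]) == ["left", "right"]

    def test_all_points_one_side(self):
        pts = [[r, 10.0] for r in range(5)]
        labels = fm.assign_quadrants(pts, self.frame)
        assert (labels["hemisphere"] == "left").all()

    def test_symmetric_population_splits_evenly(self, rng):
        pts = rng.uniform(0, 100, (2000, 2))
        labels = fm.assign_quadrants(pts, self.frame)
        frac = (labels["hemisphere"] == "right").mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(2000)  # binomial error

    def test_on_line_tie_rule_is_positive_side(self):
        labels = fm.assign_quadrants([[50.0, 50.0]], self.frame)
        assert labels.loc[0, "hemisphere"] == "right"
        assert labels.loc[0, "axis"] == "caudal"
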