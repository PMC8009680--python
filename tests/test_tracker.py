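"""Ensemble references, accurate correction, the tracking loop, RM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voltrack.core import pairwise_sq_dists
from voltrack.registration import RegistrationParams
from voltrack.segment import SegmentParams, train_classifier
from voltrack.synthetic import SceneParams, render_scene
from voltrack.tracker import (
    TrackerConfig,
    _Templates,
    accurate_correct,
    compute_rm,
    ensemble_refs,
    predict_positions,
    track_movie,
)

from .conftest import truth_positions


class TestEnsembleRefs:
    def test_earliest_times(self):
        assert ensemble_refs(2) == [1]
        assert ensemble_refs(5) == [4, 3, 2, 1]

    def test_t21_uses_all_twenty_predecessors(self):
        refs = ensemble_refs(21)
        assert refs == list(range(20, 0, -1))
        assert len(refs) == 20

    def test_t101_strided_by_quotient(self):
        refs = ensemble_refs(101)
        assert refs[0] == 96 and refs[1] == 91 and refs[-1] == 1
        assert len(refs) == 20
        assert all(a - b == 5 for a, b in zip(refs, refs[1:]))

    def test_rejects_first_volume(self):
        with pytest.raises(ValueError):
            ensemble_refs(1)

    @given(st.integers(2, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_length_bounds_and_monotonicity(self, t):
        refs = ensemble_refs(t)
        assert len(refs) == min(t - 1, 20)
        assert all(r >= 1 for r in refs)
        assert all(a > b for a, b in zip(refs, refs[1:]))


def _blob_prob(shape, center, radius):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    return np.clip(0.95 - 0.9 * (d > radius), 0.0, 1.0)


def _single_cell_setup(center_vox, radius=4):
    shape = (16, 32, 32)
    prob = _blob_prob(shape, center_vox, radius)
    template = np.zeros(shape, dtype=int)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d = np.sqrt(
        (zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2 + (xx - center_vox[2]) ** 2
    )
    template[d <= radius] = 1
    return prob, template


class TestAccurateCorrection:
    def test_fixed_point_when_already_centred(self):
        prob, template = _single_cell_setup((8, 16, 16))
        cfg = TrackerConfig(correction_max_iter=5, correction_tol=0.05)
        corrected, labels, flagged = accurate_correct(
            np.array([[8.0, 16.0, 16.0]]), prob, template, cfg
        )
        assert np.linalg.norm(corrected[0] - [8, 16, 16]) < 0.05
        assert not flagged[0]
        assert labels.max() == 1

    def test_offset_prediction_converges_to_blob_centroid(self):
        """A centre predicted 2 units off an isolated blob converges to the
        probability-weighted centroid (brute force) within tolerance."""
        prob, template = _single_cell_setup((8, 16, 16))
        w = np.where(prob > 0.5, prob, 0.0)
        idx = np.argwhere(w > 0)
        true_centroid = (w[w > 0][:, None] * idx).sum(0) / w[w > 0].sum()
        cfg = TrackerConfig(correction_max_iter=20, correction_tol=0.05)
        corrected, _, flagged = accurate_correct(
            np.array([[8.0, 18.0, 16.0]]), prob, template, cfg
        )
        assert not flagged[0]
        assert np.linalg.norm(corrected[0] - true_centroid) < 0.5

    def test_no_overlap_leaves_prediction_flagged(self):
        prob, template = _single_cell_setup((8, 16, 16), radius=3)
        cfg = TrackerConfig(correction_max_iter=3)
        far = np.array([[2.0, 4.0, 28.0]])
        corrected, _, flagged = accurate_correct(far, prob, template, cfg)
        assert flagged[0]
        np.testing.assert_allclose(corrected[0], far[0])

    def test_colliding_cells_get_disjoint_regions(self):
        """Two cells predicted onto the same blob keep disjoint painted
        regions, each containing its own seed."""
        shape = (16, 32, 32)
        prob = _blob_prob(shape, (8, 16, 14), 5)
        prob = np.maximum(prob, _blob_prob(shape, (8, 16, 22), 5))
        template = np.zeros(shape, dtype=int)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        template[np.sqrt((zz - 8) ** 2 + (yy - 16) ** 2 + (xx - 10) ** 2) <= 4] = 1
        template[np.sqrt((zz - 8) ** 2 + (yy - 16) ** 2 + (xx - 26) ** 2) <= 4] = 2
        cfg = TrackerConfig(correction_max_iter=2)
        predicted = np.array([[8.0, 16.0, 15.0], [8.0, 16.0, 20.0]])
        corrected, labels, _ = accurate_correct(predicted, prob, template, cfg)
        r1 = labels == 1
        r2 = labels == 2
        assert r1.any() and r2.any()
        assert not (r1 & r2).any()
        v1 = tuple(np.round(corrected[0]).astype(int))
        v2 = tuple(np.round(corrected[1]).astype(int))
        assert labels[v1] == 1 and labels[v2] == 2


class TestPredictPositions:
    def test_identity_when_detection_equals_reference(self, trained_ffn):
        # geometry consistent with the matcher's training distribution
        from voltrack.synthetic import random_point_cloud

        pts = random_point_cloud(120, seed=5)
        pred = predict_positions(pts, pts, trained_ffn,
                                 RegistrationParams(beta=15, lam=0.3))
        diam = np.linalg.norm(pts.max(0) - pts.min(0))
        assert np.linalg.norm(pred - pts, axis=1).max() < 5e-3 * diam

    def test_coherent_deformation_tracked(self, trained_ffn):
        """Mean prediction error stays below half the nearest-neighbour
        distance under a known smooth displacement field."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 60, (60, 3))
        disp = np.stack([
            1.5 * np.sin(pts[:, 1] / 25.0),
            2.0 * np.cos(pts[:, 2] / 30.0),
            1.5 * np.sin(pts[:, 0] / 20.0),
        ], axis=1)
        moved = pts + disp
        pred = predict_positions(pts, moved, trained_ffn,
                                 RegistrationParams(beta=20, lam=0.3))
        d2 = pairwise_sq_dists(moved, moved)
        np.fill_diagonal(d2, np.inf)
        nn = np.sqrt(d2.min(axis=1))
        assert (np.linalg.norm(pred - moved, axis=1) < 0.5 * nn).mean() > 0.95

    def test_robust_to_10_percent_missing_detections(self, trained_ffn):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 60, (60, 3))
        moved = pts + np.array([1.0, -2.0, 1.5])
        keep = rng.permutation(60)[:54]
        params = RegistrationParams(beta=20, lam=0.3)
        full = predict_positions(pts, moved, trained_ffn, params)
        part = predict_positions(pts, moved[keep], trained_ffn, params)
        err_full = np.linalg.norm(full - moved, axis=1).mean()
        err_part = np.linalg.norm(part - moved, axis=1).mean()
        assert err_part < max(2 * err_full, 0.5)


class TestComputeRM:
    def test_matches_brute_force_on_random_walks(self):
        rng = np.random.default_rng(3)
        prev = rng.uniform(0, 50, (30, 3))
        now = prev + rng.normal(0, 2, prev.shape)
        rm = compute_rm(prev, now)
        for i in range(30):
            move = np.linalg.norm(now[i] - prev[i])
            nn = min(
                np.linalg.norm(now[i] - now[j]) for j in range(30) if j != i
            )
            np.testing.assert_allclose(rm[i], move / nn, rtol=1e-9)

    def test_unit_rm_when_moving_exactly_one_neighbour_distance(self):
        prev = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        now = np.array([[0.0, 0.0, 10.0 - 1e-9], [0.0, 0.0, 20.0]])
        rm = compute_rm(prev, now)
        np.testing.assert_allclose(rm[0], 1.0, rtol=1e-6)


@pytest.fixture(scope="module")
def static_scene():
    return render_scene(
        SceneParams(n_cells=40, volume_shape=(12, 80, 80), n_volumes=5,
                    deformation_amplitude=0.0, seed=13)
    )


class TestTrackMovie:
    def test_static_scene_positions_constant_and_rm_zero(self, static_scene,
                                                         trained_ffn):
        sc = static_scene
        clf = train_classifier(
            (sc.movie.volume(0, 0), sc.truth_labels[0]),
            backend="classical_threshold",
        )
        cfg = TrackerConfig(
            use_preprocess=False,
            segment=SegmentParams(min_cell_size=20, blur_sigma=0.5),
            registration=RegistrationParams(beta=15, lam=0.3, max_iter=20),
            correction_max_iter=3,
        )
        res = track_movie(sc.movie, sc.truth_labels[0], clf, trained_ffn, cfg)
        n = sc.params.n_cells
        pos = res.tracks[["z_um", "y_um", "x_um"]].to_numpy().reshape(5, n, 3)
        for t in range(1, 5):
            # stationary cells stay put to within the blob-centroid scale
            assert np.linalg.norm(pos[t] - pos[0], axis=1).max() < 1.0
        assert (res.rm["rm"] < 0.2).all()

    def test_cell_count_conserved_and_skip_volumes_carried(self, static_scene,
                                                           trained_ffn):
        sc = static_scene
        clf = train_classifier(
            (sc.movie.volume(0, 0), sc.truth_labels[0]),
            backend="classical_threshold",
        )
        cfg = TrackerConfig(
            use_preprocess=False,
            segment=SegmentParams(min_cell_size=20, blur_sigma=0.5),
            skip_volumes=(2,),
            correction_max_iter=2,
        )
        res = track_movie(sc.movie, sc.truth_labels[0], clf, trained_ffn, cfg)
        n = sc.params.n_cells
        counts = res.tracks.groupby("t")["cell_id"].nunique()
        assert (counts == n).all()
        t2 = res.tracks[res.tracks["t"] == 2]
        t1 = res.tracks[res.tracks["t"] == 1]
        np.testing.assert_array_equal(
            t2[["z_um", "y_um", "x_um"]].to_numpy(),
            t1[["z_um", "y_um", "x_um"]].to_numpy(),
        )
        assert (t2["status"] == "carried_forward").all()
        assert (res.rm[res.rm["t"] == 2]["rm"] == 0).all()

    def test_ensemble_with_single_ref_equals_single_mode(self, static_scene,
                                                         trained_ffn):
        sc = static_scene
        clf = train_classifier(
            (sc.movie.volume(0, 0), sc.truth_labels[0]),
            backend="classical_threshold",
        )
        common = dict(
            use_preprocess=False,
            segment=SegmentParams(min_cell_size=20, blur_sigma=0.5),
            correction_max_iter=2,
        )
        res_s = track_movie(sc.movie, sc.truth_labels[0], clf, trained_ffn,
                            TrackerConfig(mode="single", **common))
        res_e = track_movie(sc.movie, sc.truth_labels[0], clf, trained_ffn,
                            TrackerConfig(mode="ensemble", ensemble_max_refs=1,
                                          **common))
        np.testing.assert_allclose(
            res_s.tracks[["z_um", "y_um", "x_um"]].to_numpy(),
            res_e.tracks[["z_um", "y_um", "x_um"]].to_numpy(),
        )

    def test_rejects_movies_with_fewer_than_two_volumes(self, static_scene,
                                                        trained_ffn):
        from voltrack.core import Movie

        sc = static_scene
        movie = Movie(sc.movie.data[:1], sc.movie.spacing)
        with pytest.raises(ValueError):
            track_movie(movie, sc.truth_labels[0], None, trained_ffn,
                        TrackerConfig())

    def test_rejects_empty_first_volume(self, static_scene, trained_ffn):
        with pytest.raises(ValueError, match="no cells"):
            track_movie(static_scene.movie,
                        np.zeros_like(static_scene.truth_labels[0]),
                        None, trained_ffn, TrackerConfig())
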