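"""Voxel classifiers, watershed instance segmentation, label ingestion."""

import numpy as np
import pytest
import tifffile

from voltrack.segment import (
    ClassicalThresholdClassifier,
    SegmentParams,
    centers_of,
    instance_segment,
    load_first_volume_segmentation,
    predict_probability,
    train_classifier,
)


def voxel_f1(prob, truth_fg):
    pred = prob > 0.5
    fg = truth_fg.astype(bool)
    return 2 * (pred & fg).sum() / max(pred.sum() + fg.sum(), 1)


class TestClassifiers:
    def test_classical_f1_on_separable_scene(self, reference_scene,
                                             reference_classifier):
        """Well-separated intensities: the threshold backend reaches F1 0.9
        against truth foreground on an unseen volume."""
        sc = reference_scene
        prob = predict_probability(reference_classifier, sc.movie.volume(10, 0))
        assert voxel_f1(prob, sc.truth_labels[10] > 0) >= 0.85

    def test_classical_probabilities_bounded(self, reference_classifier):
        prob = predict_probability(reference_classifier, np.zeros((8, 16, 16)))
        assert prob.min() >= 0 and prob.max() <= 1
        assert prob.mean() < 0.05  # empty input -> background everywhere

    def test_unet_contract_one_epoch(self, small_scene):
        """A single epoch without augmentation still yields a classifier
        whose outputs lie in [0, 1] over the whole volume."""
        sc = small_scene
        clf = train_classifier(
            (sc.movie.volume(0, 0), sc.truth_labels[0]),
            backend="unet3d_small", augmentation=False, epochs=1, seed=0,
            patch_shape=(12, 40, 40), base_channels=4, patches_per_epoch=2,
        )
        prob = predict_probability(clf, sc.movie.volume(1, 0))
        assert prob.shape == sc.movie.volume_shape
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_unet_matches_or_beats_classical(self):
        """Trained 20 epochs on one 64-cubed annotated volume, the small
        U-Net's voxelwise F1 on an unseen volume is at least the classical
        threshold backend's."""
        from voltrack.synthetic import SceneParams, render_scene

        sc = render_scene(SceneParams(
            n_cells=30, volume_shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
            cell_radius=(2.5, 0.3), deformation_amplitude=1.0,
            deformation_coherence_length=30.0, n_volumes=2, seed=5,
        ))
        train = (sc.movie.volume(0, 0), sc.truth_labels[0])
        clf_c = train_classifier(train, backend="classical_threshold")
        clf_u = train_classifier(train, backend="unet3d_small", epochs=20,
                                 seed=0, patch_shape=(16, 32, 32),
                                 patches_per_epoch=6)
        truth = sc.truth_labels[1] > 0
        f1_c = voxel_f1(predict_probability(clf_c, sc.movie.volume(1, 0)), truth)
        f1_u = voxel_f1(predict_probability(clf_u, sc.movie.volume(1, 0)), truth)
        assert clf_u.loss_history[-1] <= clf_u.loss_history[0]
        assert f1_u >= f1_c

    def test_tiling_identity_on_patch_sized_volume(self, small_scene):
        sc = small_scene
        clf = train_classifier(
            (sc.movie.volume(0, 0), sc.truth_labels[0]),
            backend="unet3d_small", augmentation=False, epochs=1, seed=0,
            patch_shape=(12, 40, 40), base_channels=4, patches_per_epoch=2,
        )
        vol = sc.movie.volume(0, 0)[:12, :40, :40]
        tiled = predict_probability(clf, vol)
        mean = clf.norm_mean
        sd = clf.norm_sd
        single = clf.predict_patch((vol - mean) / sd)
        np.testing.assert_allclose(tiled, single, atol=1e-5)

    def test_translated_blob_shifts_prediction(self, reference_classifier):
        """Moving a blob moves the probability mass with it (centroid shift
        error below one voxel)."""
        from scipy import ndimage as ndi

        vol = np.full((12, 48, 48), 10.0, dtype=np.float32)
        zz, yy, xx = np.mgrid[0:12, 0:48, 0:48]
        blob = 200 * np.exp(-(((zz - 5) ** 2) / 2 + ((yy - 20) ** 2 + (xx - 20) ** 2) / 8))
        shift = (0, 6, 9)
        p1 = predict_probability(reference_classifier, vol + blob)
        p2 = predict_probability(
            reference_classifier, vol + np.roll(blob, shift, axis=(0, 1, 2))
        )
        c1 = np.array(ndi.center_of_mass(p1 > 0.5))
        c2 = np.array(ndi.center_of_mass(p2 > 0.5))
        assert np.abs((c2 - c1) - np.array(shift)).max() < 1.0

    def test_save_load_roundtrip(self, reference_classifier, tmp_path):
        from voltrack.segment import load_classifier

        path = tmp_path / "clf.npz"
        reference_classifier.save(path)
        loaded = load_classifier(path)
        vol = np.random.default_rng(0).uniform(0, 300, (6, 20, 20))
        np.testing.assert_allclose(
            loaded.predict(vol), reference_classifier.predict(vol)
        )


class TestInstanceSegmentation:
    def test_uniform_probability_below_threshold_gives_no_labels(self):
        labels = instance_segment(np.full((8, 20, 20), 0.4), SegmentParams())
        assert labels.max() == 0

    def test_probability_exactly_half_is_background(self):
        prob = np.full((8, 20, 20), 0.5)
        with pytest.warns(UserWarning):
            labels = instance_segment(prob, SegmentParams())
        assert labels.max() == 0

    def test_two_overlapping_blobs_split_at_nearer_seed(self):
        """Two spheres overlapping by a radius yield exactly two labels,
        each containing its peak, with boundary voxels going to the nearer
        seed (verified against a brute-force nearest-seed partition)."""
        shape = (24, 48, 24)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        c1, c2 = np.array([12, 16, 12]), np.array([12, 28, 12])  # 12 apart, r=8
        r = 8
        d1 = np.sqrt((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2)
        d2 = np.sqrt((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2)
        prob = np.where((d1 <= r) | (d2 <= r), 0.9, 0.0)
        labels = instance_segment(prob, SegmentParams(min_cell_size=50))
        assert labels.max() == 2
        lab1 = labels[tuple(c1)]
        lab2 = labels[tuple(c2)]
        assert lab1 != 0 and lab2 != 0 and lab1 != lab2
        interior = (d1 <= r - 1.5) ^ (d2 <= r - 1.5)  # away from the ridge
        nearest = np.where(d1 < d2, lab1, lab2)
        agree = (labels == nearest)[interior & (labels > 0)]
        assert agree.mean() > 0.99

    def test_partition_and_min_size_invariants(self, reference_scene,
                                               reference_classifier):
        sc = reference_scene
        params = SegmentParams(min_cell_size=20, blur_sigma=0.5)
        prob = predict_probability(reference_classifier, sc.movie.volume(3, 0))
        labels = instance_segment(prob, params, spacing=sc.movie.spacing)
        mask = prob > params.prob_threshold
        # labels only inside the mask
        assert not np.any((labels > 0) & ~mask)
        sizes = np.bincount(labels.ravel())[1:]
        assert np.all(sizes >= params.min_cell_size)
        # consecutive positive labels
        ids = np.unique(labels)
        assert ids[0] == 0
        np.testing.assert_array_equal(ids[1:], np.arange(1, labels.max() + 1))

    def test_detected_count_close_to_truth(self, reference_scene,
                                           reference_classifier):
        """On a separable synthetic scene the cell count is within 5%."""
        sc = reference_scene
        params = SegmentParams(min_cell_size=20, blur_sigma=0.5)
        for t in (0, 25):
            prob = predict_probability(reference_classifier, sc.movie.volume(t, 0))
            labels = instance_segment(prob, params, spacing=sc.movie.spacing)
            n = labels.max()
            assert abs(n - sc.params.n_cells) <= 0.05 * sc.params.n_cells


class TestFirstVolumeIngestion:
    def test_roundtrip_of_segmented_labels(self, tmp_path, reference_scene,
                                           reference_classifier):
        sc = reference_scene
        prob = predict_probability(reference_classifier, sc.movie.volume(0, 0))
        labels = instance_segment(
            prob, SegmentParams(min_cell_size=20, blur_sigma=0.5),
            spacing=sc.movie.spacing,
        )
        path = tmp_path / "labels.tif"
        tifffile.imwrite(path, labels.astype(np.uint16))
        loaded = load_first_volume_segmentation(path, labels.shape)
        np.testing.assert_array_equal(loaded, labels)

    def test_disconnected_label_warns_with_offender(self, tmp_path):
        labels = np.zeros((4, 16, 16), dtype=np.uint16)
        labels[1, 2:5, 2:5] = 1
        labels[1, 10:13, 10:13] = 1  # split label 1
        labels[2, 6:9, 6:9] = 2
        path = tmp_path / "split.tif"
        tifffile.imwrite(path, labels)
        with pytest.warns(UserWarning, match=r"\[1\]"):
            load_first_volume_segmentation(path)

    def test_empty_label_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tif"
        tifffile.imwrite(path, np.zeros((4, 16, 16), dtype=np.uint16))
        with pytest.raises(ValueError, match="no cells"):
            load_first_volume_segmentation(path)

    def test_shape_mismatch_rejected(self, tmp_path):
        path = tmp_path / "labels.tif"
        arr = np.zeros((4, 16, 16), dtype=np.uint16)
        arr[1, 1, 1] = 1
        tifffile.imwrite(path, arr)
        with pytest.raises(ValueError, match="shape"):
            load_first_volume_segmentation(path, expected_shape=(5, 16, 16))


class TestCenters:
    def test_single_voxel_label_definition(self):
        labels = np.zeros((5, 6, 7), dtype=int)
        labels[2, 3, 4] = 1
        pts, ids = centers_of(labels, spacing=(1.5, 0.16, 0.16))
        np.testing.assert_allclose(pts[0], [3.0, 0.48, 0.64])
        assert list(ids) == [1]

    def test_symmetric_blob_centroid_at_centre(self):
        labels = np.zeros((9, 9, 9), dtype=int)
        labels[2:7, 2:7, 2:7] = 1
        pts, _ = centers_of(labels, spacing=(1.0, 1.0, 1.0))
        np.testing.assert_allclose(pts[0], [4.0, 4.0, 4.0], atol=1e-9)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, (6, 10, 10))
        spacing = (2.0, 0.5, 0.5)
        pts, ids = centers_of(labels, spacing)
        for k, lab in enumerate(ids):
            idx = np.argwhere(labels == lab)
            np.testing.assert_allclose(
                pts[k], idx.mean(axis=0) * np.array(spacing), atol=1e-9
            )

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            centers_of(np.zeros((3, 3, 3), dtype=int))
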