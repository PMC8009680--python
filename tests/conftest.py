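"""Shared fixtures: synthetic scenes, a trained matcher, a classifier.

Everything is generated programmatically with fixed seeds; the expensive
fixtures (matching network, reference scene) are session-scoped so the
whole suite builds them once.  Tracking parameters and the matcher recipe
were calibrated on a development realization of the scene generator; the
fixtures here use a held-out seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from voltrack.ffn import train_ffn
from voltrack.registration import RegistrationParams
from voltrack.segment import (
    SegmentParams,
    centers_of,
    instance_segment,
    predict_probability,
    train_classifier,
)
from voltrack.synthetic import (
    PairGenParams,
    SceneParams,
    random_point_cloud,
    render_scene,
    scaled_pair_params,
    training_pair_arrays,
)
from voltrack.tracker import TrackerConfig

REFERENCE_SEED = 1  # held out during parameter calibration

SCENE_SEGMENT_PARAMS = SegmentParams(min_cell_size=20, blur_sigma=0.5)


def scene_tracker_config(mode: str = "single") -> TrackerConfig:
    """Tracking configuration used for the synthetic reference scenes."""
    return TrackerConfig(
        mode=mode,
        use_preprocess=False,  # scene nuclei are rendered near-homogeneous
        segment=SegmentParams(min_cell_size=20, blur_sigma=0.5),
        registration=RegistrationParams(beta=15.0, lam=0.3, max_iter=20),
        correction_max_iter=5,
    )


@pytest.fixture(scope="session")
def base_points():
    """A 175-point base set emulating segmented cell centres."""
    return random_point_cloud(175, seed=1)


@pytest.fixture(scope="session")
def trained_ffn(base_points):
    """Matching network trained on simulated deformations of the base set."""
    arrays = training_pair_arrays(base_points, PairGenParams(seed=1), 200_000)
    return train_ffn(arrays, epochs=10, seed=1)


@pytest.fixture(scope="session")
def reference_scene():
    """The 150-cell, 50-volume scene used for tracking evaluation."""
    return render_scene(SceneParams(seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def reference_classifier(reference_scene):
    sc = reference_scene
    return train_classifier(
        (sc.movie.volume(0, 0), sc.truth_labels[0]), backend="classical_threshold"
    )


@pytest.fixture(scope="session")
def scene_ffn(reference_scene, reference_classifier):
    """Matcher trained from the scene's own segmented first volume, with
    deformation scales matched to its geometry (the same procedure a user
    would follow for a new dataset)."""
    sc = reference_scene
    prob = predict_probability(reference_classifier, sc.movie.volume(0, 0))
    det = instance_segment(prob, SCENE_SEGMENT_PARAMS, spacing=sc.movie.spacing)
    base, _ = centers_of(det, sc.movie.spacing)
    params = scaled_pair_params(base, seed=1)
    arrays = training_pair_arrays(base, params, 200_000)
    return train_ffn(arrays, epochs=10, seed=1)


@pytest.fixture(scope="session")
def persistent_scene():
    """The reference conditions with episodic (temporally persistent)
    motion, the regime of the subsampling degradation experiments: summed
    displacements grow with the skip factor instead of saturating.  The
    first volume is identical to the reference scene's, so the classifier
    and matcher carry over."""
    return render_scene(
        SceneParams(seed=REFERENCE_SEED, temporal_persistence=0.6)
    )


@pytest.fixture(scope="session")
def small_scene():
    """A light scene for fast unit tests."""
    return render_scene(
        SceneParams(
            n_cells=40,
            volume_shape=(12, 80, 80),
            n_volumes=6,
            seed=7,
        )
    )


def truth_positions(scene) -> np.ndarray:
    """(t, n, 3) truth positions from a scene's track table."""
    tr = scene.truth_tracks
    n = tr["cell_id"].nunique()
    t = tr["t"].nunique()
    return tr[["z_um", "y_um", "x_um"]].to_numpy().reshape(t, n, 3)
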