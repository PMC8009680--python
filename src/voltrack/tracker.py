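"""Per-volume tracking: predict, correct, resolve overlaps, record.

For every volume after the first, cells are segmented, the similarity
network plus non-rigid registration predicts where each tracked cell moved
(from the previous volume in single mode, averaged over up to 20 reference
volumes in ensemble mode), and the accurate-correction step pulls each
predicted centre towards the probability-weighted centroid of the
classifier-detected cell-like voxels under the cell's template region
(its shape from volume #1).  Overlapping corrected regions are re-separated
with the corrected centres as seeds.  Volumes listed in ``skip_volumes``
are not tracked: positions are carried forward unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import (
    Movie,
    STATUS_CARRIED,
    STATUS_EXITED,
    STATUS_TRACKED,
    TRACK_COLUMNS,
    pairwise_sq_dists,
)
from .ffn import FFNModel, N_NEIGHBORS, build_features, greedy_match
from .preprocess import PreprocessParams, local_contrast_normalize
from .registration import RegistrationParams, Transform, apply_transform, register
from .segment import SegmentParams, centers_of, instance_segment, predict_probability

log = logging.getLogger(__name__)


@dataclass
class TrackerConfig:
    mode: str = "single"  # or "ensemble"
    ensemble_max_refs: int = 20
    correction_max_iter: int = 1  # up to 20 until convergence for hard data
    correction_tol: float = 0.1  # µm
    interpolate_z: bool = False
    skip_volumes: tuple = ()
    use_preprocess: bool = True
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)

    def validate(self) -> None:
        if self.mode not in ("single", "ensemble"):
            raise ValueError("mode must be 'single' or 'ensemble'")
        if self.ensemble_max_refs < 1:
            raise ValueError("ensemble_max_refs must be >= 1")
        if self.correction_max_iter < 1:
            raise ValueError("correction_max_iter must be >= 1")
        self.preprocess.validate()
        self.segment.validate()
        self.registration.validate()


def ensemble_refs(t: int, max_refs: int = 20) -> list[int]:
    """Reference time points for the ensemble prediction at time ``t``.

    Times are 1-based here, matching the convention that volume #1 carries
    the manually confirmed segmentation.  For t <= max_refs the references
    are [t-1, ..., 1]; beyond that they thin out to
    [t-d, t-2d, ..., t-max_refs*d] with d = (t-1) // max_refs.
    """
    if t < 2:
        raise ValueError("ensemble references require t >= 2")
    if t - 1 <= max_refs:
        return list(range(t - 1, 0, -1))
    d = (t - 1) // max_refs
    return [t - k * d for k in range(1, max_refs + 1)]


def predict_positions(
    ref_positions: np.ndarray,
    detected: np.ndarray,
    ffn: Optional[FFNModel],
    params: RegistrationParams,
) -> np.ndarray:
    """Predict new positions of the reference cells against the detections.

    Runs scoring, greedy matching and registration, then evaluates the
    fitted transform at the reference positions (ids follow row order).
    When either set is too small for the neighbourhood descriptor, the
    registration falls back to an uninformative prior.
    """
    ref_positions = np.asarray(ref_positions, dtype=float)
    detected = np.asarray(detected, dtype=float)
    init = None
    rematcher = None
    if (
        ffn is not None
        and len(ref_positions) > N_NEIGHBORS
        and len(detected) > N_NEIGHBORS
    ):
        # the network was trained with the deformed set in the first slot,
        # so the freshly detected points go first; transpose to (ref, det)
        def _match(a, b):
            return greedy_match(
                ffn.score_matrix(build_features(b), build_features(a)).T
            )

        init = _match(ref_positions, detected)
        rematcher = _match
    transform = register(ref_positions, detected, init, params, rematcher=rematcher)
    return apply_transform(transform, ref_positions)


# ---------------------------------------------------------------------------
# accurate correction


@dataclass
class _Templates:
    """Per-cell region shapes from volume #1, as µm offsets from centroid."""

    offsets: list  # list of (k_i, 3) µm offsets
    ids: np.ndarray

    @classmethod
    def from_labels(cls, labels: np.ndarray, spacing) -> "_Templates":
        spacing = np.asarray(spacing, dtype=float)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        offsets = []
        objects = ndi.find_objects(labels)
        for lab in ids:
            sl = objects[lab - 1]
            idx = np.argwhere(labels[sl] == lab) + [s.start for s in sl]
            um = idx * spacing
            offsets.append(um - um.mean(axis=0))
        return cls(offsets=offsets, ids=ids.astype(int))


def accurate_correct(
    predicted: np.ndarray,
    prob: np.ndarray,
    template_labels: np.ndarray,
    cfg: TrackerConfig,
    spacing=(1.0, 1.0, 1.0),
    templates: Optional[_Templates] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pull predicted centres onto the detected cell-like regions.

    Each cell's template region is placed at its predicted centre and the
    centre moved (full step, up to ``correction_max_iter`` iterations or
    until the largest shift drops below ``correction_tol``) towards the
    probability-weighted centroid of cell-like voxels under the region.
    Returns ``(corrected_centres, corrected_labels, no_overlap_flags)``;
    a cell whose region covers no cell-like voxel keeps its predicted
    position and is flagged.  Voxels claimed by several cells go to the
    nearest corrected centre (seeded re-separation).
    """
    spacing = np.asarray(spacing, dtype=float)
    prob = np.asarray(prob)
    shape = np.asarray(prob.shape)
    if templates is None:
        templates = _Templates.from_labels(template_labels, spacing)
    n = len(templates.ids)
    centers = np.array(predicted, dtype=float)
    extent = shape * spacing
    clip_lo, clip_hi = np.zeros(3), extent - spacing  # centre of last voxel
    out_of_bounds = (centers < clip_lo).any(axis=1) | (centers > clip_hi).any(axis=1)
    centers = np.clip(centers, clip_lo, clip_hi)
    flagged = np.zeros(n, dtype=bool)

    order = 1 if cfg.interpolate_z else 0
    for _ in range(cfg.correction_max_iter):
        max_shift = 0.0
        for i in range(n):
            pts_um = centers[i] + templates.offsets[i]
            vox = (pts_um / spacing).T  # (3, k) fractional voxel coords
            vals = ndi.map_coordinates(prob, vox, order=order, mode="constant")
            w = np.where(vals > cfg.segment.prob_threshold, vals, 0.0)
            total = w.sum()
            if total <= 0:
                flagged[i] = True
                continue
            flagged[i] = False
            new_c = (w[:, None] * pts_um).sum(axis=0) / total
            new_c = np.clip(new_c, clip_lo, clip_hi)
            max_shift = max(max_shift, float(np.linalg.norm(new_c - centers[i])))
            centers[i] = new_c
        if max_shift < cfg.correction_tol:
            break

    # paint corrected regions; conflicts go to the nearest corrected centre
    labels_out = np.zeros(prob.shape, dtype=np.int32)
    dist_best = np.full(prob.shape, np.inf, dtype=np.float32)
    for i in range(n):
        pts_um = centers[i] + templates.offsets[i]
        vox = np.round(pts_um / spacing).astype(int)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        if len(vox) == 0:
            continue
        d = np.linalg.norm(pts_um[ok] - centers[i], axis=1).astype(np.float32)
        idx = tuple(vox.T)
        closer = d < dist_best[idx]
        sel = tuple(v[closer] for v in idx)
        labels_out[sel] = templates.ids[i]
        dist_best[sel] = d[closer]

    flagged |= out_of_bounds
    return centers, labels_out, flagged


# ---------------------------------------------------------------------------
# the tracking loop


@dataclass
class TrackResult:
    tracks: pd.DataFrame  # cell_id, t, z_um, y_um, x_um, status
    rm: pd.DataFrame  # cell_id, t, rm (undefined at the first volume)
    labels: np.ndarray  # (t, z, y, x) corrected label volumes

    def __iter__(self):  # allow (tracks, rm) unpacking
        return iter((self.tracks, self.rm))


def compute_rm(positions_prev: np.ndarray, positions_now: np.ndarray) -> np.ndarray:
    """Relative movement per cell: step length over the distance to the
    nearest other cell at the current time."""
    move = np.linalg.norm(positions_now - positions_prev, axis=1)
    d2 = pairwise_sq_dists(positions_now, positions_now)
    np.fill_diagonal(d2, np.inf)
    nn = np.sqrt(d2.min(axis=1))
    return move / np.maximum(nn, 1e-12)


def track_movie(
    movie: Movie,
    labels_t1: np.ndarray,
    clf,
    ffn: Optional[FFNModel],
    cfg: TrackerConfig,
) -> TrackResult:
    """Track every cell of the first-volume segmentation through the movie.

    Cell count is conserved: every cell id appears at every time point;
    cells that leave the volume are flagged ``exited`` and frozen.
    """
    cfg.validate()
    labels_t1 = np.asarray(labels_t1)
    if labels_t1.max() == 0:
        raise ValueError("first-volume segmentation contains no cells")
    if movie.n_volumes < 2:
        raise ValueError("movie must contain at least 2 volumes")
    spacing = np.asarray(movie.spacing)
    templates = _Templates.from_labels(labels_t1, spacing)
    ids = templates.ids
    n = len(ids)
    t_total = movie.n_volumes

    init_pts, _ = centers_of(labels_t1, spacing)
    positions = np.zeros((t_total, n, 3))
    positions[0] = init_pts
    statuses = np.full((t_total, n), STATUS_TRACKED, dtype=object)
    exited = np.zeros(n, dtype=bool)
    out_labels = np.zeros((t_total, *movie.volume_shape), dtype=np.int32)
    out_labels[0] = labels_t1
    rm_rows = []
    skip = set(int(s) for s in cfg.skip_volumes)

    for t in range(1, t_total):
        if t in skip:
            positions[t] = positions[t - 1]
            statuses[t] = np.where(exited, STATUS_EXITED, STATUS_CARRIED)
            out_labels[t] = out_labels[t - 1]
            for i in range(n):
                rm_rows.append((int(ids[i]), t, 0.0))
            continue

        vol = np.asarray(movie.volume(t, 0), dtype=np.float32)
        pre = (
            local_contrast_normalize(vol, cfg.preprocess)
            if cfg.use_preprocess
            else vol
        )
        prob = predict_probability(clf, pre)
        det = instance_segment(prob, cfg.segment, spacing)
        active = ~exited
        if det.max() > 0:
            det_pts, _ = centers_of(det, spacing)
        else:
            det_pts = np.zeros((0, 3))

        if det_pts.shape[0] >= 4 and active.sum() >= 4:
            if cfg.mode == "ensemble" and cfg.ensemble_max_refs > 1:
                refs = [r - 1 for r in ensemble_refs(t + 1, cfg.ensemble_max_refs)]
            else:
                refs = [t - 1]
            preds = []
            for r in refs:
                preds.append(
                    predict_positions(
                        positions[r][active], det_pts, ffn, cfg.registration
                    )
                )
            predicted_active = np.mean(preds, axis=0)
        else:
            log.warning("volume %d: too few detections; carrying positions", t)
            predicted_active = positions[t - 1][active]

        predicted = positions[t - 1].copy()
        predicted[active] = predicted_active
        corrected, lab_out, flagged = accurate_correct(
            predicted, prob, labels_t1, cfg, spacing, templates=templates
        )
        corrected[exited] = positions[t - 1][exited]

        # cells whose corrected centre left the volume freeze from here on
        extent = spacing * np.asarray(movie.volume_shape)
        newly_exited = active & (
            (corrected <= 0).any(axis=1) | (corrected >= extent - 1e-9).any(axis=1)
        )
        exited |= newly_exited
        corrected[newly_exited] = positions[t - 1][newly_exited]

        positions[t] = corrected
        statuses[t] = np.where(exited, STATUS_EXITED, STATUS_TRACKED)
        out_labels[t] = lab_out

        rm = compute_rm(positions[t - 1], positions[t])
        for i in range(n):
            rm_rows.append((int(ids[i]), t, float(rm[i])))

    tracks = pd.DataFrame(
        {
            "cell_id": np.tile(ids, t_total),
            "t": np.repeat(np.arange(t_total), n),
            "z_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
            "x_um": positions[:, :, 2].ravel(),
            "status": statuses.ravel(),
        }
    )[TRACK_COLUMNS]
    rm_df = pd.DataFrame(rm_rows, columns=["cell_id", "t", "rm"])
    return TrackResult(tracks=tracks, rm=rm_df, labels=out_labels)
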