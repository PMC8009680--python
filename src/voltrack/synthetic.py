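"""Synthetic data: matcher training pairs, full 3D+T scenes, degradations.

Three generators live here:

* :func:`generate_training_pairs` builds labeled descriptor pairs for the
  similarity network by deforming a base point set with a random affine
  perturbation plus per-point noise, ``x' = (I + U) x + e1 + e2`` on
  mean-removed coordinates, where ``U`` is elementwise uniform(±0.05),
  ``e1`` is uniform(±2) per point and ``e2`` is uniform(±5) applied to a
  small subset of points to mimic gross segmentation errors.
* :func:`render_scene` produces a two-channel volumetric movie of nuclei
  (Gaussian blobs, anisotropic voxels, Poisson shot noise, photobleaching)
  moved by a spatially coherent random displacement field, together with
  ground-truth labels, tracks and activity traces.
* :func:`degrade` derives harder variants of a movie: added Poisson noise,
  temporal subsampling, or sum-binning along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import cKDTree

from .core import Movie, STATUS_TRACKED, TRACK_COLUMNS, pairwise_sq_dists
from .ffn import N_NEIGHBORS, build_features


class GenerationError(RuntimeError):
    """Raised when a scene cannot be generated under the given parameters."""


# ---------------------------------------------------------------------------
# matcher training pairs


@dataclass
class PairGenParams:
    """Parameters of the random deformation used to create training pairs.

    Half-widths are the bounds of the uniform distributions: ``U`` entries
    in ±affine_half_width (unitless), the small per-point jitter e1 in
    ±small_noise_half_width and the large outlier term e2 in
    ±large_noise_half_width (both in the point set's coordinate units).
    e2 hits exactly ``n_large_noise_points`` randomly chosen points.
    """

    affine_half_width: float = 0.05
    small_noise_half_width: float = 2.0
    large_noise_half_width: float = 5.0
    n_large_noise_points: int = 20
    positive_fraction: float = 0.5
    adjacent_negative_fraction: float = 0.5
    seed: int = 0

    def validate(self, n_points: int | None = None) -> None:
        if min(
            self.affine_half_width,
            self.small_noise_half_width,
            self.large_noise_half_width,
        ) < 0:
            raise ValueError("half-widths must be non-negative")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_large_noise_points < 0:
            raise ValueError("n_large_noise_points must be non-negative")
        if n_points is not None and self.n_large_noise_points > n_points:
            raise ValueError(
                f"n_large_noise_points ({self.n_large_noise_points}) exceeds the "
                f"point-set size ({n_points})"
            )


@dataclass
class TrainingPair:
    feature_a: np.ndarray
    feature_b: np.ndarray
    label: int


def deform_point_set(
    base_centered: np.ndarray, params: PairGenParams, rng: np.random.Generator
) -> np.ndarray:
    """One random deformation ``x' = (I + U) x + e1 + e2`` of a centred set."""
    n = len(base_centered)
    u = rng.uniform(-params.affine_half_width, params.affine_half_width, (3, 3))
    e1 = rng.uniform(-params.small_noise_half_width, params.small_noise_half_width, (n, 3))
    e2 = np.zeros((n, 3))
    if params.n_large_noise_points:
        sel = rng.choice(n, size=params.n_large_noise_points, replace=False)
        e2[sel] = rng.uniform(
            -params.large_noise_half_width, params.large_noise_half_width,
            (params.n_large_noise_points, 3),
        )
    return base_centered @ (np.eye(3) + u).T + e1 + e2


def _pair_label_sequence(n_pairs: int, positive_fraction: float,
                         rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(positive_fraction * n_pairs))
    labels = np.zeros(n_pairs, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    return labels


def generate_training_pairs(
    base: np.ndarray,
    params: PairGenParams,
    n_pairs: int,
    pairs_per_set: int = 360,
):
    """Yield labeled descriptor pairs from simulated deformations of ``base``.

    Point B is drawn from the original set; its counterpart in a freshly
    deformed copy is either B's own image (label 1) or, for negatives
    (label 0), with probability ``adjacent_negative_fraction`` the image's
    nearest neighbour within the deformed set (the adjacent cell, the
    hardest negative) and otherwise a uniformly random other point (so the
    scorer also learns to reject distant cells with coincidentally similar
    neighbourhoods).  Exactly ``round(positive_fraction * n_pairs)``
    positives are emitted; output is reproducible given ``params.seed``.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim != 2 or base.shape[1] != 3:
        raise ValueError("base must be an (n, 3) point set")
    if len(base) < N_NEIGHBORS + 1:
        raise ValueError(
            f"base point set must have at least {N_NEIGHBORS + 1} points"
        )
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    params.validate(len(base))
    rng = np.random.default_rng(params.seed)
    centered = base - base.mean(axis=0)
    feats_orig = build_features(centered)
    labels = _pair_label_sequence(n_pairs, params.positive_fraction, rng)
    emitted = 0
    while emitted < n_pairs:
        deformed = deform_point_set(centered, params, rng)
        feats_def = build_features(deformed)
        tree = cKDTree(deformed)
        _, nn_idx = tree.query(deformed, k=2)
        nn_idx = nn_idx[:, 1]  # nearest other point; KD-tree ties -> lowest index
        take = min(pairs_per_set, n_pairs - emitted)
        b_indices = rng.integers(0, len(base), size=take)
        for b in b_indices:
            label = int(labels[emitted])
            if label == 1:
                a = b
            elif rng.uniform() < params.adjacent_negative_fraction:
                a = nn_idx[b]
            else:
                a = int(rng.integers(0, len(base) - 1))
                if a >= b:
                    a += 1  # any point other than B's own image
            yield TrainingPair(feats_def[a], feats_orig[b], label)
            emitted += 1


def scaled_pair_params(
    base: np.ndarray,
    seed: int = 0,
    small_noise_fraction: float = 0.15,
    large_noise_fraction: float = 0.5,
    large_noise_point_fraction: float = 0.11,
) -> PairGenParams:
    """Deformation scales transposed to a point set's own geometry.

    The canonical jitter bounds (±2 for the per-point term, ±5 for the
    outlier term, 20 of 175 points) were chosen for a worm-brain point set
    whose nearest-neighbour distances are roughly 13 of the same units;
    relative to that geometry they are ~0.15 and ~0.5 of the median
    nearest-neighbour distance, with ~11% of points carrying the outlier
    term.  This helper applies those ratios to an arbitrary base set so a
    matcher trained for one dataset sees deformations on the scale its
    data actually moves.
    """
    base = np.asarray(base, dtype=float)
    d2 = pairwise_sq_dists(base, base)
    np.fill_diagonal(d2, np.inf)
    med_nn = float(np.median(np.sqrt(d2.min(axis=1))))
    return PairGenParams(
        small_noise_half_width=small_noise_fraction * med_nn,
        large_noise_half_width=large_noise_fraction * med_nn,
        n_large_noise_points=max(1, round(large_noise_point_fraction * len(base))),
        seed=seed,
    )


def training_pair_arrays(
    base: np.ndarray, params: PairGenParams, n_pairs: int, pairs_per_set: int = 360
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Materialize :func:`generate_training_pairs` into stacked arrays."""
    fa, fb, lab = [], [], []
    for p in generate_training_pairs(base, params, n_pairs, pairs_per_set):
        fa.append(p.feature_a)
        fb.append(p.feature_b)
        lab.append(p.label)
    return np.array(fa), np.array(fb), np.array(lab)


def random_point_cloud(
    n_points: int,
    extent=(24.0, 64.0, 64.0),
    min_separation: float = 4.0,
    seed: int = 0,
    max_tries: int = 500,
) -> np.ndarray:
    """Non-overlapping random points (µm, z-y-x) in a box, for base sets."""
    rng = np.random.default_rng(seed)
    extent = np.asarray(extent, dtype=float)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_points:
        cand = rng.uniform(0, 1, 3) * extent
        if not pts or np.min(
            np.linalg.norm(np.array(pts) - cand, axis=1)
        ) >= min_separation:
            pts.append(cand)
        tries += 1
        if tries > max_tries * n_points:
            raise GenerationError(
                f"could not place {n_points} points with separation "
                f"{min_separation} in extent {tuple(extent)}"
            )
    return np.array(pts)


# ---------------------------------------------------------------------------
# full scenes


@dataclass
class SceneParams:
    """Conditions of a synthetic two-channel nuclei movie.

    Defaults describe a densely labeled tissue block: 150 nuclei of ~1.2 µm
    Gaussian radius in a 24 x 64 x 64 µm volume at anisotropic spacing
    (1.5 µm z, 0.5 µm x-y), moving each time step by a coherent random
    field whose median step is roughly a third of the nearest-neighbour
    distance.
    """

    n_cells: int = 150
    volume_shape: tuple[int, int, int] = (16, 128, 128)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.5, 0.5, 0.5)  # µm per voxel
    cell_radius: tuple[float, float] = (1.0, 0.12)  # mean, sd (µm)
    deformation_amplitude: float = 1.65  # median per-step kick (µm)
    deformation_coherence_length: float = 40.0  # µm (organ-scale coherent motion)
    # per-volume pull back toward the resting configuration: deforming
    # organs (a beating heart, a constrained brain) wander around a home
    # posture rather than drifting without bound; 0 gives a pure walk
    reversion_rate: float = 0.1
    # AR(1) correlation of the displacement field between consecutive
    # volumes: organs move in persistent episodes, so displacements summed
    # over k skipped volumes grow roughly with k instead of sqrt(k)
    temporal_persistence: float = 0.0
    # share of each step carried by a bulk (spatially uniform) motion of
    # the whole cell population, the dominant component in semi-immobilized
    # organs (whole-brain expansion/contraction, heartbeat translation);
    # the remainder is the spatially varying deformation field
    bulk_fraction: float = 0.0
    intensity_cell: float = 150.0
    intensity_bg: float = 10.0
    photobleach_rate: float = 0.002  # per-volume multiplicative decay of signal
    n_volumes: int = 50
    seed: int = 0
    shot_noise: bool = True
    excluded_volume: bool = True  # push apart nuclei whose regions would overlap

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        if self.cell_radius[0] <= 0:
            raise ValueError("mean cell radius must be positive")


@dataclass
class SyntheticScene:
    movie: Movie  # channel 0: nuclear marker, channel 1: activity reporter
    truth_labels: np.ndarray  # (t, z, y, x) int16
    truth_tracks: pd.DataFrame
    truth_activity: pd.DataFrame  # cell_id, t, ratio
    params: SceneParams = None


def _coherent_field(
    extent: np.ndarray, coherence: float, median_step: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Gaussian-filtered white vector noise on a coarse lattice (µm units)."""
    gs = max(coherence / 3.0, 2.0)  # lattice step, µm
    dims = np.maximum((extent / gs).astype(int) + 3, 4)
    field = rng.standard_normal((3, *dims))
    sig = coherence / gs
    for ax in range(3):
        field[ax] = gaussian_filter(field[ax], sigma=sig, mode="nearest")
    # rescale so the median magnitude of the 3-vector equals median_step
    # (|N(0, s)^3| has median ~1.538 s)
    sd = field.std()
    if sd > 0:
        field *= (median_step / 1.538) / sd
    return field, gs


def _sample_field(field: np.ndarray, gs: float, pts_um: np.ndarray) -> np.ndarray:
    coords = (pts_um / gs).T  # (3, n) lattice coordinates
    return np.stack(
        [map_coordinates(field[ax], coords, order=1, mode="nearest")
         for ax in range(3)], axis=1,
    )


def render_scene(params: SceneParams) -> SyntheticScene:
    """Render a deterministic synthetic movie with full ground truth.

    Ground truth (tracks, label partitions, activity ratios) is recorded
    from the noise-free geometry before shot noise is applied.  Cell count
    is conserved: no division, fusion or entry is simulated, and motion is
    reflected at the volume boundary so no cell exits.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    spacing = np.asarray(params.spacing, dtype=float)
    shape = np.asarray(params.volume_shape, dtype=int)
    extent = shape * spacing

    r_mean, r_sd = params.cell_radius
    sigmas = np.clip(
        rng.normal(r_mean, r_sd, params.n_cells), 0.8 * r_mean, 1.25 * r_mean
    )
    # keep whole label regions (2 sigma) inside the volume at all times
    margin = 2.0 * float(sigmas.max()) + 0.5
    if np.any(extent <= 2 * margin):
        raise GenerationError("volume too small for the requested cell radius")
    min_sep = 2 * 2.0 * float(sigmas.max())  # label regions extend to 2 sigma
    # rejection-sampled initial placement
    centers = np.empty((params.n_cells, 3))
    placed = 0
    tries = 0
    while placed < params.n_cells:
        cand = margin + rng.uniform(0, 1, 3) * (extent - 2 * margin)
        if placed == 0 or np.min(
            np.linalg.norm(centers[:placed] - cand, axis=1)
        ) >= min_sep:
            centers[placed] = cand
            placed += 1
        tries += 1
        if tries > 2000 * params.n_cells:
            raise GenerationError(
                f"could not place {params.n_cells} non-overlapping cells; "
                "reduce n_cells or cell_radius"
            )

    brightness = rng.uniform(0.7, 1.3, params.n_cells)
    # activity reporter: per-cell smooth oscillation with random period/phase
    periods = rng.uniform(10, 30, params.n_cells)
    phases = rng.uniform(0, 1, params.n_cells)

    positions = np.empty((params.n_volumes, params.n_cells, 3))
    positions[0] = centers
    field_state = None
    bulk_state = np.zeros(3)
    rho = params.temporal_persistence
    for t in range(1, params.n_volumes):
        field, gs = _coherent_field(
            extent, params.deformation_coherence_length,
            params.deformation_amplitude, rng,
        )
        fresh_bulk = rng.standard_normal(3) * (params.deformation_amplitude / 1.538)
        if field_state is None:
            field_state = field
            bulk_state = fresh_bulk
        else:
            field_state = rho * field_state + np.sqrt(1.0 - rho**2) * field
            bulk_state = rho * bulk_state + np.sqrt(1.0 - rho**2) * fresh_bulk
        step = (
            params.bulk_fraction * bulk_state
            + (1.0 - params.bulk_fraction)
            * _sample_field(field_state, gs, positions[t - 1])
        )
        # lattice interpolation shrinks magnitudes; rescale so the median
        # per-step displacement equals the requested amplitude exactly
        med = np.median(np.linalg.norm(step, axis=1))
        if med > 0:
            step *= params.deformation_amplitude / med
        step += params.reversion_rate * (positions[0] - positions[t - 1])
        nxt = positions[t - 1] + step
        # reflect into the interior so cells never exit
        low, high = margin, extent - margin
        nxt = np.where(nxt < low, 2 * low - nxt, nxt)
        nxt = np.where(nxt > high, 2 * high - nxt, nxt)
        nxt = np.clip(nxt, low, high)
        # excluded volume: nuclei do not interpenetrate, so push apart any
        # pair whose label regions (2 sigma each) would overlap
        for _ in range(8 if params.excluded_volume else 0):
            tree = cKDTree(nxt)
            pairs = tree.query_pairs(r=float(4.0 * sigmas.max()), output_type="ndarray")
            if len(pairs) == 0:
                break
            i, j = pairs[:, 0], pairs[:, 1]
            d = nxt[j] - nxt[i]
            dist = np.linalg.norm(d, axis=1)
            req = 2.0 * (sigmas[i] + sigmas[j])
            viol = dist < req
            if not viol.any():
                break
            i, j, d, dist, req = i[viol], j[viol], d[viol], dist[viol], req[viol]
            push = 0.5 * (req - dist) / np.maximum(dist, 1e-9)
            shift = np.zeros_like(nxt)
            np.add.at(shift, i, -d * push[:, None])
            np.add.at(shift, j, d * push[:, None])
            nxt = np.clip(nxt + shift, low, high)
        positions[t] = nxt

    nuc = np.zeros((params.n_volumes, *shape), dtype=np.float32)
    act = np.zeros_like(nuc)
    labels = np.zeros((params.n_volumes, *shape), dtype=np.int16)
    activity_rows = []
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")

    for t in range(params.n_volumes):
        bleach = (1.0 - params.photobleach_rate) ** t
        claim = np.full(shape, np.inf, dtype=np.float32)
        for c in range(params.n_cells):
            pos = positions[t, c]
            sig = sigmas[c]
            vox = pos / spacing
            half = np.ceil(3.0 * sig / spacing).astype(int)
            lo = np.maximum(np.round(vox).astype(int) - half, 0)
            hi = np.minimum(np.round(vox).astype(int) + half + 1, shape)
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            d2 = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=np.float32)
            for ax in range(3):
                coord = grids[ax][sl] * spacing[ax] - pos[ax]
                d2 += (coord * coord).astype(np.float32)
            blob = np.exp(-0.5 * d2 / sig**2)
            nuc_amp = params.intensity_cell * brightness[c] * bleach
            act_amp = params.intensity_cell * (
                0.6 + 0.4 * np.sin(2 * np.pi * (t / periods[c] + phases[c]))
            ) * bleach
            nuc[t][sl] += nuc_amp * blob
            act[t][sl] += act_amp * blob
            # label partition: voxels within 2 sigma, nearest centre in
            # sigma-normalized distance wins
            norm_d = np.sqrt(d2) / sig
            upd = (norm_d <= 2.0) & (norm_d < claim[sl])
            claim[sl][upd] = norm_d[upd]
            labels[t][sl][upd] = c + 1
            activity_rows.append((c + 1, t, act_amp / nuc_amp))
        nuc[t] += params.intensity_bg
        act[t] += params.intensity_bg

    if params.shot_noise:
        nuc = rng.poisson(nuc).astype(np.float32)
        act = rng.poisson(act).astype(np.float32)

    tracks = pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(1, params.n_cells + 1), params.n_volumes),
            "t": np.repeat(np.arange(params.n_volumes), params.n_cells),
            "z_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
            "x_um": positions[:, :, 2].ravel(),
            "status": STATUS_TRACKED,
        }
    )[TRACK_COLUMNS]
    activity = pd.DataFrame(activity_rows, columns=["cell_id", "t", "ratio"])
    movie = Movie(np.stack([nuc, act], axis=1), tuple(spacing))
    return SyntheticScene(movie, labels, tracks, activity, params)


# ---------------------------------------------------------------------------
# degradations


def add_poisson_noise(movie: Movie, sd: float, seed: int = 0) -> Movie:
    """Add zero-mean Poisson-distributed noise with the requested sd.

    Realized as ``Poisson(lambda = sd^2) - sd^2`` added per voxel and
    clipped at zero, so the injected noise has standard deviation ``sd``.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    _check_nonempty(movie)
    rng = np.random.default_rng(seed)
    lam = sd * sd
    noise = rng.poisson(lam, size=movie.data.shape).astype(np.float32) - lam
    return Movie(np.clip(movie.data + noise, 0, None), movie.spacing)


def temporal_subsample(movie: Movie, k: int) -> Movie:
    """Keep every k-th volume (the first volume is always kept)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_nonempty(movie)
    return Movie(movie.data[::k], movie.spacing)


def z_bin(movie: Movie, factor: int) -> Movie:
    """Sum-bin groups of ``factor`` adjacent z planes; z spacing scales up.

    Photon counts are conserved exactly within each binned group.  Trailing
    planes that do not fill a complete group are dropped.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    _check_nonempty(movie)
    t, c, z, y, x = movie.data.shape
    nz = z // factor
    if nz == 0:
        raise ValueError("movie has fewer z planes than the bin factor")
    binned = movie.data[:, :, : nz * factor].reshape(t, c, nz, factor, y, x).sum(axis=3)
    sz, sy, sx = movie.spacing
    return Movie(binned, (sz * factor, sy, sx))


def degrade(movie: Movie, mode: str, seed: int = 0, **kwargs) -> Movie:
    """Dispatch to one of the degradation operations.

    ``mode`` is ``"poisson_noise"`` (kwarg ``sd``), ``"temporal_subsample"``
    (kwarg ``k``) or ``"z_bin"`` (kwarg ``factor``).
    """
    if mode == "poisson_noise":
        return add_poisson_noise(movie, seed=seed, **kwargs)
    if mode == "temporal_subsample":
        return temporal_subsample(movie, **kwargs)
    if mode == "z_bin":
        return z_bin(movie, **kwargs)
    raise ValueError(f"unknown degradation mode: {mode!r}")


def _check_nonempty(movie: Movie) -> None:
    if movie.data.size == 0 or movie.n_volumes == 0:
        raise ValueError("movie is empty")
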