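"""Voxel classification and watershed instance segmentation.

A pluggable classifier turns an intensity volume into a per-voxel cell
probability: either a trainable intensity-threshold model
(``classical_threshold``) or a reduced 3D U-Net (``unet3d_small``, two
pooling levels, trainable on CPU).  Cell-like voxels (probability strictly
above 0.5) are then split into instances: Euclidean distance to background
(anisotropic spacing), Gaussian blur, local maxima as seeds, watershed
first per x-y plane and then in 3D — the two passes reflect the very
different resolutions in-plane versus along z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from . import nn
from .nn import F32
from .core import voxel_to_um

log = logging.getLogger(__name__)

PROB_THRESHOLD = 0.5  # fixed: cell-like regions are probability > 0.5


@dataclass
class SegmentParams:
    prob_threshold: float = PROB_THRESHOLD
    min_cell_size: int = 20  # voxels; typical datasets use 10-400
    blur_sigma: float = 1.0  # voxels

    def validate(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.min_cell_size < 1:
            raise ValueError("min_cell_size must be >= 1")


# ---------------------------------------------------------------------------
# classifiers


class ClassicalThresholdClassifier:
    """Soft global threshold fitted to one annotated volume.

    Probability is a logistic function of intensity around a threshold
    chosen to maximize voxelwise F1 on the training volume.  Serves as the
    non-deep baseline backend and as the fast backend for large synthetic
    runs.
    """

    backend = "classical_threshold"
    patch_shape = None

    def __init__(self, threshold: float = 0.0, width: float = 1.0):
        self.threshold = float(threshold)
        self.width = float(width)

    def fit(self, vol: np.ndarray, foreground: np.ndarray) -> "ClassicalThresholdClassifier":
        x = np.asarray(vol, dtype=float).ravel()
        fg = np.asarray(foreground, dtype=bool).ravel()
        if not fg.any() or fg.all():
            raise ValueError("annotation must contain both classes")
        lo, hi = float(x[~fg].mean()), float(x[fg].mean())
        if hi < lo:
            lo, hi = hi, lo
        best_f1, best_thr = -1.0, 0.5 * (lo + hi)
        for thr in np.linspace(lo, hi, 64):
            pred = x > thr
            tp = np.count_nonzero(pred & fg)
            f1 = 2 * tp / max(pred.sum() + fg.sum(), 1)
            if f1 > best_f1:
                best_f1, best_thr = f1, thr
        self.threshold = float(best_thr)
        self.width = max(0.05 * (hi - lo), 1e-6)
        return self

    def predict(self, vol: np.ndarray) -> np.ndarray:
        z = (np.asarray(vol, dtype=float) - self.threshold) / self.width
        return nn.sigmoid(z).astype(np.float32)

    def save(self, path) -> None:
        np.savez(path, backend="classical_threshold",
                 threshold=self.threshold, width=self.width)


class SmallUNet3D:
    """Reduced 3D U-Net: two pooling levels, 3x3x3 convolutions, numpy.

    Input and output share one channel; the logit output is squashed to a
    probability by a sigmoid.  Patch dimensions must be divisible by 4
    (two 2x2x2 poolings).
    """

    backend = "unet3d_small"

    def __init__(self, base_channels: int = 8, seed: int = 0,
                 patch_shape: tuple[int, int, int] = (16, 64, 64)):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.base_channels = c
        self.patch_shape = tuple(patch_shape)
        self.c1a = nn.Conv3D(1, c, rng)
        self.c1b = nn.Conv3D(c, c, rng)
        self.pool1 = nn.MaxPool3D((2, 2, 2))
        self.c2a = nn.Conv3D(c, 2 * c, rng)
        self.c2b = nn.Conv3D(2 * c, 2 * c, rng)
        self.pool2 = nn.MaxPool3D((2, 2, 2))
        self.c3a = nn.Conv3D(2 * c, 4 * c, rng)
        self.c3b = nn.Conv3D(4 * c, 4 * c, rng)
        self.up2 = nn.Upsample3D((2, 2, 2))
        self.d2a = nn.Conv3D(6 * c, 2 * c, rng)
        self.d2b = nn.Conv3D(2 * c, 2 * c, rng)
        self.up1 = nn.Upsample3D((2, 2, 2))
        self.d1a = nn.Conv3D(3 * c, c, rng)
        self.d1b = nn.Conv3D(c, 1, rng)
        self.loss_history: list[float] = []

    def _convs(self):
        return [self.c1a, self.c1b, self.c2a, self.c2b, self.c3a, self.c3b,
                self.d2a, self.d2b, self.d1a, self.d1b]

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, D, H, W) float32 -> logits of same shape."""
        a = {}
        h = nn.relu(self.c1a.forward(x)); a["c1a"] = h
        e1 = nn.relu(self.c1b.forward(h)); a["c1b"] = e1
        h = self.pool1.forward(e1)
        h = nn.relu(self.c2a.forward(h)); a["c2a"] = h
        e2 = nn.relu(self.c2b.forward(h)); a["c2b"] = e2
        h = self.pool2.forward(e2)
        h = nn.relu(self.c3a.forward(h)); a["c3a"] = h
        h = nn.relu(self.c3b.forward(h)); a["c3b"] = h
        h = np.concatenate([self.up2.forward(h), e2], axis=1)
        h = nn.relu(self.d2a.forward(h)); a["d2a"] = h
        h = nn.relu(self.d2b.forward(h)); a["d2b"] = h
        h = np.concatenate([self.up1.forward(h), e1], axis=1)
        h = nn.relu(self.d1a.forward(h)); a["d1a"] = h
        self._acts = a
        return self.d1b.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        a = self._acts
        c = self.base_channels
        dh = self.d1b.backward(dlogits)
        dh = self.d1a.backward(nn.drelu(a["d1a"], dh))
        dup1, de1 = dh[:, : 2 * c], dh[:, 2 * c :]
        dh = self.up1.backward(dup1)
        dh = self.d2b.backward(nn.drelu(a["d2b"], dh))
        dh = self.d2a.backward(nn.drelu(a["d2a"], dh))
        dup2, de2 = dh[:, : 4 * c], dh[:, 4 * c :]
        dh = self.up2.backward(dup2)
        dh = self.c3b.backward(nn.drelu(a["c3b"], dh))
        dh = self.c3a.backward(nn.drelu(a["c3a"], dh))
        dh = self.pool2.backward(dh) + de2
        dh = self.c2b.backward(nn.drelu(a["c2b"], dh))
        dh = self.c2a.backward(nn.drelu(a["c2a"], dh))
        dh = self.pool1.backward(dh) + de1
        dh = self.c1b.backward(nn.drelu(a["c1b"], dh))
        self.c1a.backward(nn.drelu(a["c1a"], dh))

    def predict(self, vol: np.ndarray) -> np.ndarray:
        return predict_probability(self, vol)

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        logits = self.forward_logits(
            np.asarray(patch, dtype=F32)[None, None]
        )
        return nn.sigmoid(logits[0, 0]).astype(np.float32)

    def save(self, path) -> None:
        arrays = {"backend": "unet3d_small",
                  "base_channels": self.base_channels,
                  "patch_shape": np.array(self.patch_shape)}
        for i, conv in enumerate(self._convs()):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        np.savez(path, **arrays)


def load_classifier(path):
    d = np.load(path, allow_pickle=False)
    backend = str(d["backend"])
    if backend == "classical_threshold":
        return ClassicalThresholdClassifier(float(d["threshold"]), float(d["width"]))
    model = SmallUNet3D(base_channels=int(d["base_channels"]),
                        patch_shape=tuple(int(v) for v in d["patch_shape"]))
    for i, conv in enumerate(model._convs()):
        conv.W = d[f"W{i}"]
        conv.b = d[f"b{i}"]
    return model


# ---------------------------------------------------------------------------
# training


def _random_xy_affine(rng: np.random.Generator):
    """Random affine restricted to the x-y plane (rotation, scale, shear)."""
    ang = rng.uniform(-np.pi, np.pi)
    scale = rng.uniform(0.9, 1.1, size=2)
    shear = rng.uniform(-0.1, 0.1)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    sh = np.array([[1.0, shear], [0.0, 1.0]])
    return rot @ sh @ np.diag(scale)


def _apply_xy_affine(vol: np.ndarray, mat: np.ndarray, order: int) -> np.ndarray:
    """Apply one 2-D affine about the plane centre to every z slice."""
    center = (np.asarray(vol.shape[1:]) - 1) / 2.0
    offset = center - mat @ center
    out = np.empty_like(vol)
    for z in range(vol.shape[0]):
        out[z] = ndi.affine_transform(
            vol[z], mat, offset=offset, order=order, mode="reflect"
        )
    return out


def _cut_patches(vol: np.ndarray, fg: np.ndarray, patch_shape, rng, n: int):
    """Random patches (with reflection padding for undersized volumes)."""
    pz, py, px = patch_shape
    pad = [(0, max(0, p - s)) for p, s in zip(patch_shape, vol.shape)]
    if any(p[1] for p in pad):
        vol = np.pad(vol, pad, mode="reflect")
        fg = np.pad(fg, pad, mode="reflect")
    starts = [rng.integers(0, s - p + 1, size=n)
              for s, p in zip(vol.shape, patch_shape)]
    for i in range(n):
        sl = tuple(slice(st[i], st[i] + p)
                   for st, p in zip(starts, patch_shape))
        yield vol[sl], fg[sl]


def train_classifier(
    annotated: tuple[np.ndarray, np.ndarray],
    backend: str = "unet3d_small",
    augmentation: bool = True,
    epochs: int = 20,
    seed: int = 0,
    patch_shape: tuple[int, int, int] = (16, 64, 64),
    base_channels: int = 8,
    lr: float = 3e-3,
    patches_per_epoch: int = 8,
):
    """Train a voxel classifier from one annotated volume.

    ``annotated`` is ``(intensity_volume, label_volume)``; labels are
    binarized to cell / non-cell.  For the U-Net backend, random patches
    are cut from the volume and augmented by random affine transforms
    restricted to the x-y plane (the z resolution is too coarse for
    rotations through z to be meaningful).
    """
    vol, labels = annotated
    vol = np.asarray(vol, dtype=np.float32)
    fg = (np.asarray(labels) > 0).astype(np.float32)
    if backend == "classical_threshold":
        return ClassicalThresholdClassifier().fit(vol, fg > 0)
    if backend != "unet3d_small":
        raise ValueError(f"unknown backend: {backend!r}")
    if any(p % 4 != 0 for p in patch_shape):
        raise ValueError("patch dimensions must be divisible by 4")

    rng = np.random.default_rng(seed)
    model = SmallUNet3D(base_channels=base_channels, seed=seed,
                        patch_shape=patch_shape)
    # normalize intensities once; prediction applies the same statistics
    model.norm_mean = float(vol.mean())
    model.norm_sd = float(vol.std() + 1e-6)
    voln = (vol - model.norm_mean) / model.norm_sd
    opt = nn.Adam(model._convs(), lr=lr)
    for _ in range(epochs):
        losses = []
        for img, lab in _cut_patches(voln, fg, patch_shape, rng, patches_per_epoch):
            if augmentation:
                mat = _random_xy_affine(rng)
                img = _apply_xy_affine(img, mat, order=1)
                lab = (_apply_xy_affine(lab, mat, order=0) > 0.5).astype(np.float32)
            logits = model.forward_logits(img[None, None].astype(F32))
            loss, dz = nn.bce_with_logits(logits.ravel(), lab.ravel())
            model.backward(dz.reshape(logits.shape))
            opt.step()
            losses.append(loss)
        model.loss_history.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# prediction with tiling


def predict_probability(clf, vol: np.ndarray) -> np.ndarray:
    """Per-voxel cell probability over an arbitrarily sized volume.

    U-Net volumes are tiled into overlapping patches (25% overlap,
    reflect-padded at the borders) and the tile predictions averaged where
    they overlap; a volume exactly equal to the patch shape is a single
    tile, so stitching is the identity there.
    """
    vol = np.asarray(vol, dtype=np.float32)
    if isinstance(clf, ClassicalThresholdClassifier):
        return clf.predict(vol)
    mean = getattr(clf, "norm_mean", 0.0)
    sd = getattr(clf, "norm_sd", 1.0)
    voln = (vol - mean) / sd
    patch = clf.patch_shape
    pad = [(0, max(0, p - s)) for p, s in zip(patch, voln.shape)]
    padded = np.pad(voln, pad, mode="reflect") if any(p[1] for p in pad) else voln
    shape = padded.shape
    strides = [max(p - p // 4, 1) for p in patch]
    starts = []
    for s, p, st in zip(shape, patch, strides):
        ax = list(range(0, max(s - p, 0) + 1, st))
        if ax[-1] != s - p:
            ax.append(s - p)
        starts.append(ax)
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]),
                      slice(x0, x0 + patch[2]))
                logits = clf.forward_logits(padded[sl][None, None])
                acc[sl] += nn.sigmoid(logits[0, 0])
                cnt[sl] += 1.0
    prob = (acc / cnt).astype(np.float32)
    return prob[tuple(slice(0, s) for s in vol.shape)]


# ---------------------------------------------------------------------------
# watershed instance segmentation


def _find_seeds(
    blurred: np.ndarray, mask: np.ndarray, min_cell_size: int,
    spacing=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Seed markers: local maxima of the blurred distance map.

    The only free scale, the minimum peak separation, is keyed to the
    existing minimum-cell-size parameter: the radius (µm) of a cube of
    ``min_cell_size`` voxels, converted to voxels per axis so the
    neighbourhood is physically isotropic despite anisotropic spacing.
    Plateau maxima are merged to a single seed at the plateau centroid.
    """
    spacing = np.asarray(spacing, dtype=float)
    half_um = (min_cell_size * float(np.prod(spacing))) ** (1.0 / 3.0) / 2.0
    half_vox = np.maximum(np.round(half_um / spacing).astype(int), 1)
    size = tuple(2 * half_vox + 1)
    local_max = (blurred == ndi.maximum_filter(blurred, size=size)) & mask
    plateaus, n = ndi.label(local_max)
    markers = np.zeros_like(plateaus, dtype=np.int32)
    if n:
        centroids = ndi.center_of_mass(local_max, plateaus, range(1, n + 1))
        for i, cz in enumerate(centroids, start=1):
            idx = tuple(int(round(v)) for v in cz)
            markers[idx] = i
    return markers


def instance_segment(
    prob: np.ndarray,
    params: SegmentParams,
    spacing=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Split the probability volume into labeled cell instances.

    Voxels with probability strictly above the 0.5 threshold form the
    cell-like mask.  Seeds come from the blurred anisotropic distance
    transform; a per-plane 2D watershed carves in-plane boundaries between
    distinct seeds (encoded as barriers), and the final 3D seeded watershed
    produces the instance partition.  Regions smaller than
    ``min_cell_size`` voxels are dropped and labels renumbered 1..K.
    """
    params.validate()
    prob = np.asarray(prob)
    mask = prob > params.prob_threshold
    if not mask.any():
        warnings.warn("no cell-like voxels above threshold; returning empty labels")
        return np.zeros(prob.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask, sampling=spacing)
    blurred = ndi.gaussian_filter(dist, sigma=params.blur_sigma)
    markers = _find_seeds(blurred, mask, params.min_cell_size, spacing)

    # pass 1: 2D watershed within each x-y plane using the seeds of that
    # plane; boundaries between different in-plane cells become barriers
    landscape = blurred.copy()
    for z in range(prob.shape[0]):
        if not markers[z].any() or not mask[z].any():
            continue
        lab2d = watershed(-blurred[z], markers=markers[z], mask=mask[z])
        bnd = np.zeros_like(lab2d, dtype=bool)
        for ax in (0, 1):
            d = np.diff(lab2d, axis=ax)
            edge = (d != 0)
            sl = [slice(None)] * 2
            sl[ax] = slice(0, -1)
            with_lab = (lab2d[tuple(sl)] > 0) & edge
            bnd[tuple(sl)] |= with_lab
        bnd &= lab2d > 0
        landscape[z][bnd] = 0.0

    # pass 2: 3D watershed over the barrier-carved landscape
    labels = watershed(-landscape, markers=markers, mask=mask).astype(np.int32)

    # drop small regions, renumber consecutively
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= params.min_cell_size)
    keep = keep[keep > 0]
    remap = np.zeros(sizes.size, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return remap[labels]


def load_first_volume_segmentation(path, expected_shape: Optional[tuple] = None) -> np.ndarray:
    """Read the manually corrected label volume for volume #1.

    The file must be an integer label TIFF; labels become the tracked cell
    identities for all later time points.  Disconnected labels are accepted
    with a warning (manual edits sometimes leave slivers).
    """
    labels = np.asarray(tifffile.imread(str(path)))
    if labels.ndim == 2:
        labels = labels[None]
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("first-volume segmentation must be an integer label TIFF")
    if labels.min() < 0:
        raise ValueError("label volume contains negative values")
    if expected_shape is not None and tuple(labels.shape) != tuple(expected_shape):
        raise ValueError(
            f"label volume shape {labels.shape} does not match movie volume "
            f"shape {tuple(expected_shape)}"
        )
    if labels.max() == 0:
        raise ValueError("no cells in first volume")
    bad = []
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        _, n_parts = ndi.label(labels[sl] == lab)
        if n_parts > 1:
            bad.append(lab)
    if bad:
        warnings.warn(f"labels split into disconnected components: {bad}")
    return labels.astype(np.int32)


def centers_of(labels: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    """Per-label centroids in physical µm, ordered by label id.

    Returns ``(points, ids)`` where ``points`` is (n, 3) µm (z, y, x).
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label volume contains no labels")
    centroids = ndi.center_of_mass(labels > 0, labels, ids)
    return voxel_to_um(np.array(centroids), spacing), ids.astype(int)
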