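"""Point matching across volumes with a learned similarity network.

Each cell centre is described by the positions of its 20 nearest
neighbours: the offset vectors are divided by the mean neighbour distance
d̄, sorted by ascending magnitude, and d̄ itself is appended, giving a 61-D
descriptor that is invariant to translation and (except for the final
component) to uniform scaling.  A three-layer fully connected network with
a shared 61→512 encoder per point, a 1024→512 comparison layer and a
sigmoid output scores whether two descriptors belong to the same cell; the
greedy one-to-one sweep over the score matrix yields the initial matching
that seeds the non-rigid registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .nn import F32

N_NEIGHBORS = 20
FEATURE_DIM = 3 * N_NEIGHBORS + 1  # 61
HIDDEN = 512

__all__ = [
    "FEATURE_DIM",
    "HIDDEN",
    "build_feature",
    "build_features",
    "FFNModel",
    "train_ffn",
    "score_pairs",
    "greedy_match",
    "InitialMatching",
]


def build_features(pts: np.ndarray) -> np.ndarray:
    """61-D neighbourhood descriptors for every point of a set.

    Offsets to the 20 nearest neighbours (Euclidean, physical coordinates)
    are normalized by the mean neighbour distance and sorted by ascending
    magnitude (ties broken lexicographically on the (z, y, x) offset); the
    mean distance is the 61st component.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    if n < N_NEIGHBORS + 1:
        raise ValueError(
            f"feature construction requires at least {N_NEIGHBORS + 1} points; got {n}"
        )
    tree = cKDTree(pts)
    dists, idx = tree.query(pts, k=N_NEIGHBORS + 1)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self
    dbar = dists.mean(axis=1)  # (n,)
    offsets = (pts[idx] - pts[:, None, :]) / dbar[:, None, None]  # (n, 20, 3)
    mags = np.linalg.norm(offsets, axis=2)
    # sort by magnitude, ties by lexicographic (z, y, x) offset
    order = np.lexsort(
        (offsets[:, :, 2], offsets[:, :, 1], offsets[:, :, 0], mags), axis=1
    )
    offsets = np.take_along_axis(offsets, order[:, :, None], axis=1)
    return np.concatenate(
        [offsets.reshape(n, 3 * N_NEIGHBORS), dbar[:, None]], axis=1
    )


def build_feature(i: int, pts: np.ndarray) -> np.ndarray:
    """Descriptor of a single point (see :func:`build_features`)."""
    return build_features(pts)[i]


# ---------------------------------------------------------------------------
# similarity network


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)


class FFNModel:
    """Three-layer similarity network with a shared per-point encoder.

    Architecture: 61 → 512 (Dense + BN + ReLU, weights shared between the
    two points) → concatenate → 1024 → 512 (Dense + BN + ReLU) → 512 → 1
    (sigmoid).  Batch statistics are frozen at inference.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.enc = nn.Dense(FEATURE_DIM, HIDDEN, rng)
        self.bn1 = nn.BatchNorm(HIDDEN)
        self.cmp = nn.Dense(2 * HIDDEN, HIDDEN, rng)
        self.bn2 = nn.BatchNorm(HIDDEN)
        self.out = nn.Dense(HIDDEN, 1, rng)
        self.history = TrainHistory()

    # -- modes ------------------------------------------------------------
    def _set_training(self, flag: bool) -> None:
        self.bn1.training = flag
        self.bn2.training = flag

    def _layers(self):
        return [self.enc, self.bn1, self.cmp, self.bn2, self.out]

    # -- forward / backward ------------------------------------------------
    def _forward(self, fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
        x = np.vstack([fa, fb]).astype(F32)
        z1 = self.bn1.forward(self.enc.forward(x))
        h1 = nn.relu(z1)
        self._z1 = z1
        m = len(fa)
        h = np.concatenate([h1[:m], h1[m:]], axis=1)
        z2 = self.bn2.forward(self.cmp.forward(h))
        self._z2 = z2
        h2 = nn.relu(z2)
        return self.out.forward(h2)[:, 0]

    def _backward(self, dlogit: np.ndarray) -> None:
        dh2 = self.out.backward(dlogit[:, None])
        dz2 = nn.drelu(self._z2, dh2)
        dh = self.cmp.backward(self.bn2.backward(dz2))
        dh1 = np.vstack([dh[:, :HIDDEN], dh[:, HIDDEN:]])
        dz1 = nn.drelu(self._z1, dh1)
        self.enc.backward(self.bn1.backward(dz1))

    # -- public api --------------------------------------------------------
    def similarity(self, fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
        """Scores for aligned rows of two descriptor arrays, in (0, 1)."""
        self._set_training(False)
        fa = np.atleast_2d(np.asarray(fa, dtype=F32))
        fb = np.atleast_2d(np.asarray(fb, dtype=F32))
        return nn.sigmoid(self._forward(fa, fb))

    def fit(
        self,
        fa: np.ndarray,
        fb: np.ndarray,
        labels: np.ndarray,
        epochs: int = 5,
        batch_size: int = 128,
        lr: float = 1e-3,
        val_fraction: float = 0.1,
        seed: int = 0,
    ) -> TrainHistory:
        labels = np.asarray(labels, dtype=F32)
        if labels.min() == labels.max():
            raise ValueError("training stream contains a single class")
        rng = np.random.default_rng(seed)
        n = len(labels)
        perm = rng.permutation(n)
        n_val = int(round(val_fraction * n))
        val, trn = perm[:n_val], perm[n_val:]
        fa = np.asarray(fa, dtype=F32)
        fb = np.asarray(fb, dtype=F32)
        opt = nn.Adam(self._layers(), lr=lr)
        for _ in range(epochs):
            order = rng.permutation(trn)
            losses = []
            self._set_training(True)
            for start in range(0, len(order), batch_size):
                sel = order[start : start + batch_size]
                if len(sel) < 2:
                    continue
                z = self._forward(fa[sel], fb[sel])
                loss, dz = nn.bce_with_logits(z, labels[sel])
                self._backward(dz)
                opt.step()
                losses.append(loss)
            self.history.loss.append(float(np.mean(losses)))
            if n_val:
                pred = self.similarity(fa[val], fb[val]) > 0.5
                self.history.val_accuracy.append(
                    float(np.mean(pred == (labels[val] > 0.5)))
                )
        return self.history

    # -- efficient all-pairs scoring --------------------------------------
    def score_matrix(
        self, feats_a: np.ndarray, feats_b: np.ndarray, row_chunk: int = 256
    ) -> np.ndarray:
        """Similarity of every A descriptor against every B descriptor.

        Exploits the shared encoder: each point is encoded once, and the
        comparison layer's weight matrix is split into its A and B halves so
        the pairwise pass is a broadcast sum instead of |A|x|B| forward
        passes.
        """
        self._set_training(False)
        fa = np.asarray(feats_a, dtype=F32)
        fb = np.asarray(feats_b, dtype=F32)

        def encode(f):
            z = self.enc.forward(f)
            z = self.bn1.forward(z)
            return nn.relu(z)

        ha, hb = encode(fa), encode(fb)
        w_a, w_b = self.cmp.W[:HIDDEN], self.cmp.W[HIDDEN:]
        pa = ha @ w_a  # (m, 512)
        pb = hb @ w_b + self.cmp.b  # (n, 512)
        # fold eval-mode batchnorm into an affine map
        scale = self.bn2.gamma / np.sqrt(self.bn2.run_var + self.bn2.eps)
        shift = self.bn2.beta - self.bn2.run_mean * scale
        m, n = len(fa), len(fb)
        out = np.empty((m, n), dtype=F32)
        for s in range(0, m, row_chunk):
            e = min(s + row_chunk, m)
            z2 = (pa[s:e, None, :] + pb[None, :, :]) * scale + shift
            h2 = nn.relu(z2)
            out[s:e] = nn.sigmoid(
                (h2 @ self.out.W)[:, :, 0] + self.out.b[0]
            )
        return out

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            enc_W=self.enc.W,
            enc_b=self.enc.b,
            bn1_gamma=self.bn1.gamma,
            bn1_beta=self.bn1.beta,
            bn1_mean=self.bn1.run_mean,
            bn1_var=self.bn1.run_var,
            cmp_W=self.cmp.W,
            cmp_b=self.cmp.b,
            bn2_gamma=self.bn2.gamma,
            bn2_beta=self.bn2.beta,
            bn2_mean=self.bn2.run_mean,
            bn2_var=self.bn2.run_var,
            out_W=self.out.W,
            out_b=self.out.b,
        )

    @classmethod
    def load(cls, path) -> "FFNModel":
        d = np.load(path)
        model = cls(seed=0)
        model.enc.W, model.enc.b = d["enc_W"], d["enc_b"]
        model.bn1.gamma, model.bn1.beta = d["bn1_gamma"], d["bn1_beta"]
        model.bn1.run_mean, model.bn1.run_var = d["bn1_mean"], d["bn1_var"]
        model.cmp.W, model.cmp.b = d["cmp_W"], d["cmp_b"]
        model.bn2.gamma, model.bn2.beta = d["bn2_gamma"], d["bn2_beta"]
        model.bn2.run_mean, model.bn2.run_var = d["bn2_mean"], d["bn2_var"]
        model.out.W, model.out.b = d["out_W"], d["out_b"]
        return model


def train_ffn(
    pairs,
    epochs: int = 5,
    batch_size: int = 128,
    seed: int = 0,
    lr: float = 1e-3,
) -> FFNModel:
    """Train a similarity network from a stream (or arrays) of labeled pairs.

    ``pairs`` is either an iterable of objects with ``feature_a``,
    ``feature_b`` and ``label`` attributes, or a ``(feats_a, feats_b,
    labels)`` tuple of arrays.
    """
    if isinstance(pairs, tuple) and len(pairs) == 3:
        fa, fb, labels = pairs
    else:
        items = list(pairs)
        fa = np.array([p.feature_a for p in items])
        fb = np.array([p.feature_b for p in items])
        labels = np.array([p.label for p in items])
    model = FFNModel(seed=seed)
    model.fit(fa, fb, labels, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed)
    return model


def score_pairs(ffn: FFNModel, set_a: np.ndarray, set_b: np.ndarray) -> np.ndarray:
    """Score matrix (|A| x |B|) between all cells of two point sets."""
    return ffn.score_matrix(build_features(set_a), build_features(set_b))


@dataclass
class InitialMatching:
    """Injective pairing produced by the greedy sweep over a score matrix."""

    pairs: list  # (index_a, index_b, score)
    unmatched_a: list
    unmatched_b: list

    def as_dict(self) -> dict:
        return {a: b for a, b, _ in self.pairs}


def greedy_match(scores: np.ndarray, min_score: float = 0.5) -> InitialMatching:
    """Repeatedly pair the globally best remaining (row, col) entry.

    The highest remaining score is selected, its row and column removed, and
    the process repeats until the best remaining score falls below
    ``min_score`` or one side is exhausted.  Ties resolve to the lowest row,
    then column, index.
    """
    s = np.array(scores, dtype=float)
    if s.ndim != 2:
        raise ValueError("score matrix must be 2-D")
    m, n = s.shape
    pairs = []
    for _ in range(min(m, n)):
        flat = int(np.argmax(s))  # first occurrence = lowest (row, col)
        i, j = divmod(flat, n)
        best = s[i, j]
        if best < min_score:
            break
        pairs.append((int(i), int(j), float(scores[i, j])))
        s[i, :] = -np.inf
        s[:, j] = -np.inf
    used_a = {a for a, _, _ in pairs}
    used_b = {b for _, b, _ in pairs}
    return InitialMatching(
        pairs=pairs,
        unmatched_a=[i for i in range(m) if i not in used_a],
        unmatched_b=[j for j in range(n) if j not in used_b],
    )
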