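"""EM-based non-rigid point-set registration with matching priors.

The initial matching produced by the similarity network is refined into a
spatially coherent transformation: cells are treated as centroids of an
isotropic Gaussian mixture with a uniform outlier component, and the
displacement field lives in the RKHS of a Gaussian kernel of width ``beta``
(motion coherence: neighbouring cells move alike).  The E step computes
posterior correspondence probabilities with the initial matching injected
as prior weights; the M step solves the ``lam``-regularized kernel least
squares for the displacement coefficients.  The mixture variance is
initialized from the residual of the initial matching and re-estimated
every iteration (no deterministic annealing schedule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .core import pairwise_sq_dists
from .ffn import InitialMatching


@dataclass
class RegistrationParams:
    """beta: kernel width (same units as the coordinates, typically µm).

    lam: regularization weight on the displacement field's RKHS norm.
    rematch_every: if set, the matcher callback is re-invoked on the moved
    points every that many EM iterations (useful for very large movements).
    outlier_weight: prior mass of the uniform outlier component, in [0, 1).
    """

    beta: float = 15.0
    lam: float = 0.1
    max_iter: int = 20
    rematch_every: Optional[int] = None
    outlier_weight: float = 0.1
    # prior probability that a greedy-matched pair is the true
    # correspondence; 1.0 makes the matching binding (no reassignment)
    prior_confidence: float = 0.9
    tol_fraction: float = 1e-4  # of the moving set's diameter
    # the mixture variance never drops below (this fraction x median
    # nearest-neighbour distance of the target set)^2, so the matching
    # prior stays influential relative to raw proximity; 0 disables
    sigma_floor_fraction: float = 0.3

    def validate(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.outlier_weight < 1.0:
            raise ValueError("outlier_weight must be in [0, 1)")


@dataclass
class Transform:
    """Smooth displacement mapping T(x) = x + sum_i c_i k(x, anchor_i).

    ``k`` is a Gaussian kernel of width ``beta``; with all coefficients
    zero, T is the identity.
    """

    anchors: np.ndarray  # (m, 3)
    coefficients: np.ndarray  # (m, 3)
    beta: float

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return apply_transform(self, pts)


def apply_transform(transform: Transform, pts: np.ndarray) -> np.ndarray:
    """Evaluate the transform at each point; ordering is preserved."""
    pts = np.asarray(pts, dtype=float)
    k = np.exp(
        -pairwise_sq_dists(pts, transform.anchors) / (2.0 * transform.beta**2)
    )
    return pts + k @ transform.coefficients


def _prior_matrix(
    init: Union[InitialMatching, np.ndarray, None], m: int, n: int,
    match_confidence: float = 0.9,
) -> np.ndarray:
    """Per-row correspondence priors from a matching or a score matrix."""
    if init is None:
        return np.full((m, n), 1.0 / n)
    if isinstance(init, InitialMatching):
        p = np.full((m, n), 1.0 / n)
        if n > 1:
            off = (1.0 - match_confidence) / (n - 1)
            for a, b, _ in init.pairs:
                p[a, :] = off
                p[a, b] = match_confidence
        return p
    scores = np.asarray(init, dtype=float)
    if scores.shape != (m, n):
        raise ValueError("score matrix shape does not match the point sets")
    p = scores + 1e-6
    return p / p.sum(axis=1, keepdims=True)


def register(
    set_a: np.ndarray,
    set_b: np.ndarray,
    init: Union[InitialMatching, np.ndarray, None],
    params: RegistrationParams,
    rematcher: Optional[Callable] = None,
) -> Transform:
    """Fit a coherent transformation moving ``set_a`` towards ``set_b``.

    ``init`` may be an :class:`InitialMatching`, a raw score matrix, or
    None (uninformative prior).  Returns the final :class:`Transform` whose
    anchors are the points of ``set_a``.
    """
    params.validate()
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    m, n = len(a), len(b)
    prior = _prior_matrix(init, m, n, match_confidence=params.prior_confidence)
    g = np.exp(-pairwise_sq_dists(a, a) / (2.0 * params.beta**2))
    coeffs = np.zeros((m, 3))
    diam = float(np.linalg.norm(b.max(axis=0) - b.min(axis=0))) or 1.0
    tol = params.tol_fraction * max(
        diam, float(np.linalg.norm(a.max(axis=0) - a.min(axis=0)))
    )
    volume = float(np.prod(np.maximum(b.max(axis=0) - b.min(axis=0), 1e-6)))
    w = params.outlier_weight

    if len(b) > 1:
        d2b = pairwise_sq_dists(b, b)
        np.fill_diagonal(d2b, np.inf)
        nn_med = float(np.median(np.sqrt(d2b.min(axis=1))))
    else:
        nn_med = diam
    # two floors: the E-step floor keeps the matching prior influential
    # against raw proximity; the (much smaller) M-step floor only guards
    # the conditioning of the ridge and lets good fits converge tightly
    sigma2_floor = max((params.sigma_floor_fraction * nn_med) ** 2,
                       1e-10 * diam**2)
    sigma2_reg_floor = max((0.05 * nn_med) ** 2, 1e-10 * diam**2)

    # variance from the initial matching's residuals
    if isinstance(init, InitialMatching) and init.pairs:
        res = [np.sum((a[i] - b[j]) ** 2) for i, j, _ in init.pairs]
        sigma2_est = float(np.mean(res))
    else:
        sigma2_est = pairwise_sq_dists(a, b).mean() / 3.0
    sigma2 = max(sigma2_est, sigma2_floor)

    prior_col = prior / np.maximum(prior.sum(axis=0, keepdims=True), 1e-12)
    for it in range(params.max_iter):
        if (
            params.rematch_every
            and rematcher is not None
            and it > 0
            and it % params.rematch_every == 0
        ):
            new_init = rematcher(a + g @ coeffs, b)
            prior = _prior_matrix(new_init, m, n,
                                  match_confidence=params.prior_confidence)
            prior_col = prior / np.maximum(prior.sum(axis=0, keepdims=True), 1e-12)

        ta = a + g @ coeffs
        d2 = pairwise_sq_dists(ta, b)
        phi = np.exp(-d2 / (2.0 * sigma2)) / (2.0 * np.pi * sigma2) ** 1.5
        num = (1.0 - w) * prior_col * phi
        denom = num.sum(axis=0, keepdims=True) + w / volume
        post = num / np.maximum(denom, 1e-300)  # (m, n) posteriors

        p1 = post.sum(axis=1)  # (m,)
        px = post @ b  # (m, 3)
        safe = np.maximum(p1, 1e-12)
        target = px / safe[:, None] - a  # desired displacement per anchor
        sigma2_reg = max(sigma2_est, sigma2_reg_floor)
        lhs = g + params.lam * sigma2_reg * np.diag(1.0 / safe)
        try:
            new_coeffs = np.linalg.solve(lhs, target)
        except np.linalg.LinAlgError:
            warnings.warn("singular M-step system; adding ridge jitter")
            jitter = 1e-8 * np.trace(lhs) / m
            new_coeffs = np.linalg.solve(lhs + jitter * np.eye(m), target)

        update = float(np.mean(np.linalg.norm(g @ (new_coeffs - coeffs), axis=1)))
        coeffs = new_coeffs
        ta = a + g @ coeffs
        d2 = pairwise_sq_dists(ta, b)
        npost = post.sum()
        if npost > 0:
            sigma2_est = float((post * d2).sum() / (3.0 * npost))
            sigma2 = max(sigma2_est, sigma2_floor)
        if update < tol:
            break

    return Transform(anchors=a, coefficients=coeffs, beta=params.beta)
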