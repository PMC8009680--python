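"""Tracking difficulty and performance metrics; fluorescence extraction.

Relative movement (RM) of a cell at time t is its displacement from t-1
divided by the distance to its nearest neighbouring cell at t; movements
with RM >= 0.5 defeat naive nearest-cell assignment, and RM >= 1.0 even
more so, which makes the per-cell counts of such movements a useful
difficulty summary for a dataset.  Accuracy against ground truth uses an
automated criterion (tracked position inside the true labeled region, or
within half the local nearest-neighbour distance of the true position).
Activity traces are mean raw intensities over the tracked region per
channel, optionally as a ratio (e.g. GCaMP over tdTomato, or FRET
acceptor over donor) — preprocessing never touches these values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import Movie, pairwise_sq_dists, um_to_voxel
from .tracker import TrackResult, compute_rm


def _positions_by_time(tracks: pd.DataFrame):
    """(times, ids, positions[t, cell, 3]) from a long-format track table."""
    ids = np.sort(tracks["cell_id"].unique())
    times = np.sort(tracks["t"].unique())
    piv = tracks.sort_values(["t", "cell_id"])
    pos = piv[["z_um", "y_um", "x_um"]].to_numpy().reshape(len(times), len(ids), 3)
    return times, ids, pos


def rm_record(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per (cell, t >= first+1) relative movement computed from the table."""
    times, ids, pos = _positions_by_time(tracks)
    rows = []
    for k in range(1, len(times)):
        rm = compute_rm(pos[k - 1], pos[k])
        rows.extend(
            (int(c), int(times[k]), float(v)) for c, v in zip(ids, rm)
        )
    return pd.DataFrame(rows, columns=["cell_id", "t", "rm"])


def rm_stats(tracks_or_rm: pd.DataFrame) -> dict:
    """Counts of challenging movements (RM >= 0.5 and >= 1.0).

    Accepts either a track table or a precomputed RM record; per-cell
    values are totals divided by the number of cells.
    """
    df = tracks_or_rm
    if "rm" not in df.columns:
        if len(df["t"].unique()) < 2:
            raise ValueError("need at least 2 time points for RM statistics")
        df = rm_record(df)
    n_cells = df["cell_id"].nunique()
    ge05 = int((df["rm"] >= 0.5).sum())
    ge10 = int((df["rm"] >= 1.0).sum())
    return {
        "n_cells": int(n_cells),
        "total_rm_ge_0.5": ge05,
        "total_rm_ge_1.0": ge10,
        "per_cell_rm_ge_0.5": ge05 / n_cells,
        "per_cell_rm_ge_1.0": ge10 / n_cells,
    }


def accuracy_vs_truth(
    tracks: pd.DataFrame,
    truth: pd.DataFrame,
    truth_labels: np.ndarray | None = None,
    spacing=None,
) -> pd.DataFrame:
    """Fraction of cells tracked correctly at each time point.

    A cell is correct at t if its tracked position falls inside its true
    labeled region (when ``truth_labels`` and ``spacing`` are given) or
    within half the true nearest-neighbour distance of its true position.
    Returns a DataFrame with columns ``t`` and ``accuracy``.
    """
    ids_a = set(tracks["cell_id"].unique())
    ids_b = set(truth["cell_id"].unique())
    if ids_a != ids_b:
        raise ValueError("tracked and truth tables cover different cell ids")
    times, ids, pos = _positions_by_time(tracks)
    times_t, ids_t, pos_t = _positions_by_time(truth)
    common = np.intersect1d(times, times_t)
    rows = []
    for k, t in enumerate(common):
        p = pos[np.searchsorted(times, t)]
        q = pos_t[np.searchsorted(times_t, t)]
        d2 = pairwise_sq_dists(q, q)
        np.fill_diagonal(d2, np.inf)
        half_nn = 0.5 * np.sqrt(d2.min(axis=1))
        err = np.linalg.norm(p - q, axis=1)
        correct = err < half_nn
        if truth_labels is not None and spacing is not None:
            vox = np.round(um_to_voxel(p, spacing)).astype(int)
            shape = np.asarray(truth_labels.shape[1:])
            inside = np.all((vox >= 0) & (vox < shape), axis=1)
            region_id = np.zeros(len(p), dtype=int)
            iv = vox[inside]
            region_id[inside] = truth_labels[int(t)][iv[:, 0], iv[:, 1], iv[:, 2]]
            correct |= region_id == ids
        rows.append((int(t), float(np.mean(correct))))
    return pd.DataFrame(rows, columns=["t", "accuracy"])


def extract_activity(
    result: TrackResult | np.ndarray,
    movie: Movie,
    numerator_channel: int,
    denominator_channel: int | None = None,
) -> pd.DataFrame:
    """Mean raw intensities per tracked region and time, plus their ratio.

    ``result`` is a :class:`TrackResult` or a (t, z, y, x) label array.
    Intensities are always measured on the raw movie. Cells whose region is
    empty at some time get missing values and ``missing=True``.
    """
    labels = result.labels if isinstance(result, TrackResult) else np.asarray(result)
    if numerator_channel >= movie.n_channels or (
        denominator_channel is not None
        and denominator_channel >= movie.n_channels
    ):
        raise ValueError("requested channel not present in the movie")
    ids = np.unique(labels[0])
    ids = ids[ids > 0]
    rows = []
    for t in range(min(len(labels), movie.n_volumes)):
        lab = labels[t]
        present = np.isin(ids, lab)
        num = np.full(len(ids), np.nan)
        num[present] = ndi.mean(
            movie.data[t, numerator_channel], labels=lab, index=ids[present]
        )
        if denominator_channel is not None:
            den = np.full(len(ids), np.nan)
            den[present] = ndi.mean(
                movie.data[t, denominator_channel], labels=lab, index=ids[present]
            )
        else:
            den = np.full(len(ids), np.nan)
        for i, cid in enumerate(ids):
            ratio = np.nan
            if denominator_channel is not None and np.isfinite(den[i]) and den[i] > 0:
                ratio = num[i] / den[i]
            rows.append(
                (int(cid), t, num[i], den[i], ratio, not bool(present[i]))
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "t", "ch1_mean", "ch2_mean", "ratio", "missing"]
    )


# ---------------------------------------------------------------------------
# dataset-specific extras (beating-organ analyses)


def region_size_proxy(tracks: pd.DataFrame, cell_ids) -> pd.DataFrame:
    """Size proxy sd(x)·sd(y)·sd(z) over a group of tracked cells per time,
    normalized by its own standard deviation."""
    sub = tracks[tracks["cell_id"].isin(list(cell_ids))]
    g = sub.groupby("t")
    size = (
        g["x_um"].std() * g["y_um"].std() * g["z_um"].std()
    ).rename("size")
    norm = size / size.std() if size.std() > 0 else size
    return pd.DataFrame({"t": size.index, "size": norm.values})


def phase_lag(a: np.ndarray, b: np.ndarray) -> int:
    """Delay (samples) of ``b`` relative to ``a`` with maximal
    cross-correlation; positive when ``b`` trails ``a``."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    xc = np.correlate(a, b, mode="full")
    return int((len(b) - 1) - np.argmax(xc))
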