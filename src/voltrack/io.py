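"""Reading and writing the on-disk formats.

Movies are series of multi-page TIFFs, one z-stack per time point and
channel (``<name>_t{####}_c{#}.tif``), or one single-page TIFF per
(time, z, channel) (``<name>_t{####}_z{###}_c{#}.tif``).  Label volumes
are 16-bit TIFFs (one page per z plane).  Tables (tracks, RM, activity)
are plain CSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Movie, TRACK_COLUMNS

_STACK_RE = re.compile(r"_t(\d+)_c(\d+)\.tiff?$")
_PLANE_RE = re.compile(r"_t(\d+)_z(\d+)_c(\d+)\.tiff?$")


def write_movie(movie: Movie, out_dir, name: str = "movie") -> list[Path]:
    """One multi-page TIFF per time point and channel."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(movie.n_volumes):
        for c in range(movie.n_channels):
            p = out_dir / f"{name}_t{t + 1:04d}_c{c + 1}.tif"
            tifffile.imwrite(p, movie.data[t, c], photometric="minisblack")
            paths.append(p)
    return paths


def read_movie(pattern, spacing=(1.0, 1.0, 1.0)) -> Movie:
    """Assemble a movie from TIFF files matching a glob pattern.

    Both per-time z-stack files and per-(time, z) single-page files are
    recognized from the file names; time, z and channel indices in names
    are 1-based.  Missing planes or inconsistent 2D shapes raise an error
    naming the offending file; dtype is preserved.
    """
    pattern = Path(pattern)
    files = sorted(pattern.parent.glob(pattern.name))
    if not files:
        raise FileNotFoundError(f"no files match {pattern}")
    stacks: dict[tuple[int, int], Path] = {}
    planes: dict[tuple[int, int, int], Path] = {}
    for f in files:
        m = _PLANE_RE.search(f.name)
        if m:
            planes[(int(m.group(1)), int(m.group(2)), int(m.group(3)))] = f
            continue
        m = _STACK_RE.search(f.name)
        if m:
            stacks[(int(m.group(1)), int(m.group(2)))] = f
            continue
        raise ValueError(f"unrecognized movie file name: {f.name}")
    if stacks and planes:
        raise ValueError("mixed stack and single-plane naming in one movie")

    if stacks:
        ts = sorted({t for t, _ in stacks})
        cs = sorted({c for _, c in stacks})
        vols = []
        for t in ts:
            chans = []
            for c in cs:
                key = (t, c)
                if key not in stacks:
                    raise ValueError(f"missing file for t{t:04d} c{c}")
                arr = tifffile.imread(stacks[key])
                if arr.ndim == 2:
                    arr = arr[None]
                chans.append(arr)
            vols.append(np.stack(chans))
        data = np.stack(vols)
    else:
        ts = sorted({t for t, _, _ in planes})
        zs = sorted({z for _, z, _ in planes})
        cs = sorted({c for _, _, c in planes})
        vols = []
        for t in ts:
            chans = []
            for c in cs:
                pages = []
                for z in zs:
                    key = (t, z, c)
                    if key not in planes:
                        raise ValueError(
                            f"missing plane for t{t:04d} z{z} c{c}"
                        )
                    pages.append(tifffile.imread(planes[key]))
                chans.append(np.stack(pages))
            vols.append(np.stack(chans))
        data = np.stack(vols)

    shapes = {data[t, c].shape for t in range(data.shape[0]) for c in range(data.shape[1])}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent volume shapes: {shapes}")
    return Movie(data, spacing)


def write_labels(labels: np.ndarray, path) -> Path:
    """Write an integer label volume as a 16-bit TIFF (one page per z)."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more labels than a 16-bit TIFF can hold")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    return path


def read_labels(path) -> np.ndarray:
    labels = np.asarray(tifffile.imread(str(path)))
    if labels.ndim == 2:
        labels = labels[None]
    return labels.astype(np.int32)


def write_tracks(tracks: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks.to_csv(path, index=False)
    return path


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns) - {"status"}
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def save_scene(scene, out_dir, name: str = "scene") -> dict:
    """Write a synthetic scene: movie TIFFs, truth label TIFFs, truth CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    movie_paths = write_movie(scene.movie, out_dir, name=name)
    label_paths = []
    for t in range(len(scene.truth_labels)):
        label_paths.append(
            write_labels(
                scene.truth_labels[t], out_dir / f"{name}_labels_t{t + 1:04d}.tif"
            )
        )
    tracks_path = write_tracks(scene.truth_tracks, out_dir / f"{name}_truth_tracks.csv")
    activity_path = write_table(
        scene.truth_activity, out_dir / f"{name}_truth_activity.csv"
    )
    return {
        "movie": movie_paths,
        "labels": label_paths,
        "tracks": tracks_path,
        "activity": activity_path,
    }
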