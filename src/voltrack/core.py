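"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* Volumes are numpy arrays in ``(z, y, x)`` axis order with a physical voxel
  spacing in micrometres per axis, also ``(z, y, x)``.  Anisotropic spacing
  (coarse z, fine x-y) is the norm for confocal stacks and is carried through
  every distance computation.
* Point sets are ``(n, 3)`` float arrays of cell-centre coordinates in
  micrometres, ``(z, y, x)`` order, 0-based voxel indexing scaled by spacing.
* Label volumes are integer arrays; 0 is background, positive integers are
  cell instances.
* Track tables are pandas DataFrames with columns
  ``cell_id, t, z_um, y_um, x_um, status`` (t is a 0-based volume index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Movie",
    "TRACK_COLUMNS",
    "STATUS_TRACKED",
    "STATUS_CARRIED",
    "STATUS_EXITED",
    "empty_track_table",
    "voxel_to_um",
    "um_to_voxel",
    "pairwise_sq_dists",
]

TRACK_COLUMNS = ["cell_id", "t", "z_um", "y_um", "x_um", "status"]
STATUS_TRACKED = "tracked"
STATUS_CARRIED = "carried_forward"
STATUS_EXITED = "exited"


@dataclass
class Movie:
    """A time- and channel-indexed sequence of 3D volumes.

    data : float or integer array, shape ``(t, channel, z, y, x)``.
    spacing : physical voxel size in µm, ``(z, y, x)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"movie data must be 5-D (t, c, z, y, x); got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[2:])

    def volume(self, t: int, channel: int = 0) -> np.ndarray:
        return self.data[t, channel]


def empty_track_table() -> pd.DataFrame:
    return pd.DataFrame(columns=TRACK_COLUMNS)


def voxel_to_um(idx: np.ndarray, spacing) -> np.ndarray:
    """Scale (z, y, x) voxel indices to physical µm coordinates."""
    return np.asarray(idx, dtype=float) * np.asarray(spacing, dtype=float)


def um_to_voxel(coords: np.ndarray, spacing) -> np.ndarray:
    return np.asarray(coords, dtype=float) / np.asarray(spacing, dtype=float)


def pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between two (n, 3) point sets, (|a|, |b|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)
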