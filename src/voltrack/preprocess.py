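"""Local contrast normalization of the nuclear-marker channel.

Cells in one volume can differ in brightness by an order of magnitude;
equalizing them before voxel classification makes weak cells detectable.
Each voxel is mean-subtracted and divided by the windowed standard
deviation, floored at the dataset's ``noise_level`` so flat background does
not blow up.  The activity channels are never normalized — signal
extraction always reads raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass
class PreprocessParams:
    """noise_level: intensity counts (dataset dependent, typically 1-500).

    window: sliding-window size in voxels, (z, y, x); the short axis is z
    for the usual anisotropic stacks (the default corresponds to
    27 x 27 voxels in-plane over 3 planes).
    """

    noise_level: float = 20.0
    window: tuple[int, int, int] = (3, 27, 27)

    def validate(self) -> None:
        if self.noise_level <= 0:
            raise ValueError("noise_level must be positive")
        if any(w < 1 or w % 2 == 0 for w in self.window):
            raise ValueError("window dimensions must be odd and >= 1")


def local_contrast_normalize(vol: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """(I - mean_w) / max(sd_w, noise_level) over a sliding window.

    Borders are handled by reflection.  Output is invariant to adding a
    global constant to the input, and in bright regions (sd_w above the
    floor) to positive rescaling.
    """
    params.validate()
    x = np.asarray(vol, dtype=np.float64)
    mean = uniform_filter(x, size=params.window, mode="reflect")
    sq = uniform_filter(x * x, size=params.window, mode="reflect")
    var = np.clip(sq - mean * mean, 0.0, None)
    sd = np.sqrt(var)
    return ((x - mean) / np.maximum(sd, params.noise_level)).astype(np.float32)
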