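"""Copy-number preprocessing: smoothing, ploidy scaling, group assignment.

Raw per-marker copy estimates from SNP arrays are noisy, so profiles are
smoothed with a local median over a window of consecutive markers (default
10), never crossing a chromosome boundary.  Tumour samples of unknown ploidy
can additionally be rescaled sample-wise so that the modal copy level sits
at two copies ("scale copy number mode to 2"), preventing hyperdiploid
genomes from being read as genome-wide deletion.  Finally, at any single
marker the samples are split into three groups by fixed, inclusive
thresholds: Deletion (<= 1.5 copies), Gain (>= 2.5 copies) and "No change"
in between; missing values are unassignable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import GenomeMatrix

logger = logging.getLogger(__name__)

GROUP_DELETION = 0
GROUP_NO_CHANGE = 1
GROUP_GAIN = 2
GROUP_UNASSIGNED = -1

#: display labels indexed by group code
GROUP_LABELS = ("Deletion", "No change", "Gain")


@dataclass(frozen=True)
class SmoothingConfig:
    """Preprocessing parameters.

    window
        number of consecutive markers in the local median (1 = no smoothing).
    del_thresh / gain_thresh
        inclusive copy-number thresholds for the Deletion and Gain groups.
    scale_mode_to_two
        rescale each sample so its modal copy level equals 2 before smoothing.
    """

    window: int = 10
    del_thresh: float = 1.5
    gain_thresh: float = 2.5
    scale_mode_to_two: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("smoothing window must be >= 1")
        if not self.del_thresh < self.gain_thresh:
            raise ValueError("del_thresh must be strictly below gain_thresh")


def _smooth_block(block: np.ndarray, window: int) -> np.ndarray:
    """Centered running median down one chromosome block (markers x samples).

    Window covers floor((w-1)/2) markers to the left and the rest to the
    right, truncated at the block ends; missing values are excluded from
    each median, an all-missing window stays missing.
    """
    if window == 1:
        return block.copy()
    left = (window - 1) // 2
    right = window - 1 - left
    padded = np.pad(block, ((left, right), (0, 0)), constant_values=np.nan)
    wins = sliding_window_view(padded, window, axis=0)  # (L, S, window)
    if np.isnan(block).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            out = np.nanmedian(wins, axis=-1)
    else:
        # interior windows are complete; only the first `left` and last
        # `right` rows contain padding NaNs
        out = np.empty_like(block)
        lo, hi = left, block.shape[0] - right
        if hi > lo:
            out[lo:hi] = np.median(wins[lo:hi], axis=-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if lo > 0:
                out[:lo] = np.nanmedian(wins[:lo], axis=-1)
            if right > 0:
                out[hi:] = np.nanmedian(wins[hi:], axis=-1)
    return out


def smooth_profile(matrix: GenomeMatrix, config: SmoothingConfig) -> GenomeMatrix:
    """Local-median smoothing of every sample, one chromosome at a time."""
    out = np.empty_like(matrix.values)
    for _, start, stop in matrix.annotation.chromosome_blocks():
        out[start:stop] = _smooth_block(matrix.values[start:stop], config.window)
    return matrix.with_values(out)


# histogram for the modal copy level: 0.1-copy bins positioned so that
# multiples of 0.1 are bin midpoints (a profile sitting exactly at 3.0
# copies yields mode 3.0, not 3.05)
_MODE_BIN_EDGES = np.arange(-0.05, 8.06, 0.1)


def estimate_mode(profile: np.ndarray) -> float:
    """Modal copy level of one sample: midpoint of the fullest 0.1-copy bin."""
    vals = np.asarray(profile, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 20:
        raise ValueError("need at least 20 non-missing values to estimate the mode")
    counts, edges = np.histogram(vals, bins=_MODE_BIN_EDGES)
    idx = int(np.argmax(counts))  # ties -> lowest bin
    mode = (edges[idx] + edges[idx + 1]) / 2.0
    if mode <= 0.2:
        raise ValueError(f"degenerate profile: modal copy level {mode:.2f} <= 0.2")
    return float(mode)


def scale_mode_to_two(profile: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale one sample's profile so its modal copy level becomes 2.

    Returns the scaled profile and the estimated mode.
    """
    mode = estimate_mode(profile)
    return np.asarray(profile, dtype=float) * (2.0 / mode), mode


def scale_matrix_mode_to_two(matrix: GenomeMatrix) -> tuple[GenomeMatrix, np.ndarray]:
    """Apply mode-to-2 scaling to every sample column; returns modes."""
    out = np.empty_like(matrix.values)
    modes = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        out[:, j], modes[j] = scale_mode_to_two(matrix.values[:, j])
    logger.info("mode-to-2 scaling: modes in [%.2f, %.2f]", modes.min(), modes.max())
    return matrix.with_values(out), modes


def assign_cn_groups(values: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    """Per-sample group codes at one marker (or a markers x samples block).

    Deletion if value <= del_thresh, Gain if value >= gain_thresh (both
    inclusive), No change strictly between, Unassigned where missing.
    """
    v = np.asarray(values, dtype=float)
    codes = np.full(v.shape, GROUP_NO_CHANGE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[v <= config.del_thresh] = GROUP_DELETION
        codes[v >= config.gain_thresh] = GROUP_GAIN
    codes[np.isnan(v)] = GROUP_UNASSIGNED
    return codes


def preprocess_matrix(matrix: GenomeMatrix, config: SmoothingConfig) -> GenomeMatrix:
    """Full preprocessing pipeline: optional mode-to-2 scaling, then smoothing.

    Scaling acts on the raw profile (its histogram), smoothing afterwards.
    """
    if config.scale_mode_to_two:
        matrix, _ = scale_matrix_mode_to_two(matrix)
    return smooth_profile(matrix, config)
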