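"""Genome-wide significance by MaxT permutation.

Two schemes simulate the global null hypothesis that no chromosome region's
copy number is associated with survival:

* ``blocks`` -- for each sample independently, the genome-ordered profile is
  cut into K (>= 2) random contiguous blocks whose order is then shuffled;
  within-block marker order is preserved, so the local correlation of
  neighbouring copy numbers survives while genome position is decoupled
  from the phenotype;
* ``clinical`` -- the (time, event) pairs are permuted jointly across
  samples, leaving the copy-number data untouched.

For each permuted dataset the identical scan is rerun and the maximum score
over tested markers recorded.  The ceil(alpha * n_perm)-th largest of these
maxima is the genome-wide threshold at level alpha (with 100 permutations
and alpha = 0.05, the 5th largest); the add-one empirical genome-wide
p-value is (1 + #{perm max >= observed max}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_scan import ScanConfig, ScanResult, _scan_scores, tested_indices
from .io_formats import GenomeMatrix
from .survival_stats import SurvivalData

logger = logging.getLogger(__name__)

SCHEMES = ("blocks", "clinical")


@dataclass(frozen=True)
class PermutationConfig:
    """MaxT permutation parameters.

    scheme
        ``"blocks"`` (chromosome-block shuffling per sample) or
        ``"clinical"`` (joint permutation of time/event pairs).
    n_perm
        number of permuted datasets; must be at least ceil(1/alpha) for the
        threshold order statistic to exist.
    K
        number of genome blocks (blocks scheme), at least 2.
    """

    scheme: str = "clinical"
    n_perm: int = 100
    K: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < math.ceil(1.0 / self.alpha):
            raise ValueError(
                f"n_perm = {self.n_perm} too small for alpha = {self.alpha}: "
                f"need at least {math.ceil(1.0 / self.alpha)}"
            )


@dataclass
class PermutationNull:
    """Null distribution of per-permutation maximal scores."""

    maxima: np.ndarray
    threshold: float
    alpha: float
    observed_max: float
    p_value: float
    scheme: str
    n_perm: int
    seed: int
    n_degenerate: int = 0

    def threshold_at(self, alpha: float) -> float:
        """Genome-wide threshold at another significance level."""
        return _order_statistic_threshold(self.maxima, alpha)

    def summary(self) -> str:
        return (
            f"MaxT permutation null ({self.scheme}, {self.n_perm} permutations, "
            f"seed {self.seed})\n"
            f"  genome-wide threshold at alpha={self.alpha:g}: {self.threshold:.4f}\n"
            f"  observed maximum: {self.observed_max:.4f} "
            f"(empirical genome-wide p = {self.p_value:.4g})"
        )


# ---------------------------------------------------------------------------
# permutation primitives
# ---------------------------------------------------------------------------


def block_permute_profile(
    profile: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle K random contiguous blocks of one genome-ordered profile.

    K - 1 distinct breakpoints are drawn uniformly from the L - 1 internal
    boundaries; the resulting blocks are rearranged by a uniform random
    permutation with within-block order intact.
    """
    profile = np.asarray(profile)
    L = len(profile)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > L:
        raise ValueError(f"K = {K} exceeds profile length {L}")
    cuts = np.sort(rng.choice(L - 1, size=K - 1, replace=False) + 1)
    bounds = np.concatenate(([0], cuts, [L]))
    order = rng.permutation(K)
    return np.concatenate([profile[bounds[b] : bounds[b + 1]] for b in order])


def block_permute_matrix(
    values: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Block-permute every sample column independently (fresh cuts each)."""
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = block_permute_profile(values[:, j], K, rng)
    return out


def permute_clinical(data: SurvivalData, rng: np.random.Generator) -> SurvivalData:
    """Permute the (time, event) pairs jointly across all samples."""
    perm = rng.permutation(len(data))
    return SurvivalData(data.time[perm], data.event[perm], data.ids)


# ---------------------------------------------------------------------------
# MaxT
# ---------------------------------------------------------------------------


def _order_statistic_threshold(maxima: np.ndarray, alpha: float) -> float:
    """ceil(alpha * n)-th largest of the permutation maxima (NaN = -inf)."""
    filled = np.where(np.isnan(maxima), -np.inf, maxima)
    m = math.ceil(alpha * len(filled))
    return float(np.sort(filled)[::-1][m - 1])


def maxt_threshold(
    observed: ScanResult,
    matrix: GenomeMatrix,
    data: SurvivalData,
    scan_cfg: ScanConfig,
    perm_cfg: PermutationConfig,
) -> PermutationNull:
    """MaxT null distribution, threshold and empirical genome-wide p.

    ``matrix`` must be the same preprocessed matrix the observed scan ran
    on; each permutation reruns the identical scan (same strided markers,
    same score definitions) and keeps the maximal score (|z| for Cox,
    -log10 p for log-rank; missing scores are skipped).
    """
    idx = tested_indices(matrix, scan_cfg.stride)
    if not np.array_equal(idx, observed.tested_idx):
        raise ValueError("observed scan was produced with a different configuration")
    strided = matrix.values[idx]
    take_abs = scan_cfg.method == "cox"

    children = np.random.SeedSequence(perm_cfg.seed).spawn(perm_cfg.n_perm)
    maxima = np.full(perm_cfg.n_perm, np.nan)
    for b in range(perm_cfg.n_perm):
        rng = np.random.default_rng(children[b])
        if perm_cfg.scheme == "clinical":
            vals_b = strided
            data_b = permute_clinical(data, rng)
        else:
            full_b = block_permute_matrix(matrix.values, perm_cfg.K, rng)
            vals_b = full_b[idx]
            data_b = data
        res_b = _scan_scores(vals_b, data_b, scan_cfg)
        # same gate as the observed scan's threshold_scores: only markers
        # whose score is considered computable enter the maximum
        scores = np.where(res_b["eligible"], res_b["score"], np.nan)
        if take_abs:
            scores = np.abs(scores)
        if np.isfinite(scores).any():
            maxima[b] = np.nanmax(scores)
    n_degenerate = int(np.isnan(maxima).sum())
    if n_degenerate == perm_cfg.n_perm:
        raise ValueError("all permutation scans were degenerate (no testable marker)")
    if n_degenerate:
        logger.warning("%d of %d permutation scans degenerate", n_degenerate, perm_cfg.n_perm)

    threshold = _order_statistic_threshold(maxima, perm_cfg.alpha)
    obs_max = observed.observed_max
    filled = np.where(np.isnan(maxima), -np.inf, maxima)
    if np.isnan(obs_max):
        p = 1.0  # no computable observed score: no evidence against the null
    else:
        p = (1.0 + int((filled >= obs_max).sum())) / (perm_cfg.n_perm + 1.0)
    return PermutationNull(
        maxima=maxima,
        threshold=threshold,
        alpha=perm_cfg.alpha,
        observed_max=obs_max,
        p_value=p,
        scheme=perm_cfg.scheme,
        n_perm=perm_cfg.n_perm,
        seed=perm_cfg.seed,
        n_degenerate=n_degenerate,
    )


def significant_regions(
    observed: ScanResult, null: PermutationNull | float
) -> pd.DataFrame:
    """Maximal runs of consecutive tested markers at or above the threshold.

    Runs never cross a chromosome boundary; each is reported as a 1-based
    inclusive genomic interval with its peak marker and peak score.
    Missing scores break runs.
    """
    threshold = null.threshold if isinstance(null, PermutationNull) else float(null)
    tab = observed.table
    s = observed.threshold_scores
    above = np.isfinite(s) & (s >= threshold)
    rows: list[dict] = []
    i = 0
    n = len(tab)
    chroms = tab["chromosome"].to_numpy()
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        run = slice(i, j + 1)
        peak = i + int(np.nanargmax(s[run]))
        rows.append(
            {
                "chromosome": chroms[i],
                "start": int(tab["position"].iloc[i]),
                "end": int(tab["position"].iloc[j]),
                "n_markers": j - i + 1,
                "peak_marker": tab["marker_id"].iloc[peak],
                "peak_score": float(s[peak]),
                "first_marker": tab["marker_id"].iloc[i],
                "last_marker": tab["marker_id"].iloc[j],
            }
        )
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start",
            "end",
            "n_markers",
            "peak_marker",
            "peak_score",
            "first_marker",
            "last_marker",
        ],
    )
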