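"""Hierarchical sample clustering on expression data and K-M comparisons.

The workflow mirrors the interactive one: filter genes by a variation
criterion (sd/mean within configurable bounds on the linear signal scale),
cluster samples hierarchically on the filtered, row-standardized matrix
with correlation distance, select branches of the dendrogram (by node id
or a height cut -- the non-interactive stand-in for clicking branches),
and compare the selected clusters' survival with a Kaplan-Meier plot and
log-rank test, reporting how many samples were omitted for missing
survival data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import GenomeMatrix
from .survival_stats import KMCurveSet, LogrankResult, SurvivalData, km_estimate, logrank_test

logger = logging.getLogger(__name__)

LINKAGES = ("average", "complete", "centroid")


def variation_filter(
    expr: GenomeMatrix | np.ndarray,
    lower: float = 0.5,
    upper: float = 1000.0,
) -> np.ndarray:
    """Row indices whose coefficient of variation (sd/mean) lies in bounds.

    Expression must be on the linear, nonnegative scale.  Constant rows
    have sd/mean = 0 and are removed whenever ``lower`` > 0.
    """
    values = expr.values if isinstance(expr, GenomeMatrix) else np.asarray(expr, float)
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = np.flatnonzero((cv >= lower) & (cv <= upper))
    logger.info("variation filter kept %d of %d rows", len(keep), len(values))
    if len(keep) == 0:
        raise ValueError(
            "no rows pass the variation filter; relax the sd/mean bounds "
            f"(current: [{lower}, {upper}])"
        )
    return keep


@dataclass
class Dendrogram:
    """Binary merge tree over samples (scipy linkage encoding).

    Leaves are numbered 0..n-1 in sample order; internal nodes n..2n-2 in
    merge order, the root being the last merge.
    """

    linkage: np.ndarray
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def root(self) -> int:
        return 2 * self.n_samples - 2

    def members(self, node: int) -> list[int]:
        """Leaf indices under a node id."""
        n = self.n_samples
        if node < 0 or node > self.root:
            raise ValueError(f"node id {node} out of range 0..{self.root}")
        if node < n:
            return [node]
        left, right = int(self.linkage[node - n, 0]), int(self.linkage[node - n, 1])
        return self.members(left) + self.members(right)

    def height(self, node: int) -> float:
        n = self.n_samples
        return 0.0 if node < n else float(self.linkage[node - n, 2])

    def select(self, nodes: Sequence[int]) -> np.ndarray:
        """Per-sample labels from selected nodes; others None.

        Labels are ``"C<node>"``.  Overlapping selections are an error.
        """
        labels = np.full(self.n_samples, None, dtype=object)
        seen: set[int] = set()
        for node in nodes:
            mem = self.members(int(node))
            if seen & set(mem):
                raise ValueError(f"selected cluster nodes overlap at node {node}")
            seen.update(mem)
            for i in mem:
                labels[i] = f"C{int(node)}"
        return labels

    def cut(self, height: float) -> np.ndarray:
        """Flat cluster labels ("C1", "C2", ...) from a height cut."""
        flat = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return np.array([f"C{c}" for c in flat], dtype=object)

    def to_newick(self) -> str:
        """Newick export with sample ids as leaf labels, heights as lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.sample_ids[node.id]}:{length:g}"
            inner = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
            return f"{inner}:{max(length, 0.0):g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def cluster_samples(
    expr: GenomeMatrix | np.ndarray,
    sample_ids: Sequence[str] | None = None,
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples with 1 - Pearson distance.

    Gene rows are standardized (mean 0, sd 1) first, then samples are
    clustered on correlation distance with the chosen linkage.  scipy's
    deterministic tie handling (lowest cluster index first) applies.
    """
    if isinstance(expr, GenomeMatrix):
        values = expr.values
        sample_ids = sample_ids or list(expr.sample_ids)
    else:
        values = np.asarray(expr, dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2 or n_genes < 2:
        raise ValueError("clustering needs at least 2 samples and 2 genes")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]

    col_sd = values.std(axis=0)
    if (col_sd == 0).any():
        bad = sample_ids[int(np.flatnonzero(col_sd == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero expression variance; correlation undefined")
    row_sd = values.std(axis=1)
    usable = row_sd > 0
    if not usable.any():
        raise ValueError("all gene rows are constant; nothing to cluster on")
    standardized = (values[usable] - values[usable].mean(axis=1, keepdims=True)) / row_sd[
        usable, None
    ]
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if linkage == "centroid":
        # centroid linkage requires euclidean geometry; use the standardized
        # sample vectors, whose squared distances are affine in correlation
        Z = hierarchy.linkage(standardized.T, method="centroid", metric="euclidean")
    else:
        dist = pdist(standardized.T, metric="correlation")
        Z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(linkage=Z, sample_ids=list(sample_ids))


def compare_clusters_survival(
    labels: Sequence,
    data: SurvivalData,
    min_expected: float = 5.0,
) -> tuple[KMCurveSet, LogrankResult]:
    """K-M curves and log-rank test for the labelled sample clusters.

    ``labels`` is a per-sample vector (None/NaN = not selected), e.g. from
    :meth:`Dendrogram.select` or :meth:`Dendrogram.cut` -- or any labels at
    all: selection is pure label plumbing.
    """
    mask = data.complete_mask
    arr = np.asarray(labels, dtype=object)
    if arr.shape != mask.shape:
        raise ValueError("labels must align with the survival data")
    present = {}
    for lab, ok in zip(arr, mask):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)):
            continue
        present.setdefault(lab, 0)
        present[lab] += int(ok)
    usable = [lab for lab, n in present.items() if n > 0]
    empty = [str(lab) for lab, n in present.items() if n == 0]
    if empty:
        raise ValueError(
            f"cluster(s) {', '.join(empty)} have no sample with survival data"
        )
    if len(usable) < 2:
        raise ValueError("need at least two clusters with usable survival data")
    curves = km_estimate(data, arr)
    result = logrank_test(data, arr, min_expected=min_expected)
    return curves, result
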