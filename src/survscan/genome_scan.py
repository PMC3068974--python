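"""Marker-by-marker survival-association scans across the genome.

The scan applies either the three-group log-rank test (groups defined by
each marker's copy number: Deletion / No change / Gain) or univariate Cox
regression on the continuous smoothed copy number, at one of every
``stride`` consecutive markers within each chromosome.  Because the
smoothed copy numbers of nearby markers are correlated, so are their test
statistics, and testing every ``stride``-th marker (default 10) loses
little information while cutting computation.

Scores follow the track convention: the log-rank track carries
-log10(p-value) (3 corresponds to p = 0.001), the Cox track carries the
signed z score (plotted as |z| with the sign encoded by color).  Markers
where no comparison is possible -- a single nonempty group, a degenerate
covariate, a non-converged fit -- carry a missing score, never zero.

``GenomeSurvivalScan`` is the model object: build it from a matrix plus the
survival response (preprocessing -- optional mode-to-2 scaling and median
smoothing -- happens once, up front), call :meth:`GenomeSurvivalScan.fit`
to obtain a :class:`ScanResult`, and hang permutation thresholds and plots
off the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .copy_number import (
    GROUP_LABELS,
    GROUP_UNASSIGNED,
    SmoothingConfig,
    assign_cn_groups,
    preprocess_matrix,
)
from .io_formats import GenomeMatrix, SampleTable
from .survival_stats import (
    SurvivalData,
    _cox_scores_batch,
    _logrank_scores_batch,
    _prepare_sorted,
    cox_fit,
    logrank_test,
)

if TYPE_CHECKING:  # pragma: no cover
    from .permutation import PermutationConfig, PermutationNull

logger = logging.getLogger(__name__)

METHODS = ("logrank", "cox")


def score_from_p(p: float | np.ndarray) -> float | np.ndarray:
    """Log-rank track score: -log10 of the p-value (p = 0.001 -> 3)."""
    with np.errstate(divide="ignore"):
        return -np.log10(p)


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    stride
        test one of every ``stride`` consecutive markers, restarting at the
        first marker of each chromosome.
    method
        ``"logrank"`` (copy-number groups) or ``"cox"`` (continuous copies).
    smoothing
        preprocessing parameters (window, thresholds, mode scaling).
    covariates
        names of sample-information columns used as adjustment covariates
        in multivariate Cox fits.
    min_expected
        expected-event count at least two groups must reach before a
        log-rank p-value is displayed on plots.
    """

    stride: int = 10
    method: str = "logrank"
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    covariates: tuple[str, ...] = ()
    min_expected: float = 5.0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


def tested_indices(matrix: GenomeMatrix, stride: int) -> np.ndarray:
    """Row indices tested by the scan: offsets 0, stride, ... per chromosome."""
    idx: list[np.ndarray] = []
    for _, start, stop in matrix.annotation.chromosome_blocks():
        idx.append(np.arange(start, stop, stride))
    return np.concatenate(idx) if idx else np.array([], dtype=int)


@dataclass
class ScanResult:
    """Per-tested-marker survival-association scores plus scan metadata.

    ``table`` has one row per tested marker with columns ``marker_id``,
    ``chromosome``, ``position``, ``score``, ``statistic``, ``p_value``,
    ``eligible`` and per-group sample counts (log-rank) or ``converged``
    (Cox).  Missing scores are NaN.
    """

    table: pd.DataFrame
    method: str
    config: ScanConfig
    n_samples: int
    n_omitted: int
    tested_idx: np.ndarray
    model: "GenomeSurvivalScan | None" = None

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    @property
    def threshold_scores(self) -> np.ndarray:
        """Scores on the scale the MaxT maximum is taken over (|z| for Cox).

        Restricted to eligible markers: for the log-rank scan these are the
        markers where the p-value is considered computable (at least two
        groups with ``min_expected`` expected events) -- with tiny groups
        the chi-square approximation is wildly unstable and would dominate
        the permutation maxima; for Cox, the converged fits.  The full
        ungated track remains in ``table``.
        """
        s = self.scores
        eligible = self.table["eligible"].to_numpy(dtype=bool)
        s = np.where(eligible, s, np.nan)
        return np.abs(s) if self.method == "cox" else s

    @property
    def observed_max(self) -> float:
        s = self.threshold_scores
        return float(np.nanmax(s)) if np.isfinite(s).any() else np.nan

    @property
    def n_tested(self) -> int:
        return len(self.table)

    def summary(self) -> str:
        s = self.threshold_scores
        n_ok = int(np.isfinite(s).sum())
        lines = [
            f"Genome-wide survival scan ({self.method})",
            f"  markers tested: {self.n_tested} (stride {self.config.stride}),"
            f" scores computed: {n_ok}",
            f"  samples: {self.n_samples} ({self.n_omitted} omitted, missing survival)",
        ]
        if n_ok:
            peak = self.table.iloc[int(np.nanargmax(s))]
            lines.append(
                f"  peak: {peak['marker_id']} (chr{peak['chromosome']}:"
                f"{int(peak['position'])}), score {peak['score']:.3f},"
                f" p = {peak['p_value']:.3g}"
            )
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA", index=False)

    # -- results-object conveniences -------------------------------------
    def permutation_null(
        self,
        scheme: str = "clinical",
        n_perm: int = 100,
        K: int = 10,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> "PermutationNull":
        """MaxT permutation null for this scan (requires the parent model)."""
        from .permutation import PermutationConfig, maxt_threshold

        if self.model is None:
            raise ValueError("scan result is detached from its model")
        cfg = PermutationConfig(scheme=scheme, n_perm=n_perm, K=K, alpha=alpha, seed=seed)
        return maxt_threshold(self, self.model.smoothed, self.model.survival, self.config, cfg)

    def significant_regions(self, null: "PermutationNull | float") -> pd.DataFrame:
        from .permutation import significant_regions

        return significant_regions(self, null)

    def plot(self, null: "PermutationNull | None" = None, out: str | Path = "scan.png", **kw):
        from .viz import plot_scan

        return plot_scan(self, null=null, out=out, **kw)


# ---------------------------------------------------------------------------
# scan internals (shared verbatim by the permutation reruns)
# ---------------------------------------------------------------------------


def _scan_scores(
    values: np.ndarray, data: SurvivalData, config: ScanConfig
) -> dict[str, np.ndarray]:
    """Scores for the given (already strided) marker rows.

    ``values`` is (M_tested, n_samples) aligned with ``data``.  Complete
    cases are selected here, so permuted survival responses re-enter the
    identical code path as the observed scan.
    """
    mask = data.complete_mask
    vals = values[:, mask]
    sub = SurvivalData(data.time[mask], data.event[mask])
    prep = _prepare_sorted(sub.time, sub.event)
    M = vals.shape[0]
    if config.method == "logrank":
        codes = assign_cn_groups(vals, config.smoothing)
        has_missing = (codes == GROUP_UNASSIGNED).any(axis=1)
        res = _logrank_scores_batch(
            prep, np.where(has_missing[:, None], 0, codes), k=3, min_expected=config.min_expected
        )
        stat, df, p = res["stat"], res["df"], res["p"]
        eligible, group_n = res["eligible"], res["group_n"]
        for m in np.flatnonzero(has_missing):
            stat[m] = df[m] = 0
            p[m] = np.nan
            eligible[m] = False
            keep = codes[m] != GROUP_UNASSIGNED
            labels = np.array(GROUP_LABELS, dtype=object)[codes[m, keep]]
            group_n[m] = [(codes[m] == j).sum() for j in range(3)]
            try:
                lr = logrank_test(sub.subset(keep), labels, config.min_expected)
                stat[m], p[m], eligible[m] = lr.chi_square, lr.p_value, lr.eligible
                df[m] = lr.df
            except ValueError:
                stat[m] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(np.isnan(p), np.nan, score_from_p(np.where(np.isnan(p), 1.0, p)))
        return dict(
            score=score, statistic=stat, p_value=p, eligible=eligible, group_n=group_n, df=df
        )
    else:
        has_missing = np.isnan(vals).any(axis=1)
        res = _cox_scores_batch(prep, np.where(has_missing[:, None], 0.0, vals))
        beta, se, z, conv = res["beta"], res["se"], res["z"], res["converged"]
        for m in np.flatnonzero(has_missing):
            beta[m] = se[m] = z[m] = np.nan
            conv[m] = False
            keep = ~np.isnan(vals[m])
            try:
                fit = cox_fit(sub.subset(keep), vals[m, keep])
                if fit.converged:
                    beta[m], se[m], z[m], conv[m] = fit.beta, fit.se, fit.z, True
            except ValueError:
                pass
        from scipy import stats as _st

        p = 2.0 * _st.norm.sf(np.abs(z))
        return dict(score=z, statistic=beta, p_value=p, eligible=conv, converged=conv, se=se)


def _result_table(
    matrix: GenomeMatrix, idx: np.ndarray, scores: dict[str, np.ndarray]
) -> pd.DataFrame:
    ann = matrix.annotation.table.iloc[idx]
    tab = pd.DataFrame(
        {
            "marker_id": ann["marker_id"].to_numpy(),
            "chromosome": ann["chromosome"].to_numpy(),
            "position": ann["position"].to_numpy(),
            "score": scores["score"],
            "statistic": scores["statistic"],
            "p_value": scores["p_value"],
            "eligible": scores["eligible"],
        }
    )
    if "group_n" in scores:
        for j, lab in enumerate(("n_deletion", "n_nochange", "n_gain")):
            tab[lab] = scores["group_n"][:, j]
        tab["df"] = scores["df"]
    if "se" in scores:
        tab["se"] = scores["se"]
        tab["converged"] = scores["converged"]
    return tab


def _run_scan(matrix: GenomeMatrix, data: SurvivalData, config: ScanConfig) -> ScanResult:
    if len(data) != matrix.n_samples:
        raise ValueError("survival data does not align with matrix samples")
    idx = tested_indices(matrix, config.stride)
    scores = _scan_scores(matrix.values[idx], data, config)
    if not np.isfinite(scores["score"]).any():
        raise ValueError("no testable marker genome-wide")
    return ScanResult(
        table=_result_table(matrix, idx, scores),
        method=config.method,
        config=config,
        n_samples=int(data.complete_mask.sum()),
        n_omitted=data.n_omitted,
        tested_idx=idx,
    )


def scan_logrank(matrix: GenomeMatrix, data: SurvivalData, config: ScanConfig) -> ScanResult:
    """Log-rank scan: copy-number groups at each strided marker.

    ``matrix`` must already be preprocessed (smoothed/scaled) per
    ``config.smoothing``; scores are -log10 p, missing where fewer than two
    nonempty groups exist.
    """
    return _run_scan(matrix, data, replace(config, method="logrank"))


def scan_cox(matrix: GenomeMatrix, data: SurvivalData, config: ScanConfig) -> ScanResult:
    """Cox scan: signed z for the smoothed copy number at each strided marker.

    With adjustment covariates configured, each marker gets a multivariate
    fit and the copy-number term's z is the score (slower path).
    """
    config = replace(config, method="cox")
    if config.covariates:
        raise ValueError(
            "adjusted Cox scans need per-sample covariate values; use "
            "GenomeSurvivalScan with a SampleTable"
        )
    return _run_scan(matrix, data, config)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------


class GenomeSurvivalScan:
    """Genome-wide survival-association scan model.

    Parameters
    ----------
    matrix
        raw copy-number matrix in genome order (linear copy scale).
    samples
        a :class:`~survscan.io_formats.SampleTable` (survival columns per
        its configuration) or a :class:`SurvivalData` aligned with the
        matrix columns.
    config
        scan parameters; preprocessing (mode scaling, smoothing) is applied
        once at construction.
    array_list
        optional ordered sample subset restricting the analysis.
    """

    def __init__(
        self,
        matrix: GenomeMatrix,
        samples: SampleTable | SurvivalData,
        config: ScanConfig | None = None,
        array_list: list[str] | None = None,
    ) -> None:
        self.config = config or ScanConfig()
        self.sample_table: SampleTable | None = None
        if isinstance(samples, SampleTable):
            ids = array_list if array_list is not None else [
                s for s in matrix.sample_ids if s in samples.data.index
            ]
            dropped = [s for s in matrix.sample_ids if s not in samples.data.index]
            if dropped:
                logger.warning(
                    "%d matrix sample(s) missing from sample information; excluded", len(dropped)
                )
            matrix = matrix.subset_samples(ids)
            self.sample_table = samples.subset(ids)
            self.survival = self.sample_table.survival_data()
        else:
            if array_list is not None:
                raise ValueError("array_list requires a SampleTable")
            self.survival = samples
        if len(self.survival) != matrix.n_samples:
            raise ValueError("survival data does not align with matrix samples")
        self.matrix = matrix
        self.smoothed = preprocess_matrix(matrix, self.config.smoothing)

    def fit(self, method: str | None = None) -> ScanResult:
        """Run the scan; returns a :class:`ScanResult` bound to this model."""
        cfg = self.config if method is None else replace(self.config, method=method)
        if cfg.method == "cox" and cfg.covariates:
            result = self._fit_cox_adjusted(cfg)
        else:
            result = _run_scan(self.smoothed, self.survival, cfg)
        result.model = self
        return result

    def _fit_cox_adjusted(self, cfg: ScanConfig) -> ScanResult:
        if self.sample_table is None:
            raise ValueError("adjustment covariates require a SampleTable")
        extra = pd.DataFrame(
            {c: self.sample_table.covariate(c) for c in cfg.covariates}
        )
        idx = tested_indices(self.smoothed, cfg.stride)
        vals = self.smoothed.values[idx]
        M = len(idx)
        beta = np.full(M, np.nan)
        se = np.full(M, np.nan)
        z = np.full(M, np.nan)
        conv = np.zeros(M, dtype=bool)
        for m in range(M):
            try:
                fit = cox_fit(self.survival, vals[m], extra=extra)
            except ValueError:
                continue
            if fit.converged:
                beta[m], se[m], z[m], conv[m] = fit.beta, fit.se, fit.z, True
        if not np.isfinite(z).any():
            raise ValueError("no testable marker genome-wide")
        from scipy import stats as _st

        scores = dict(
            score=z,
            statistic=beta,
            p_value=2.0 * _st.norm.sf(np.abs(z)),
            eligible=conv,
            converged=conv,
            se=se,
        )
        return ScanResult(
            table=_result_table(self.smoothed, idx, scores),
            method="cox",
            config=cfg,
            n_samples=int(self.survival.complete_mask.sum()),
            n_omitted=self.survival.n_omitted,
            tested_idx=idx,
        )

    def km_at_marker(self, marker_id: str):
        """Kaplan-Meier comparison of the CN groups at one marker."""
        from .survival_stats import km_estimate

        i = self.smoothed.annotation.locate(marker_id)
        codes = assign_cn_groups(self.smoothed.values[i], self.config.smoothing)
        labels = [GROUP_LABELS[c] if c != GROUP_UNASSIGNED else None for c in codes]
        curves = km_estimate(self.survival, labels)
        try:
            lr = logrank_test(self.survival, labels, self.config.min_expected)
        except ValueError:
            lr = None
        return curves, lr
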