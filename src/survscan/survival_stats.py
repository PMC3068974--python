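"""Survival statistics: product-limit curves, k-sample log-rank, Cox PH.

All three are implemented from first principles so they can be verified
against independent reference implementations:

* Kaplan-Meier product-limit estimate per group, with at-risk counts and
  observed/expected event counts (the expected counts come from the
  log-rank decomposition over pooled event times, so Obs and Exp sum to
  the same total across groups by construction);
* the k-sample log-rank test with the full hypergeometric covariance
  matrix, chi-square on g-1 degrees of freedom (generalized inverse when
  the covariance is singular);
* Cox proportional-hazards regression maximizing the partial likelihood
  by Newton-Raphson, Breslow tie handling by default (Efron available),
  z = beta / SE from the inverse observed information.

Analyses use complete cases only: samples missing the (time, event) pair,
or any covariate for Cox, are omitted and the omitted count is reported.

The private ``_logrank_scores_batch`` / ``_cox_scores_batch`` helpers
evaluate many markers against one survival response at once; they are the
hot path of the genome scan and its permutation reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "KMCurve",
    "KMCurveSet",
    "LogrankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]


# ---------------------------------------------------------------------------
# survival response container
# ---------------------------------------------------------------------------


@dataclass
class SurvivalData:
    """Right-censored survival response: times and 0/1 event indicators.

    Missing values (NaN) are allowed; a sample is a complete case only when
    both fields are present.
    """

    time: np.ndarray
    event: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be equal-length 1-D arrays")
        ev = self.event[~np.isnan(self.event)]
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1 where present")
        tm = self.time[~np.isnan(self.time)]
        if (tm < 0).any():
            raise ValueError("survival times must be nonnegative")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def complete_mask(self) -> np.ndarray:
        return ~np.isnan(self.time) & ~np.isnan(self.event)

    @property
    def n_omitted(self) -> int:
        """Samples omitted from analyses due to missing survival data."""
        return int((~self.complete_mask).sum())

    def complete_cases(self) -> "SurvivalData":
        m = self.complete_mask
        ids = [s for s, keep in zip(self.ids, m) if keep] if self.ids else None
        return SurvivalData(self.time[m], self.event[m], ids)

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        ids = [s for s, keep in zip(self.ids, mask) if keep] if self.ids else None
        return SurvivalData(self.time[mask], self.event[mask], ids)


class _SortedSurvival(NamedTuple):
    """Complete-case survival response pre-sorted by time (ascending).

    ``first_event_idx`` indexes, within the sorted arrays, the first sample
    at each distinct *event* time; ``d`` counts events and ``n_risk`` the
    at-risk total at those times.
    """

    order: np.ndarray        # permutation into time order
    time: np.ndarray         # sorted times
    event: np.ndarray        # events in sorted order (float 0/1)
    ut: np.ndarray           # distinct event times
    first_event_idx: np.ndarray
    d: np.ndarray            # events per distinct event time
    n_risk: np.ndarray       # at-risk totals at distinct event times
    first_all_idx: np.ndarray  # first index of every distinct time


def _prepare_sorted(time: np.ndarray, event: np.ndarray) -> _SortedSurvival:
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    n = len(t)
    # first occurrence of each distinct time
    first_all = np.flatnonzero(np.concatenate(([True], t[1:] != t[:-1])))
    d_all = np.add.reduceat(e, first_all) if n else np.array([])
    is_ev = d_all > 0
    first_ev = first_all[is_ev]
    return _SortedSurvival(
        order=order,
        time=t,
        event=e,
        ut=t[first_ev],
        first_event_idx=first_ev,
        d=d_all[is_ev],
        n_risk=(n - first_ev).astype(float),
        first_all_idx=first_all,
    )


# ---------------------------------------------------------------------------
# log-rank O/E/V machinery
# ---------------------------------------------------------------------------


def _logrank_oev(
    prep: _SortedSurvival, codes_sorted: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed events, expected events and covariance for k groups.

    ``codes_sorted`` holds group codes 0..k-1 in the sorted-time order.
    At each distinct event time with d events among n at risk, group j is
    expected d * n_j / n events; the covariance is hypergeometric.
    """
    Te = len(prep.ut)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    if Te == 0:
        return O, E, V
    d = prep.d
    n = prep.n_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(n > 1, d * (n - d) / (n - 1), 0.0)
    for j in range(k):
        mask = (codes_sorted == j).astype(float)
        # suffix count = members of j still at risk at each event time
        suffix = np.cumsum(mask[::-1])[::-1]
        n_j = suffix[prep.first_event_idx]
        d_j = np.add.reduceat(mask * prep.event, prep.first_all_idx)
        d_j = d_j[np.isin(prep.first_all_idx, prep.first_event_idx)]
        O[j] = d_j.sum()
        p_j = n_j / n
        E[j] = (d * p_j).sum()
        V[j, j] = (w * p_j * (1 - p_j)).sum()
        for l in range(j):
            mask_l = (codes_sorted == l).astype(float)
            suffix_l = np.cumsum(mask_l[::-1])[::-1]
            p_l = suffix_l[prep.first_event_idx] / n
            V[j, l] = V[l, j] = -(w * p_j * p_l).sum()
    return O, E, V


def _chi_square_from_oev(O: np.ndarray, E: np.ndarray, V: np.ndarray) -> float:
    """Quadratic form (O-E)' V^- (O-E) on the first g-1 groups."""
    u = (O - E)[:-1]
    Vr = V[:-1, :-1]
    if Vr.size == 0:
        return 0.0
    try:
        sol = np.linalg.solve(Vr, u)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Vr) @ u
    stat = float(u @ sol)
    return max(stat, 0.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate for one sample group."""

    label: str
    n: int
    observed: float
    expected: float
    event_times: np.ndarray      # distinct times with >= 1 event in this group
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # at-risk count just before each event time
    censor_times: np.ndarray     # times of censored observations

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class KMCurveSet:
    """Kaplan-Meier curves for the compared groups plus shared bookkeeping."""

    curves: list[KMCurve]
    total_events: float
    n_omitted: int

    def __iter__(self):
        return iter(self.curves)

    def __getitem__(self, label: str) -> KMCurve:
        for c in self.curves:
            if c.label == label:
                return c
        raise KeyError(label)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [c.label for c in self.curves],
                "n": [c.n for c in self.curves],
                "observed": [c.observed for c in self.curves],
                "expected": [c.expected for c in self.curves],
            }
        )


def _group_codes(groups: Sequence, mask: np.ndarray) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Map arbitrary labels to codes over complete cases; None/NaN excluded."""
    arr = np.asarray(groups, dtype=object)
    if arr.shape != mask.shape:
        raise ValueError("groups must align with the survival data")
    labeled = np.array(
        [g is not None and not (isinstance(g, float) and np.isnan(g)) for g in arr]
    )
    use = mask & labeled
    labels_use = arr[use]
    uniq = sorted(set(labels_use), key=str)
    code_of = {lab: i for i, lab in enumerate(uniq)}
    codes = np.array([code_of[g] for g in labels_use], dtype=np.int64)
    return codes, [str(u) for u in uniq], use


def km_estimate(data: SurvivalData, groups: Sequence) -> KMCurveSet:
    """Product-limit estimate per group with observed/expected events.

    ``groups`` is a per-sample label vector; samples with label None/NaN or
    missing survival are omitted (counted in ``n_omitted``).  Expected
    events per group come from the pooled log-rank decomposition, so the
    observed and expected totals match exactly.
    """
    mask = data.complete_mask
    codes, labels, use = _group_codes(groups, mask)
    if len(labels) == 0:
        raise ValueError("no usable groups for the K-M estimate")
    time = data.time[use]
    event = data.event[use]
    prep = _prepare_sorted(time, event)
    codes_sorted = codes[prep.order]
    O, E, _ = _logrank_oev(prep, codes_sorted, len(labels))

    curves: list[KMCurve] = []
    for j, lab in enumerate(labels):
        sel = codes == j
        t_j = time[sel]
        e_j = event[sel]
        p = _prepare_sorted(t_j, e_j)
        surv = np.cumprod(1.0 - p.d / p.n_risk)
        curves.append(
            KMCurve(
                label=lab,
                n=int(sel.sum()),
                observed=float(O[j]),
                expected=float(E[j]),
                event_times=p.ut.copy(),
                survival=surv,
                at_risk=p.n_risk.copy(),
                censor_times=np.sort(t_j[e_j == 0]),
            )
        )
    n_omitted = int(len(data) - use.sum())
    return KMCurveSet(curves=curves, total_events=float(event.sum()), n_omitted=n_omitted)


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogrankResult:
    """k-sample log-rank test outcome."""

    chi_square: float
    df: int
    p_value: float
    labels: list[str]
    n: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    eligible: bool
    min_expected: float
    n_omitted: int

    def summary(self) -> str:
        lines = ["Log-rank test"]
        for lab, n, o, e in zip(self.labels, self.n, self.observed, self.expected):
            lines.append(f"  {lab}: n={n}, Obs={o:g}, Exp={e:.2f}")
        lines.append(
            f"  chi-square = {self.chi_square:.4f} on {self.df} df, p = {self.p_value:.4g}"
        )
        if not self.eligible:
            lines.append(
                f"  [p-value suppressed in plots: fewer than two groups with "
                f">= {self.min_expected:g} expected events]"
            )
        if self.n_omitted:
            lines.append(f"  {self.n_omitted} sample(s) omitted (missing survival data)")
        return "\n".join(lines)


def logrank_test(
    data: SurvivalData, groups: Sequence, min_expected: float = 5.0
) -> LogrankResult:
    """k-sample log-rank test on the nonempty groups among complete cases.

    The statistic uses the full covariance of the observed-minus-expected
    vector on g-1 groups; ``eligible`` records whether at least two groups
    reach ``min_expected`` expected events (the condition under which the
    p-value is displayed on plots; the statistic itself is always computed).
    """
    mask = data.complete_mask
    codes, labels, use = _group_codes(groups, mask)
    g = len(labels)
    if g < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    time = data.time[use]
    event = data.event[use]
    prep = _prepare_sorted(time, event)
    O, E, V = _logrank_oev(prep, codes[prep.order], g)
    stat = _chi_square_from_oev(O, E, V)
    df = g - 1
    p = float(stats.chi2.sf(stat, df))
    n_groups = np.array([(codes == j).sum() for j in range(g)])
    return LogrankResult(
        chi_square=stat,
        df=df,
        p_value=p,
        labels=labels,
        n=n_groups,
        observed=O,
        expected=E,
        eligible=bool((E >= min_expected).sum() >= 2),
        min_expected=min_expected,
        n_omitted=int(len(data) - use.sum()),
    )


# ---------------------------------------------------------------------------
# batched log-rank over many markers (shared survival response)
# ---------------------------------------------------------------------------


def _logrank_scores_batch(
    prep: _SortedSurvival,
    codes: np.ndarray,
    k: int = 3,
    min_expected: float = 5.0,
) -> dict[str, np.ndarray]:
    """Log-rank chi-square for M markers at once.

    ``codes`` is (M, n) with group codes 0..k-1 for every complete-case
    sample (no missing codes allowed here; markers with missing copy values
    take the scalar path).  Because every sample belongs to some group, the
    per-time event totals and at-risk totals are marker-independent.
    """
    M, n = codes.shape
    Te = len(prep.ut)
    out_stat = np.full(M, np.nan)
    out_df = np.zeros(M, dtype=int)
    out_p = np.full(M, np.nan)
    eligible = np.zeros(M, dtype=bool)
    group_n = np.zeros((M, k), dtype=int)
    if Te == 0:
        return dict(stat=out_stat, df=out_df, p=out_p, eligible=eligible, group_n=group_n)

    cs = codes[:, prep.order]
    d = prep.d
    nr = prep.n_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(nr > 1, d * (nr - d) / (nr - 1), 0.0)

    ev_cols = np.isin(prep.first_all_idx, prep.first_event_idx)
    O = np.empty((M, k))
    E = np.empty((M, k))
    P = np.empty((M, k, Te))
    for j in range(k):
        mask = (cs == j).astype(float)
        group_n[:, j] = mask.sum(axis=1).astype(int)
        suffix = np.cumsum(mask[:, ::-1], axis=1)[:, ::-1]
        n_j = suffix[:, prep.first_event_idx]
        d_j = np.add.reduceat(mask * prep.event[None, :], prep.first_all_idx, axis=1)
        O[:, j] = d_j[:, ev_cols].sum(axis=1)
        p_j = n_j / nr
        P[:, j, :] = p_j
        E[:, j] = (d * p_j).sum(axis=1)

    # covariance: V[m, j, l] = sum_t w_t p_j (delta_jl - p_l)
    V = -np.einsum("t,mjt,mlt->mjl", w, P, P)
    diag = np.einsum("t,mjt->mj", w, P)
    V[:, np.arange(k), np.arange(k)] += diag

    U = O - E
    nonempty = group_n > 0
    g = nonempty.sum(axis=1)
    testable = g >= 2
    if testable.any():
        Vt = V[testable]
        Ut = U[testable]
        Vinv = np.linalg.pinv(Vt, hermitian=True)
        stat = np.einsum("mi,mij,mj->m", Ut, Vinv, Ut)
        out_stat[testable] = np.maximum(stat, 0.0)
        out_df[testable] = g[testable] - 1
        out_p[testable] = stats.chi2.sf(out_stat[testable], out_df[testable])
    eligible = (E >= min_expected).sum(axis=1) >= 2
    eligible &= testable
    return dict(stat=out_stat, df=out_df, p=out_p, eligible=eligible, group_n=group_n)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Cox regression fit; the first covariate is the marker score of interest."""

    params: pd.Series
    bse: pd.Series
    names: list[str] = field(default_factory=list)
    loglik: float = np.nan
    score_chi2: float = np.nan
    iterations: int = 0
    converged: bool = True
    n: int = 0
    n_events: int = 0
    n_omitted: int = 0
    ties: str = "breslow"

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    # convenience accessors for the primary covariate
    @property
    def beta(self) -> float:
        return float(self.params.iloc[0])

    @property
    def se(self) -> float:
        return float(self.bse.iloc[0])

    @property
    def z(self) -> float:
        return float(self.zvalues.iloc[0])

    @property
    def p_value(self) -> float:
        return float(self.pvalues.iloc[0])

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "exp(coef)": np.exp(self.params),
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        tab.attrs["loglik"] = self.loglik
        tab.attrs["n"] = self.n
        tab.attrs["n_events"] = self.n_events
        tab.attrs["converged"] = self.converged
        tab.attrs["ties"] = self.ties
        return tab


def _breslow_derivatives(
    prep: _SortedSurvival, X: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and observed information (Breslow)."""
    eta = np.clip(X @ beta, -500, 500)
    r = np.exp(eta)
    rX = r[:, None] * X
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rX[::-1], axis=0)[::-1]
    S2 = np.cumsum((rX[:, :, None] * X[:, None, :])[::-1], axis=0)[::-1]
    f = prep.first_event_idx
    d = prep.d
    s0 = S0[f]
    m1 = S1[f] / s0[:, None]
    m2 = S2[f] / s0[:, None, None]
    ev = prep.event.astype(bool)
    ll = float(eta[ev].sum() - (d * np.log(s0)).sum())
    grad = X[ev].sum(axis=0) - (d[:, None] * m1).sum(axis=0)
    info = (d[:, None, None] * (m2 - m1[:, :, None] * m1[:, None, :])).sum(axis=0)
    return ll, grad, info


def _efron_derivatives(
    prep: _SortedSurvival, X: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron tie correction; looped over distinct event times (API path only)."""
    eta = np.clip(X @ beta, -500, 500)
    r = np.exp(eta)
    rX = r[:, None] * X
    rXX = rX[:, :, None] * X[:, None, :]
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rX[::-1], axis=0)[::-1]
    S2 = np.cumsum(rXX[::-1], axis=0)[::-1]
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ev = prep.event.astype(bool)
    for f, d in zip(prep.first_event_idx, prep.d):
        d = int(d)
        stop = np.searchsorted(prep.time, prep.time[f], side="right")
        idx = f + np.flatnonzero(ev[f:stop])  # the tied events at this time
        s0_t, s1_t, s2_t = r[idx].sum(), rX[idx].sum(axis=0), rXX[idx].sum(axis=0)
        ll += eta[idx].sum()
        grad += X[idx].sum(axis=0)
        for l in range(d):
            frac = l / d
            a0 = S0[f] - frac * s0_t
            a1 = S1[f] - frac * s1_t
            a2 = S2[f] - frac * s2_t
            ll -= np.log(a0)
            m1 = a1 / a0
            grad -= m1
            info += a2 / a0 - np.outer(m1, m1)
    return float(ll), grad, info


def cox_fit(
    data: SurvivalData,
    covariate: np.ndarray,
    extra: pd.DataFrame | dict | None = None,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
    name: str = "copy_number",
) -> CoxResult:
    """Fit a Cox proportional-hazards model; ``covariate`` is the score term.

    Additional adjustment covariates can be supplied via ``extra`` (columns
    aligned with the samples).  Newton-Raphson starts at beta = 0 and stops
    when the log partial likelihood changes by less than ``tol`` (followed
    by one polishing step); non-convergence or a monotone likelihood is
    flagged through ``converged`` rather than raised.
    """
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != data.time.shape:
        raise ValueError("covariate must align with the survival data")
    names = [name]
    columns = [covariate]
    if extra is not None:
        extra_df = pd.DataFrame(extra)
        for c in extra_df.columns:
            names.append(str(c))
            columns.append(extra_df[c].to_numpy(dtype=float))
    X_full = np.column_stack(columns)

    mask = data.complete_mask & ~np.isnan(X_full).any(axis=1)
    n_omitted = int(len(data) - mask.sum())
    time = data.time[mask]
    event = data.event[mask]
    X = X_full[mask]
    if event.sum() < 1:
        raise ValueError("Cox regression needs at least one observed event")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = names[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"degenerate covariate {bad!r}: no variation across complete cases")

    prep = _prepare_sorted(time, event)
    Xs = X[prep.order]
    deriv = _breslow_derivatives if ties == "breslow" else _efron_derivatives
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = deriv(prep, Xs, beta)
    try:
        score_chi2 = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        score_chi2 = np.nan
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = deriv(prep, Xs, new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 10:
            new_beta = (beta + new_beta) / 2.0
            new_ll, new_grad, new_info = deriv(prep, Xs, new_beta)
            halvings += 1
        delta = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(delta) < tol:
            converged = True
            break
    if converged:
        # one polishing Newton step: quadratic convergence makes the
        # remaining error negligible relative to the reference optimum
        try:
            step = np.linalg.solve(info, grad)
            beta = beta + step
            ll, grad, info = deriv(prep, Xs, beta)
        except np.linalg.LinAlgError:
            pass
    if np.abs(beta * sds).max() > 50:
        converged = False  # monotone likelihood / separation
        logger.warning("cox_fit: likely monotone likelihood (|beta| diverging)")

    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        converged = False
    return CoxResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        names=names,
        loglik=ll,
        score_chi2=score_chi2,
        iterations=iterations,
        converged=converged,
        n=int(mask.sum()),
        n_events=int(event.sum()),
        n_omitted=n_omitted,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# batched single-covariate Cox over many markers (shared survival response)
# ---------------------------------------------------------------------------


def _cox_scores_batch(
    prep: _SortedSurvival,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> dict[str, np.ndarray]:
    """Univariate Breslow Cox fits for M markers at once.

    ``X`` is (M, n) in the complete-case sample order that produced
    ``prep``.  Returns beta, se, z and a converged flag per marker;
    degenerate (zero-variance) covariates come back as NaN.
    """
    M, n = X.shape
    xs = X[:, prep.order]
    e = prep.event
    f = prep.first_event_idx
    d = prep.d

    beta = np.zeros(M)
    ok = xs.std(axis=1) > 0
    xe_tot = (xs * e[None, :]).sum(axis=1)

    def _ll_grad_info(b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eta = np.clip(b[:, None] * xs, -500, 500)
        r = np.exp(eta)
        rx = r * xs
        rxx = rx * xs
        S0 = np.cumsum(r[:, ::-1], axis=1)[:, ::-1][:, f]
        S1 = np.cumsum(rx[:, ::-1], axis=1)[:, ::-1][:, f]
        S2 = np.cumsum(rxx[:, ::-1], axis=1)[:, ::-1][:, f]
        ll = b * xe_tot - (d[None, :] * np.log(S0)).sum(axis=1)
        m1 = S1 / S0
        g = xe_tot - (d[None, :] * m1).sum(axis=1)
        info = (d[None, :] * (S2 / S0 - m1 * m1)).sum(axis=1)
        return ll, g, info

    ll, g, info = _ll_grad_info(beta)
    converged = np.zeros(M, dtype=bool)
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, g / info, 0.0)
        step = np.clip(step, -10.0, 10.0)
        new_beta = np.where(active, beta + step, beta)
        new_ll, new_g, new_info = _ll_grad_info(new_beta)
        # vectorized step-halving where the likelihood went down
        for _ in range(8):
            worse = active & (new_ll < ll - 1e-12)
            if not worse.any():
                break
            new_beta = np.where(worse, (beta + new_beta) / 2.0, new_beta)
            new_ll, new_g, new_info = _ll_grad_info(new_beta)
        done = active & (np.abs(new_ll - ll) < tol)
        converged |= done
        beta, ll, g, info = new_beta, new_ll, new_g, new_info
        active &= ~done
    # polishing step for the converged markers
    with np.errstate(divide="ignore", invalid="ignore"):
        step = np.where(converged & (info > 1e-12), g / info, 0.0)
    beta = beta + np.clip(step, -10.0, 10.0)
    ll, g, info = _ll_grad_info(beta)

    sds = xs.std(axis=1)
    diverged = np.abs(beta * np.where(ok, sds, 1.0)) > 50
    converged &= ~diverged
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
        z = beta / se
    bad = ~ok | ~converged
    out = dict(
        beta=np.where(bad, np.nan, beta),
        se=np.where(bad, np.nan, se),
        z=np.where(bad, np.nan, z),
        converged=converged & ok,
    )
    return out
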