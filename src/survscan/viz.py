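"""Static figures: Kaplan-Meier plots and genome score tracks.

These replace the interactive chromosome browser with matplotlib output
(PNG or SVG).  Plot functions are pure consumers: they never mutate the
result objects they draw.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .genome_scan import ScanResult
from .permutation import PermutationNull
from .survival_stats import KMCurveSet, LogrankResult

_GROUP_COLORS = {
    "Deletion": "#1f77b4",
    "No change": "#2ca02c",
    "Gain": "#d62728",
}
_FALLBACK = ("#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e", "#8c564b")


def _steps(curve):
    """Step-function vertices (start at S=1, drop after each event time)."""
    x = np.concatenate(([0.0], curve.event_times))
    y = np.concatenate(([1.0], curve.survival))
    return x, y


def plot_km(
    curves: KMCurveSet,
    result: LogrankResult | None = None,
    out: str | Path = "km.png",
    title: str | None = None,
) -> Path:
    """Kaplan-Meier step curves with censor ticks and an n/Exp/Obs legend.

    The log-rank p-value is printed only when the result is eligible (at
    least two groups with enough expected events); an ineligible or absent
    result renders the figure without a p-value annotation.
    """
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    for i, curve in enumerate(curves):
        color = _GROUP_COLORS.get(curve.label, _FALLBACK[i % len(_FALLBACK)])
        x, y = _steps(curve)
        ax.step(
            np.append(x, max(x.max(), curve.censor_times.max() if len(curve.censor_times) else 0)),
            np.append(y, y[-1]),
            where="post",
            color=color,
            label=f"{curve.label}: n={curve.n}, Exp={curve.expected:.1f}, Obs={curve.observed:g}",
        )
        if len(curve.censor_times):
            cy = [curve.survival_at(t) for t in curve.censor_times]
            ax.plot(curve.censor_times, cy, "|", color=color, markersize=8)
    if result is not None and result.eligible:
        ax.text(
            0.02,
            0.06,
            f"log-rank p = {result.p_value:.3g}",
            transform=ax.transAxes,
            fontsize=9,
        )
    ax.set_xlabel("Time")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(-0.02, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150, metadata={"Software": None} if out.suffix == ".png" else None)
    plt.close(fig)
    return out


def plot_scan(
    result: ScanResult,
    null: PermutationNull | None = None,
    out: str | Path = "scan.png",
    title: str | None = None,
) -> Path:
    """Per-chromosome score tracks; threshold drawn when a null is given.

    The log-rank track is -log10 p; the Cox track shows |z| with the sign
    encoded by color (red positive, blue negative).
    """
    tab = result.table
    chroms = list(dict.fromkeys(tab["chromosome"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(2.8 * len(chroms) + 1, 3.2), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = tab[tab["chromosome"] == chrom]
        pos = sub["position"].to_numpy() / 1e6
        score = sub["score"].to_numpy()
        finite = np.isfinite(score)
        if not finite.any():
            ax.text(0.5, 0.5, "no testable markers", transform=ax.transAxes,
                    ha="center", fontsize=8, color="gray")
        elif result.method == "cox":
            colors = np.where(score[finite] >= 0, "#d62728", "#1f77b4")
            ax.scatter(pos[finite], np.abs(score[finite]), s=8, c=colors)
        else:
            ax.plot(pos[finite], score[finite], color="#1f77b4", lw=1)
        if null is not None:
            ax.axhline(null.threshold, color="red", lw=1, ls="--")
        ax.set_title(f"chr{chrom}", fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
    ylabel = "|z| (Cox)" if result.method == "cox" else "-log10 p (log-rank)"
    axes[0][0].set_ylabel(ylabel, fontsize=9)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
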