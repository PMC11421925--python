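"""Figure-style plotting utilities.

Kept deliberately thin: a DF-vs-depth profile with random-walk 95%
bands and an optional five-level moving average, and a null-rho
histogram with an arrow marking the observed correlation.  Figures are
built with the object-oriented matplotlib API so no interactive backend
is needed.
"""

from __future__ import annotations

import numpy as np
from matplotlib.figure import Figure

from .df_randomwalk import DFSeries, moving_average
from .predator_trend import TrendTestResult


def df_profile_figure(
    series: DFSeries,
    band_lower: np.ndarray | None = None,
    band_upper: np.ndarray | None = None,
    smooth_window: int = 5,
) -> Figure:
    """DF vs depth (depth increasing downward) with optional 95% bands."""
    fig = Figure(figsize=(4.5, 6))
    ax = fig.subplots()
    ax.plot(series.values, series.depths, "o-", color="tab:blue", label="DF")
    if band_lower is not None and band_upper is not None:
        ax.fill_betweenx(
            series.depths,
            band_lower,
            band_upper,
            color="tab:blue",
            alpha=0.15,
            label="random-walk 95% band",
        )
    if series.n_levels >= smooth_window:
        smooth = moving_average(series.values, smooth_window)
        centres = series.depths[smooth_window // 2 : smooth_window // 2 + smooth.size]
        ax.plot(smooth, centres, "-", color="tab:red", label=f"{smooth_window}-level mean")
    ax.invert_yaxis()
    ax.set_xlabel("drilling frequency")
    ax.set_ylabel("core depth (cm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def null_rho_figure(result: TrendTestResult, bins: int = 40) -> Figure:
    """Histogram of the Monte-Carlo null rhos with the observed value arrowed."""
    fig = Figure(figsize=(5, 3.5))
    ax = fig.subplots()
    ax.hist(result.null_rhos, bins=bins, color="0.7", edgecolor="0.4")
    ymax = ax.get_ylim()[1]
    ax.annotate(
        f"observed rho = {result.rho_observed:.2f}",
        xy=(result.rho_observed, 0),
        xytext=(result.rho_observed, 0.6 * ymax),
        arrowprops={"arrowstyle": "->", "color": "tab:red"},
        ha="center",
        fontsize=8,
    )
    ax.set_xlabel("Spearman rho under the null")
    ax.set_ylabel("iterations")
    fig.tight_layout()
    return fig


def save_df_profile(series, band_lower, band_upper, path) -> None:
    df_profile_figure(series, band_lower, band_upper).savefig(path, dpi=150)


def save_null_rho(result, path) -> None:
    null_rho_figure(result).savefig(path, dpi=150)
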