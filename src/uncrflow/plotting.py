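"""Diagnostic and report plots (matplotlib, Agg-safe)."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from uncrflow.epochs import EpochResult
from uncrflow.features import TrendFit, UNCRSeries, peak_height_series


def plot_participant(series: UNCRSeries, fit: TrendFit, path=None):
    """Two-panel decomposition view: series with robust trend on top,
    shaded percent-height curve below."""
    heights = peak_height_series(series, fit)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    ax1.plot(series.days, series.values, "o-", ms=3, lw=0.8, label="UNCR")
    ax1.plot(series.days, fit.predict(series.days), "r-", label="robust trend")
    mid = (series.days[0] + series.days[-1]) / 2
    ax1.axvline(mid, color="r", ls=":", lw=1)
    ax1.set_ylabel("UNCR (µmol/mol)")
    ax1.legend(frameon=False)
    ax1.set_title(
        f"{series.participant_id}: background {fit.midpoint_value:.1f} µmol/mol"
    )
    ax2.fill_between(series.days, heights, color="c", alpha=0.5)
    ax2.plot(series.days, heights, "c-", lw=0.8)
    ax2.set_xlabel("study day")
    ax2.set_ylabel("height above trend (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_stratified(curves: Mapping[str, "pd.DataFrame"], path=None):
    """Predicted atrophy vs inflammatory response per background stratum."""
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"below_median": "tab:red", "above_median": "tab:blue",
              "lower_tertile": "tab:red", "upper_tertile": "tab:blue"}
    for name, df in curves.items():
        c = colors.get(name, None)
        ax.plot(df["response"], df["predicted"], color=c, label=f"{name} (n={df['n'].iloc[0]})")
        ax.plot(df["response"], df["ci_low"], ls=":", lw=1, color=c)
        ax.plot(df["response"], df["ci_high"], ls=":", lw=1, color=c)
    ax.set_xlabel("inflammatory response (%·days/year)")
    ax.set_ylabel("predicted annualized cord atrophy (%/year)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_epoch_profile(results: Sequence[EpochResult], path=None,
                       predictors: Sequence[str] = ("response", "background")):
    """Lag profile: standardized β with 95% CI per epoch, significant
    epochs highlighted."""
    fig, axes = plt.subplots(len(predictors), 1, figsize=(9, 3 * len(predictors)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, pred in zip(axes, predictors):
        idx = [r.window.index for r in results if r.fitted and pred in r.terms]
        beta = [r.terms[pred].std_beta for r in results if r.fitted and pred in r.terms]
        lo = [r.terms[pred].ci_low for r in results if r.fitted and pred in r.terms]
        hi = [r.terms[pred].ci_high for r in results if r.fitted and pred in r.terms]
        sig = [r.terms[pred].significant for r in results if r.fitted and pred in r.terms]
        ax.plot(idx, beta, "k-", lw=1)
        ax.fill_between(idx, lo, hi, color="grey", alpha=0.3)
        sig_idx = [i for i, s in zip(idx, sig) if s]
        sig_beta = [b for b, s in zip(beta, sig) if s]
        ax.plot(sig_idx, sig_beta, "ro", ms=3, label="p < 0.05")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel(f"std β ({pred})")
        ax.legend(frameon=False)
    axes[-1].set_xlabel("epoch (1 = earliest window before exit)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
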