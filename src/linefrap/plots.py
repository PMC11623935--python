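"""Publication-style figures: recovery curves with fits, bleach profiles with
Gaussian fits, and diffusion-coefficient bar charts with SE bars and
significance tiers."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_recovery", "plot_profile", "plot_d_bar"]


def plot_recovery(curve, fit=None, path=None, title=""):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.time, curve.intensity, ".", ms=2, color="0.5", label="data")
    if curve.pointwise_se is not None and np.any(curve.pointwise_se > 0):
        ax.fill_between(
            curve.time,
            curve.intensity - curve.pointwise_se,
            curve.intensity + curve.pointwise_se,
            color="0.8",
            lw=0,
        )
    if fit is not None and fit.ok:
        t = np.linspace(0, curve.time.max(), 400)
        ax.plot(t, fit.predict(t), "r-", lw=1.5,
                label=f"fit (R={fit.fit_corr:.2f})")
        if np.isfinite(fit.tau_half):
            ax.axvline(fit.tau_half, color="b", ls=":", lw=1,
                       label=f"$\\tau_{{1/2}}$ = {fit.tau_half * 1e3:.1f} ms")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized fluorescence")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_profile(profile, radius=None, path=None, title=""):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.position, profile.depth, ".", ms=3, color="0.4", label="depth")
    if radius is not None:
        x = np.linspace(profile.position[0], profile.position[-1], 400)
        y = radius.bleach_depth_K * np.exp(
            -2.0 * (x - radius.center_um) ** 2 / radius.r_e**2
        )
        ax.plot(x, y, "g-", lw=1.5, label=f"Gaussian, $r_e$={radius.r_e:.2f} µm")
    ax.set_xlabel("position (µm)")
    ax.set_ylabel("bleach depth")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_d_bar(results, comparisons=None, path=None):
    """Bar chart of D_confocal ± SE per condition, annotated with tiers."""
    labels = [r.condition for r in results]
    d = [r.d_confocal for r in results]
    se = [r.se for r in results]
    fig, ax = plt.subplots(figsize=(1.2 * max(len(labels), 3) + 1, 3.5))
    xs = np.arange(len(labels))
    ax.bar(xs, d, yerr=se, capsize=3, color="steelblue")
    ax.set_xticks(xs)
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel("$D_{confocal}$ (µm²/s)")
    if comparisons:
        tier_by_label = {c.condition_a: c.tier for c in comparisons}
        for i, label in enumerate(labels):
            if label in tier_by_label:
                ax.text(i, d[i] + se[i], tier_by_label[label],
                        ha="center", va="bottom", fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
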