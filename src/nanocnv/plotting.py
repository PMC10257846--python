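"""Diagnostic plots: regional-mean scatter and windowed read-depth profiles.

Plots are reporting artifacts; the numbers live in the TSV outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .confirm import ConfirmationResult
from .depth import WindowedDepth

__all__ = ["plot_regional_means", "plot_windowed_depth"]

_ROLE_COLORS = {"control": "#4878a8", "pad_left": "#6aa84f",
                "pad_right": "#6aa84f", "cnv": "#c0392b"}


def plot_regional_means(result: ConfirmationResult, path: str | Path) -> None:
    """Scatter of normalized regional mean depths with the dynamic cutoffs."""
    ratios = result.ratios
    fig, ax = plt.subplots(figsize=(6, 4))
    x = 0
    for value, label, role in [
        *[(v, lab, "control") for v, lab in
          zip(ratios.control_ratios, ratios.control_labels)],
        *[(v, "pad", "pad_left") for v in ratios.pad_ratios],
        (ratios.cnv_ratio, "cnv", "cnv"),
    ]:
        ax.scatter(x, value, color=_ROLE_COLORS[role], zorder=3)
        x += 1
    ax.axhline(1.0, color="gray", ls=":", lw=1)
    ax.axhline(result.cutoffs.controls_only, color="gray", ls="--",
               label="cutoff (controls)")
    if result.cutoffs.controls_plus_pads is not None:
        ax.axhline(result.cutoffs.controls_plus_pads, color="#6aa84f", ls="--",
                   label="cutoff (controls+pads)")
    ax.set_ylabel("normalized mean depth ratio")
    ax.set_xlabel("region")
    ax.set_title(
        f"{result.cnv.expected_type}: ratio {result.cnv_ratio:.2f}, "
        f"cutoff {result.cutoffs.effective:.2f}, "
        f"{'confirmed' if result.confirmed else 'not confirmed'}"
    )
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_windowed_depth(
    windows: WindowedDepth, normalizer: float, path: str | Path
) -> None:
    """Windowed depth across the target, normalized by the control mean."""
    fig, ax = plt.subplots(figsize=(8, 3))
    starts = windows.region.start + windows.window_sizes.cumsum() - windows.window_sizes
    ax.step(starts, windows.window_means / normalizer, where="post", lw=1)
    mean_ratio = (
        float((windows.window_means * windows.window_sizes).sum())
        / windows.window_sizes.sum() / normalizer
    )
    ax.axhline(mean_ratio, color="#c0392b", ls="--", lw=1)
    ax.set_xlabel(f"{windows.region.chrom} position")
    ax.set_ylabel("depth ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
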