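"""Minimal plotting helpers (PNG summaries only)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_band_power(bp_list, path, title: str = "") -> None:
    """Overlay smoothed band-power series for a handful of animals."""
    fig, ax = plt.subplots(figsize=(8, 3))
    for bp in bp_list:
        v = np.where(bp.valid, bp.values, np.nan)
        ax.plot(bp.age_days, v, lw=0.8, label=bp.animal_id)
    ax.set_xlabel("postnatal day")
    ax.set_ylabel(f"max power {bp_list[0].band[0]:g}-{bp_list[0].band[1]:g} h")
    if title:
        ax.set_title(title)
    if len(bp_list) <= 8:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_combined_metric(metric, path) -> None:
    """Daily combined ovulatory metric z(CBT) - z(UR power) for one animal."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(metric.day, metric.combined, "o-", ms=3)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("postnatal day")
    ax.set_ylabel("z(CBT) - z(UR power)")
    ax.set_title(metric.animal_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
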