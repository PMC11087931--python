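"""Plot helpers for DVH curves and contour-edit histograms (matplotlib, Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_dvh(curves, path: str | Path, title: str = "Cumulative DVH"):
    """Plot one or more :class:`~caaseg.dosimetry.DvhCurve` objects."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.bin_edges_gy, curve.relative_volume_pct, label=curve.structure or None)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_ylim(0, 105)
    ax.set_title(title)
    if any(c.structure for c in curves):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_edit_histograms(values_msd, values_dsc, path: str | Path, msd_bin_mm: float = 0.25, dsc_bin: float = 0.01):
    """Histograms of MSD and DSC between auto and clinician-edited contours.

    Bins cover the observed range at the stated widths.
    """
    values_msd = np.asarray(values_msd, dtype=float)
    values_dsc = np.asarray(values_dsc, dtype=float)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    bins_msd = np.arange(0.0, values_msd.max() + 2 * msd_bin_mm, msd_bin_mm)
    bins_dsc = np.arange(max(0.0, values_dsc.min() - dsc_bin), 1.0 + dsc_bin, dsc_bin)
    axes[0].hist(values_msd, bins=bins_msd, color="tab:blue")
    axes[0].set_xlabel("MSD (mm)")
    axes[0].set_ylabel("Cases")
    axes[1].hist(values_dsc, bins=bins_dsc, color="tab:orange")
    axes[1].set_xlabel("DSC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
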