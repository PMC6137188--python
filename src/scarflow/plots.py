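"""Optional QC figures: streakline histograms and segmentation overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_streakline", "plot_segmentation_overlay"]


def plot_streakline(
    edges_frac: np.ndarray,
    counts: np.ndarray,
    path: str | Path,
    title: str = "lateral intensity",
) -> None:
    """Save the lateral intensity histogram of a focused mixture as PNG."""
    fig, ax = plt.subplots(figsize=(6, 3))
    centers = (edges_frac[:-1] + edges_frac[1:]) / 2.0
    ax.bar(centers, counts, width=np.diff(edges_frac), color="0.3")
    ax.set_xlabel("lateral position x/w (0 = convex wall)")
    ax.set_ylabel("particle count")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_segmentation_overlay(
    image: np.ndarray,
    labels: np.ndarray,
    path: str | Path,
) -> None:
    """Save the raw channel with segmented cell outlines as a QC PNG."""
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image, cmap="gray")
    edges = find_boundaries(labels, mode="outer")
    overlay = np.zeros((*image.shape, 4))
    overlay[edges] = (1.0, 0.2, 0.2, 0.9)
    ax.imshow(overlay)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
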