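"""Heat-map and scatter figures for the comparative analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .essential_dynamics import PCAResult
from .stability_metrics import TrajMapMatrix
from .structural_features import ContactMap

__all__ = ["plot_contact_map", "plot_trajectory_map", "plot_pca_projections"]


def plot_contact_map(cmap: ContactMap, path: str | Path, title: str = "") -> None:
    """Contact heat map: pairwise C-alpha distances below the cutoff."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    masked = np.where(cmap.distances < cmap.cutoff, cmap.distances, np.nan)
    im = ax.imshow(masked, origin="lower", cmap="viridis",
                   extent=[cmap.residue_numbers[0], cmap.residue_numbers[-1]] * 2)
    fig.colorbar(im, ax=ax, label="C$\\alpha$ distance ($\\mathrm{\\AA}$)")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(title or f"contacts < {cmap.cutoff:g} $\\mathrm{{\\AA}}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory_map(tmap: TrajMapMatrix, path: str | Path, title: str = "") -> None:
    """Frames x residues displacement heat map (frames on x, residues on y)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(tmap.displacement.T, origin="lower", aspect="auto", cmap="inferno",
                   extent=[0, tmap.n_frames, tmap.residue_numbers[0], tmap.residue_numbers[-1]])
    fig.colorbar(im, ax=ax, label="backbone COM displacement ($\\mathrm{\\AA}$)")
    ax.set_xlabel("frame")
    ax.set_ylabel("residue")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_projections(
    results: list[tuple[str, np.ndarray]], path: str | Path, title: str = ""
) -> None:
    """PC1-PC2 scatter overlay of one or more systems."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for label, proj in results:
        ax.scatter(proj[:, 0], proj[:, 1], s=6, alpha=0.5, label=label)
    ax.set_xlabel("PC1 ($\\mathrm{\\AA}$)")
    ax.set_ylabel("PC2 ($\\mathrm{\\AA}$)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_occupancy_histogram(pca_result: PCAResult, bins: int = 30) -> np.ndarray:
    """2D histogram of PC1-PC2 occupancy (for TSV export)."""
    h, _, _ = np.histogram2d(
        pca_result.projections[:, 0], pca_result.projections[:, 1], bins=bins
    )
    return h
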