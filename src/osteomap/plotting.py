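"""Programmatic rendering of maps, heatmaps and ordinations.

Colour conventions follow the field: resorption maps use cold tones for high
percent resorption and warm tones for low (0 = formation); shape-change
heatmaps use warm tones for positive (outward) and cold for negative
displacement, symmetric about zero.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

_PNG_META = {"Software": None}  # keep rendered files byte-stable across runs


def _save(fig, path):
    fig.savefig(path, dpi=110, metadata=_PNG_META)
    plt.close(fig)


def render_bm_map(values: np.ndarray, valid: np.ndarray, path,
                  title: str = "") -> None:
    """Render a resorption map; masked squares are blank."""
    shown = np.where(valid, values, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(shown, cmap="coolwarm_r", vmin=0, vmax=100)
    ax.set_title(title)
    ax.set_xlabel("anterior -> posterior")
    ax.set_ylabel("inferior <- superior")
    fig.colorbar(im, ax=ax, label="% bone resorption")
    _save(fig, path)


def render_heatmap(heatmap, path, title: str = "") -> None:
    """Render a signed-distance heatmap as a vertex scatter (warm = outward)."""
    mesh = heatmap.base_mesh
    lim = max(heatmap.scale[1], 1e-12)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    sc = ax.scatter(mesh.vertices[:, 0], mesh.vertices[:, 2], s=4,
                    c=heatmap.distances, cmap="coolwarm", vmin=-lim, vmax=lim)
    ax.set_aspect("equal")
    ax.set_title(title or f"AG {heatmap.group_pair[0]} -> "
                          f"AG {heatmap.group_pair[1]}")
    fig.colorbar(sc, ax=ax, label="signed distance (mm)")
    _save(fig, path)


def render_pca(scores: np.ndarray, variance_fractions: np.ndarray,
               labels, path, axes: tuple[int, int] = (0, 1),
               title: str = "") -> None:
    a, b = axes
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for g in np.unique(labels):
        sel = labels == g
        ax.scatter(scores[sel, a], scores[sel, b], s=14, label=str(g))
    ax.set_xlabel(f"PC{a + 1} ({100 * variance_fractions[a]:.1f}%)")
    ax.set_ylabel(f"PC{b + 1} ({100 * variance_fractions[b]:.1f}%)")
    ax.legend(fontsize=7)
    ax.set_title(title)
    _save(fig, path)


def render_br_trajectories(table, path) -> None:
    """Total %BR against age group, one line per species (mean with
    quartile band)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for sp, sub in table.groupby("species"):
        agg = sub.groupby("age_group")["total_pct_br"]
        ages = agg.mean().index.to_numpy()
        ax.plot(ages, agg.mean().to_numpy(), "--", label=sp)
        ax.fill_between(ages, agg.quantile(0.25).to_numpy(),
                        agg.quantile(0.75).to_numpy(), alpha=0.2)
    ax.set_xlabel("age group")
    ax.set_ylabel("total % bone resorption")
    ax.legend(fontsize=7)
    _save(fig, path)
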