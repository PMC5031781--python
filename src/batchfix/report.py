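"""Diagnostic plots: CV distributions, cluster drift curves, PCA scores."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)  # file output; no display required

import matplotlib.pyplot as plt
import numpy as np

from .drift import DriftCorrectionResults
from .peak_table import PeakTable

__all__ = ["cv_histogram", "drift_cluster_plot", "pca_scores"]


def _finish(fig, path):
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def cv_histogram(cv_before, cv_after, path=None, *, cv_limit: float = 30.0):
    """Overlaid QC-CV histograms before/after correction, with the filter limit."""
    before = np.asarray(cv_before, dtype=float)
    after = np.asarray(cv_after, dtype=float)
    before, after = before[np.isfinite(before)], after[np.isfinite(after)]
    hi = np.nanpercentile(np.concatenate([before, after]), 99) if before.size else 100
    bins = np.linspace(0, max(hi, cv_limit * 1.5), 40)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(before, bins=bins, alpha=0.6, color="0.25", label="before")
    ax.hist(after, bins=bins, alpha=0.6, color="0.7", label="after")
    ax.axvline(cv_limit, color="firebrick", ls="--", lw=1, label=f"{cv_limit:g} % limit")
    ax.set_xlabel("QC feature CV (%)")
    ax.set_ylabel("features")
    ax.legend(frameon=False)
    return _finish(fig, path)


def drift_cluster_plot(results: DriftCorrectionResults, cluster_id: int, path=None):
    """Scaled member features (grey), drift function (black), and the
    corrected features on the same y-scale below."""
    cluster = next(c for c in results.clusters if c.cluster_id == cluster_id)
    t = results.model.table
    inj = t.injection_orders()
    idx = [t.feature_index(f) for f in cluster.member_ids]
    scaled = t.intensities[:, idx] / results.scales[idx]
    if cluster.correction_factors is not None:
        pos = np.searchsorted(results.injection_orders, inj)
        corrected = scaled * cluster.correction_factors[pos][:, None]
    else:
        corrected = scaled
    order = np.argsort(inj)
    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True, sharey=True)
    for ax, mat, title in (
        (axes[0], scaled, f"cluster {cluster_id} ({cluster.action})"),
        (axes[1], corrected, "after correction"),
    ):
        ax.plot(inj[order], mat[order], color="0.7", lw=0.6)
        ax.set_title(title, fontsize=10)
        ax.set_ylabel("scaled intensity")
    axes[0].plot(
        results.injection_orders, cluster.drift_values, color="black", lw=1.8,
        label="drift function",
    )
    axes[0].legend(frameon=False, fontsize=8)
    axes[1].set_xlabel("injection order")
    return _finish(fig, path)


def pca_scores(table: PeakTable, path=None, *, color_by: str = "sample_type"):
    """PCA score plot of log-intensities, coloured by sample type or batch."""
    from sklearn.decomposition import PCA

    x = np.log(np.maximum(table.intensities, 1.0))
    x = x - x.mean(axis=0)
    scores = PCA(n_components=2).fit_transform(x)
    if color_by == "sample_type":
        labels = [s.sample_type for s in table.samples]
    elif color_by == "batch":
        labels = [s.batch for s in table.samples]
    else:
        raise ValueError(f"color_by must be 'sample_type' or 'batch', got {color_by!r}")
    fig, ax = plt.subplots(figsize=(5, 5))
    for lab in dict.fromkeys(labels):
        mask = np.array([l == lab for l in labels])
        ax.scatter(scores[mask, 0], scores[mask, 1], s=14, label=lab, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    return _finish(fig, path)
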