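"""Plots: PC scatter with cluster boundaries, loading heat maps, box plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort_compare import DistanceRecord, split_intra_inter
from .fingerprint_core import ClusterAssignment, Embedding, PCAModel


def plot_embedding(
    embedding: Embedding,
    model: PCAModel,
    path: str | Path,
    clusters: ClusterAssignment | None = None,
    cohorts: Mapping[str, str] | None = None,
) -> Path:
    """PC1-vs-PC2 scatter colored by donor.

    Axis labels carry the percent variation explained by each component;
    when a clustering is given, each cluster is circled at twice its RMS
    radius.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    donors = list(dict.fromkeys(embedding.donors))
    cmap = plt.colormaps["tab10"]
    for i, donor in enumerate(donors):
        mask = np.array([d == donor for d in embedding.donors])
        label = donor
        if cohorts and donor in cohorts:
            label = f"{donor} ({cohorts[donor]})"
        ax.scatter(
            embedding.coordinates[mask, 0],
            embedding.coordinates[mask, 1],
            s=18,
            color=cmap(i % 10),
            label=label,
        )
    if clusters is not None:
        for k in range(clusters.k):
            mask = clusters.labels == k
            pts = embedding.coordinates[mask, :2]
            center = pts.mean(axis=0)
            radius = 2.0 * np.sqrt(((pts - center) ** 2).sum(axis=1).mean())
            ax.add_patch(
                plt.Circle(center, radius, fill=False, color="black", linewidth=1.2)
            )
    ratios = model.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * ratios[0]:.1f}%)")
    if len(ratios) > 1:
        ax.set_ylabel(f"PC2 ({100 * ratios[1]:.1f}%)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_weight_heatmap(weights: pd.DataFrame, path: str | Path) -> Path:
    """Feature-by-component heat map of PCA loadings."""
    path = Path(path)
    components = [c for c in weights.columns if not c.endswith("_rank")]
    values = weights[components].to_numpy()
    fig, ax = plt.subplots(figsize=(4, max(3, 0.04 * len(weights))))
    limit = np.abs(values).max() or 1.0
    image = ax.imshow(values, aspect="auto", cmap="RdBu_r", vmin=-limit, vmax=limit)
    ax.set_xticks(range(len(components)), components)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(weights)} V-J pairs")
    fig.colorbar(image, ax=ax, label="loading")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_distance_boxes(
    records_by_metric: Mapping[str, Sequence[DistanceRecord]],
    path: str | Path,
) -> Path:
    """Side-by-side intra/inter distance box plots, one panel per metric."""
    path = Path(path)
    fig, axes = plt.subplots(
        1, len(records_by_metric), figsize=(4 * len(records_by_metric), 4),
        squeeze=False,
    )
    for ax, (metric, records) in zip(axes[0], records_by_metric.items()):
        first, second, inter = split_intra_inter(records)
        labels = sorted({r.group for r in records if r.group != "inter"}) + ["inter"]
        data = [g for g in (first, second, inter) if g]
        ax.boxplot(data, tick_labels=labels[: len(data)])
        ax.set_title(metric)
        ax.set_ylabel("distance")
        ax.tick_params(axis="x", labelrotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
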