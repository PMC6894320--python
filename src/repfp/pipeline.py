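"""High-level drivers composing the fingerprinting stages.

These helpers run count table -> replicates -> normalization -> PCA ->
embedding -> K-means (and the cohort comparison on top) in one call; the
command-line interface and batch analyses are thin wrappers around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .clonotype_io import VJCountTable
from .cohort_compare import (
    DistanceRecord,
    RDISpec,
    TestResult,
    intra_vs_inter_tests,
    pc_pairwise_distances,
    rdi_pairwise_distances,
)
from .fingerprint_core import (
    ClusterAssignment,
    ClusterSpec,
    Embedding,
    FeatureMatrix,
    NormalizationSpec,
    PCAModel,
    SubsampleSpec,
    build_replicate_matrix,
    feature_weights,
    fit_pca,
    kmeans_cluster,
    project,
    zscore_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class FingerprintResult:
    """Everything produced by one fingerprinting run."""

    replicates: FeatureMatrix
    normalized: FeatureMatrix
    model: PCAModel
    embedding: Embedding
    clusters: ClusterAssignment
    weights: "object" = field(default=None, repr=False)  # pandas DataFrame


def run_fingerprint(
    table: VJCountTable,
    subsample: SubsampleSpec | None = None,
    normalization: NormalizationSpec | None = None,
    n_components: int = 2,
    cluster: ClusterSpec | None = None,
) -> FingerprintResult:
    """Full fingerprint pipeline on a donor x V-J count table."""
    subsample = subsample or SubsampleSpec()
    replicates = build_replicate_matrix(table, subsample)
    normalized = zscore_normalize(replicates, normalization)
    model = fit_pca(normalized, n_components=n_components)
    embedding = project(model, normalized)
    clusters = kmeans_cluster(embedding, cluster)
    weights = feature_weights(model, components=tuple(range(min(2, n_components))))
    return FingerprintResult(
        replicates=replicates,
        normalized=normalized,
        model=model,
        embedding=embedding,
        clusters=clusters,
        weights=weights,
    )


def run_fingerprint_matrix(
    matrix: FeatureMatrix,
    normalization: NormalizationSpec | None = None,
    n_components: int = 2,
    cluster: ClusterSpec | None = None,
) -> FingerprintResult:
    """Pipeline from a prebuilt replicate matrix (e.g. alternate features)."""
    normalized = zscore_normalize(matrix, normalization)
    model = fit_pca(normalized, n_components=n_components)
    embedding = project(model, normalized)
    clusters = kmeans_cluster(embedding, cluster)
    weights = feature_weights(model, components=tuple(range(min(2, n_components))))
    return FingerprintResult(
        replicates=matrix,
        normalized=normalized,
        model=model,
        embedding=embedding,
        clusters=clusters,
        weights=weights,
    )


@dataclass
class ComparisonResult:
    """Distances and rank tests for both metrics."""

    pc_distances: list[DistanceRecord]
    rdi_distances: list[DistanceRecord]
    pc_tests: dict[str, TestResult]
    rdi_tests: dict[str, TestResult]


def run_comparison(
    table: VJCountTable,
    embedding: Embedding,
    cohorts: Mapping[str, str],
    rdi: RDISpec | None = None,
) -> ComparisonResult:
    """PC-distance and RDI comparisons with intra-vs-inter rank tests."""
    pc_records = pc_pairwise_distances(embedding, cohorts)
    count_rows = {d: table.row(d) for d in table.donor_ids}
    rdi_records = rdi_pairwise_distances(count_rows, cohorts, rdi or RDISpec())
    return ComparisonResult(
        pc_distances=pc_records,
        rdi_distances=rdi_records,
        pc_tests=intra_vs_inter_tests(pc_records),
        rdi_tests=intra_vs_inter_tests(rdi_records),
    )


def cluster_cohort_agreement(
    clusters: ClusterAssignment,
    embedding: Embedding,
    cohorts: Mapping[str, str],
) -> float:
    """Adjusted Rand index between replicate cluster labels and cohorts."""
    from sklearn.metrics import adjusted_rand_score

    truth = [cohorts[d] for d in embedding.donors]
    return float(adjusted_rand_score(truth, clusters.labels))
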