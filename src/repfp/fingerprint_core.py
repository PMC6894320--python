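"""Core fingerprinting pipeline: replicates, normalization, PCA, clustering.

A donor's V-J pair count vector is resampled with replacement to a fixed
depth (multinomial draws), emulating repeated sequencing of the same
subject. The replicate count matrix is normalized per feature — log10 with
a pseudocount for unobserved genes, Z-scored across rows, then transformed
back out of log space — which de-emphasizes genes with very low counts.
PCA reduces the normalized matrix to a few components ("the repertoire
fingerprint") and K-means groups replicates in component space.

Numerical conventions fixed here: the Z score uses the population standard
deviation (divide by n); zero-variance features get Z = 0 everywhere
(back-transformed value 1); PCA centers columns but applies no further
scaling, since Z-normalization already equalized feature scales.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .clonotype_io import FeatureSpace, VJCountTable

logger = logging.getLogger(__name__)


def _donor_rng(seed: int, donor_id: str) -> np.random.Generator:
    """Independent stream per donor, keyed by donor id.

    Keyed by a hash of the donor label (not its position) so adding or
    removing one donor never perturbs another donor's replicates.
    """
    key = zlib.crc32(str(donor_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SubsampleSpec:
    """Multinomial resampling parameters: depth 1e5, 10 replicates."""

    depth: int = 100_000
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.n_replicates < 1:
            raise ValueError("depth and n_replicates must be >= 1")


@dataclass(frozen=True)
class NormalizationSpec:
    """Log10 + pseudocount + Z score + back-transform parameters."""

    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class FeatureMatrix:
    """Replicate rows × named feature columns.

    Rows are labeled ``(donor, replicate_index)``. Used both for integer
    subsampled counts (:func:`build_replicate_matrix`) and for real-valued
    normalized or noise-perturbed matrices.
    """

    donors: tuple[str, ...]
    replicate_ids: tuple[int, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.donors)
        if len(self.replicate_ids) != n or self.values.shape != (n, len(self.feature_names)):
            raise ValueError("inconsistent row labels / value shape")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_arrays(
            [self.donors, self.replicate_ids], names=["donor_id", "replicate"]
        )
        return pd.DataFrame(self.values, index=index, columns=list(self.feature_names))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


#: Alias used where rows are guaranteed to be integer counts summing to depth.
ReplicateMatrix = FeatureMatrix


def subsample_replicates(
    counts: np.ndarray,
    spec: SubsampleSpec,
    donor_id: str = "donor",
) -> np.ndarray:
    """Draw ``spec.n_replicates`` multinomial resamples of one donor.

    Each replicate is a multinomial draw of size ``spec.depth`` with cell
    probabilities proportional to ``counts``; every row sums exactly to the
    depth. Returns an ``(n_replicates, n_features)`` integer array.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"donor {donor_id!r} has an all-zero count vector")
    probabilities = counts / total
    rng = _donor_rng(spec.seed, donor_id)
    return rng.multinomial(spec.depth, probabilities, size=spec.n_replicates)


def build_replicate_matrix(
    table: VJCountTable, spec: SubsampleSpec
) -> ReplicateMatrix:
    """Stack subsampled replicates for every donor of a count table."""
    blocks, donors, replicate_ids = [], [], []
    for donor_id in table.donor_ids:
        blocks.append(subsample_replicates(table.row(donor_id), spec, donor_id))
        donors.extend([donor_id] * spec.n_replicates)
        replicate_ids.extend(range(spec.n_replicates))
    return ReplicateMatrix(
        donors=tuple(donors),
        replicate_ids=tuple(replicate_ids),
        feature_names=table.feature_space.pairs,
        values=np.vstack(blocks),
    )


def zscore_normalize(
    matrix: FeatureMatrix, spec: NormalizationSpec | None = None
) -> FeatureMatrix:
    """Per-feature log10 / pseudocount / Z score / back-transform.

    For each feature column: zeros are replaced by the pseudocount, values
    are log10-transformed, Z-scored across rows (population standard
    deviation), and transformed back out of log space as ``10**Z``. A
    zero-variance column gets Z = 0 everywhere, i.e. output 1.
    """
    spec = spec or NormalizationSpec()
    if matrix.n_rows < 2:
        raise ValueError("normalization needs at least 2 rows")
    values = np.asarray(matrix.values, dtype=np.float64).copy()
    values[values == 0] = spec.pseudocount
    logs = np.log10(values)
    mean = logs.mean(axis=0)
    sd = logs.std(axis=0)  # population convention
    z = np.zeros_like(logs)
    nonzero = sd > 0
    z[:, nonzero] = (logs[:, nonzero] - mean[nonzero]) / sd[nonzero]
    return FeatureMatrix(
        donors=matrix.donors,
        replicate_ids=matrix.replicate_ids,
        feature_names=matrix.feature_names,
        values=10.0 ** z,
    )


@dataclass
class PCAModel:
    """Fitted principal components over a named feature space.

    ``loadings`` rows are orthonormal component directions; ratios are
    non-increasing and sum to at most 1.
    """

    feature_names: tuple[str, ...]
    mean: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)
    explained_variance_ratio: np.ndarray = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path: str | Path) -> None:
        document = {
            "format": "repfp-pca-model",
            "version": 1,
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        Path(path).write_text(json.dumps(document))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        document = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(document["feature_names"]),
            mean=np.asarray(document["mean"]),
            loadings=np.asarray(document["loadings"]),
            explained_variance_ratio=np.asarray(document["explained_variance_ratio"]),
        )


@dataclass
class Embedding:
    """Replicate coordinates in principal-component space."""

    donors: tuple[str, ...]
    replicate_ids: tuple[int, ...]
    coordinates: np.ndarray = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_arrays(
            [self.donors, self.replicate_ids], names=["donor_id", "replicate"]
        )
        columns = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.coordinates, index=index, columns=columns)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def fit_pca(matrix: FeatureMatrix, n_components: int = 2) -> PCAModel:
    """Fit PCA on a normalized matrix.

    Columns are centered; loadings and explained-variance ratios equal
    those of the eigendecomposition of the column covariance matrix, with
    components ordered by decreasing variance. A matrix with zero total
    variance (identical rows) yields all-zero ratios and a warning rather
    than an error, keeping toy inputs usable.
    """
    n_rows, n_features = matrix.values.shape
    if not 1 <= n_components <= min(n_rows - 1, n_features):
        raise ValueError(
            f"n_components={n_components} must be in [1, "
            f"min(rows - 1, features) = {min(n_rows - 1, n_features)}]"
        )
    values = np.asarray(matrix.values, dtype=np.float64)
    mean = values.mean(axis=0)
    total_variance = ((values - mean) ** 2).sum() / n_rows
    if total_variance <= 1e-300:
        warnings.warn(
            "matrix has zero total variance; PCA is degenerate "
            "(all explained-variance ratios reported as 0)",
            stacklevel=2,
        )
        loadings = np.eye(n_components, n_features)
        return PCAModel(
            feature_names=matrix.feature_names,
            mean=mean,
            loadings=loadings,
            explained_variance_ratio=np.zeros(n_components),
        )
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(values)
    return PCAModel(
        feature_names=matrix.feature_names,
        mean=model.mean_,
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def project(model: PCAModel, matrix: FeatureMatrix) -> Embedding:
    """Project a matrix into the model's component space."""
    if tuple(matrix.feature_names) != tuple(model.feature_names):
        missing = set(model.feature_names) - set(matrix.feature_names)
        extra = set(matrix.feature_names) - set(model.feature_names)
        raise ValueError(
            f"feature mismatch with PCA model; missing={sorted(missing)} "
            f"extra={sorted(extra)}"
        )
    coordinates = (np.asarray(matrix.values, dtype=np.float64) - model.mean) @ model.loadings.T
    return Embedding(
        donors=matrix.donors,
        replicate_ids=matrix.replicate_ids,
        coordinates=coordinates,
    )


def feature_weights(
    model: PCAModel, components: Sequence[int] = (0, 1)
) -> pd.DataFrame:
    """Loadings of the requested components, keyed by pair name.

    Sign convention: each component's largest-|weight| entry is made
    positive, so heat maps are comparable across runs. Columns ``PCk``
    hold the (sign-fixed) weights and ``PCk_rank`` the 1-based rank by
    absolute weight.
    """
    for c in components:
        if not 0 <= c < model.n_components:
            raise ValueError(f"component index {c} out of range [0, {model.n_components})")
    data: dict[str, np.ndarray] = {}
    for c in components:
        weights = model.loadings[c].copy()
        top = int(np.argmax(np.abs(weights)))
        if weights[top] < 0:
            weights = -weights
        order = np.argsort(-np.abs(weights), kind="stable")
        ranks = np.empty(len(weights), dtype=np.int64)
        ranks[order] = np.arange(1, len(weights) + 1)
        data[f"PC{c + 1}"] = weights
        data[f"PC{c + 1}_rank"] = ranks
    return pd.DataFrame(data, index=pd.Index(model.feature_names, name="vj_pair"))


@dataclass(frozen=True)
class ClusterSpec:
    """K-means parameters: k=2 on PC1+2 by default, 10 seeded restarts."""

    k: int = 2
    seed: int = 0
    n_init: int = 10
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_init < 1 or self.n_components < 1:
            raise ValueError("k, n_init and n_components must be >= 1")


@dataclass
class ClusterAssignment:
    """Per-row cluster labels, relabeled by centroid lexicographic order."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray = field(repr=False)


def kmeans_cluster(embedding: Embedding, spec: ClusterSpec | None = None) -> ClusterAssignment:
    """K-means on the leading components of an embedding.

    Best of ``spec.n_init`` k-means++ restarts by within-cluster sum of
    squares; labels are deterministic given the seed, with clusters
    renumbered by lexicographic order of their centroids.
    """
    spec = spec or ClusterSpec()
    points = embedding.coordinates[:, : spec.n_components]
    if points.shape[0] < spec.k:
        raise ValueError(f"{points.shape[0]} rows < k={spec.k}")
    model = KMeans(
        n_clusters=spec.k, n_init=spec.n_init, random_state=spec.seed
    ).fit(points)
    order = np.lexsort(model.cluster_centers_.T[::-1])
    relabel = np.empty(spec.k, dtype=np.int64)
    relabel[order] = np.arange(spec.k)
    return ClusterAssignment(
        labels=relabel[model.labels_],
        k=spec.k,
        centroids=model.cluster_centers_[order],
    )
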