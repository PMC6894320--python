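"""Cohort-level discrimination: PC distances, the RDI baseline, rank tests.

Donor-level summaries are the centroids of each donor's replicate cloud in
PC1+2. Pairwise Euclidean distances between centroids are split into
intra-cohort and inter-cohort groups, and a two-sided Mann-Whitney rank
test asks whether inter-cohort pairs are farther apart than intra-cohort
pairs. The Repertoire Dissimilarity Index (RDI) serves as the comparison
baseline: for each bootstrap iteration both donors' V-J count vectors are
resampled with replacement to a common depth, converted to frequencies,
and the Euclidean norm of their difference is averaged over iterations.

The Mann-Whitney p-value is exact (full enumeration over rank splits, ties
by mid-ranks) whenever the number of splits is small enough to enumerate;
otherwise the normal approximation with tie correction is used. At the
cohort sizes typical here (3 vs 5 donors, hence 3/10/15 pair groups) the
exact branch always applies; its two-sided floor for a 3-vs-15 comparison
is 2/816.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .fingerprint_core import Embedding

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RDISpec:
    """RDI bootstrap parameters: depth 1e5, 100 iterations."""

    depth: int = 100_000
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.n_boot < 1:
            raise ValueError("depth and n_boot must be >= 1")


@dataclass(frozen=True)
class DistanceRecord:
    """One unordered donor pair's distance under one metric."""

    donor_a: str
    donor_b: str
    group: str  # "intra_<cohort>" or "inter"
    metric: str  # "pc_euclidean" or "rdi"
    value: float


@dataclass(frozen=True)
class TestResult:
    """Two-sided Mann-Whitney rank-test outcome."""

    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" or "normal-approximation"


def donor_centroids(embedding: Embedding, n_components: int = 2) -> dict[str, np.ndarray]:
    """Mean of each donor's replicate coordinates over the leading components."""
    points = embedding.coordinates[:, :n_components]
    centroids: dict[str, np.ndarray] = {}
    for donor in dict.fromkeys(embedding.donors):  # preserve first-seen order
        mask = np.array([d == donor for d in embedding.donors])
        centroids[donor] = points[mask].mean(axis=0)
    return centroids


def _group_label(cohort_a: str, cohort_b: str) -> str:
    return f"intra_{cohort_a}" if cohort_a == cohort_b else "inter"


def pc_pairwise_distances(
    embedding: Embedding,
    cohorts: Mapping[str, str],
    n_components: int = 2,
) -> list[DistanceRecord]:
    """Euclidean distance in PC space between every unordered donor pair."""
    centroids = donor_centroids(embedding, n_components=n_components)
    donors = list(centroids)
    if len(donors) < 2:
        raise ValueError("need at least 2 donors for pairwise distances")
    missing = [d for d in donors if d not in cohorts]
    if missing:
        raise ValueError(f"donors missing a cohort label: {missing}")
    records = []
    for a, b in itertools.combinations(donors, 2):
        records.append(
            DistanceRecord(
                donor_a=a,
                donor_b=b,
                group=_group_label(cohorts[a], cohorts[b]),
                metric="pc_euclidean",
                value=float(np.linalg.norm(centroids[a] - centroids[b])),
            )
        )
    return records


def _rdi_rng(seed: int, own: bytes, other: bytes) -> np.random.Generator:
    # Stream keyed by the donor's own counts plus its rank within the pair,
    # so rdi(a, b) == rdi(b, a) exactly and a == b still uses two streams.
    rank = 0 if own <= other else 1
    key = zlib.crc32(own)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, rank)))


def compute_rdi(
    counts_a: np.ndarray, counts_b: np.ndarray, spec: RDISpec | None = None
) -> float:
    """Repertoire Dissimilarity Index between two V-J count vectors.

    Mean over bootstrap iterations of the Euclidean distance between the
    two donors' subsampled frequency vectors. This is the plain
    bootstrap-subsampling core of the index, without baseline subtraction
    or unit calibration. Symmetric in its arguments under the built-in
    seeding scheme.
    """
    spec = spec or RDISpec()
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("count vectors must share a feature space")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both count vectors must have a positive sum")
    bytes_a, bytes_b = a.tobytes(), b.tobytes()
    rng_a = _rdi_rng(spec.seed, bytes_a, bytes_b)
    rng_b = _rdi_rng(spec.seed, bytes_b, bytes_a)
    draws_a = rng_a.multinomial(spec.depth, a / a.sum(), size=spec.n_boot) / spec.depth
    draws_b = rng_b.multinomial(spec.depth, b / b.sum(), size=spec.n_boot) / spec.depth
    return float(np.linalg.norm(draws_a - draws_b, axis=1).mean())


def rdi_pairwise_distances(
    count_rows: Mapping[str, np.ndarray],
    cohorts: Mapping[str, str],
    spec: RDISpec | None = None,
) -> list[DistanceRecord]:
    """RDI between every unordered donor pair of a count table."""
    spec = spec or RDISpec()
    donors = list(count_rows)
    if len(donors) < 2:
        raise ValueError("need at least 2 donors for pairwise distances")
    missing = [d for d in donors if d not in cohorts]
    if missing:
        raise ValueError(f"donors missing a cohort label: {missing}")
    records = []
    for a, b in itertools.combinations(donors, 2):
        records.append(
            DistanceRecord(
                donor_a=a,
                donor_b=b,
                group=_group_label(cohorts[a], cohorts[b]),
                metric="rdi",
                value=compute_rdi(count_rows[a], count_rows[b], spec),
            )
        )
    return records


def split_intra_inter(
    records: Sequence[DistanceRecord],
) -> tuple[list[float], list[float], list[float]]:
    """Partition distance values into (intra first cohort, intra second, inter).

    Intra groups are ordered by lexicographic cohort label. All records
    must share one metric.
    """
    metrics = {r.metric for r in records}
    if len(metrics) > 1:
        raise ValueError(f"mixed metrics in distance records: {sorted(metrics)}")
    intra_labels = sorted({r.group for r in records if r.group != "inter"})
    if len(intra_labels) > 2:
        raise ValueError(f"more than two cohorts: {intra_labels}")
    first = [r.value for r in records if intra_labels and r.group == intra_labels[0]]
    second = [r.value for r in records if len(intra_labels) > 1 and r.group == intra_labels[1]]
    inter = [r.value for r in records if r.group == "inter"]
    return first, second, inter


def _rank_sum_u(ranks: np.ndarray, n1: int) -> float:
    return float(ranks.sum() - n1 * (n1 + 1) / 2)


def mann_whitney_two_sided(
    x: Sequence[float],
    y: Sequence[float],
    max_enumeration: int = 1_000_000,
) -> TestResult:
    """Two-sided Mann-Whitney rank test.

    Exact when ``C(n1 + n2, n1) <= max_enumeration``: the p-value is found
    by enumerating every assignment of pooled mid-ranks to the first group
    and counting U statistics at least as extreme as observed, two-sided
    as ``min(1, 2 * one-sided)``. Larger samples fall back to the normal
    approximation with tie correction.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.asarray(x + y)
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    u_obs = _rank_sum_u(ranks[:n1], n1)

    if math.comb(n1 + n2, n1) <= max_enumeration:
        eps = 1e-9
        n_le = n_ge = 0
        total = 0
        for subset in itertools.combinations(range(n1 + n2), n1):
            u = _rank_sum_u(ranks[list(subset)], n1)
            total += 1
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return TestResult(
            u_statistic=u_obs, p_two_sided=p, n1=n1, n2=n2, method="exact"
        )

    result = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(
        u_statistic=float(result.statistic),
        p_two_sided=float(result.pvalue),
        n1=n1,
        n2=n2,
        method="normal-approximation",
    )


def intra_vs_inter_tests(
    records: Sequence[DistanceRecord],
) -> dict[str, TestResult]:
    """Each intra-cohort distance group tested against the inter group."""
    metrics = {r.metric for r in records}
    if len(metrics) != 1:
        raise ValueError("records must share one metric")
    intra_labels = sorted({r.group for r in records if r.group != "inter"})
    inter = [r.value for r in records if r.group == "inter"]
    if not inter:
        raise ValueError("no inter-cohort pairs (single-cohort input?)")
    tests = {}
    for label in intra_labels:
        intra = [r.value for r in records if r.group == label]
        tests[f"{label}_vs_inter"] = mann_whitney_two_sided(intra, inter)
    return tests


def separation_ratio(records: Sequence[DistanceRecord]) -> float:
    """Median inter-cohort distance divided by median intra-cohort distance."""
    first, second, inter = split_intra_inter(records)
    intra = first + second
    if not intra or not inter:
        raise ValueError("need both intra and inter pairs")
    return float(np.median(inter) / np.median(intra))
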