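"""Synthetic two-cohort repertoire studies for offline pipeline testing.

Donor V-J usage is generated from a Dirichlet-multinomial hierarchy: each
cohort has a baseline usage profile over the V-J pair space; a cohort
effect multiplies selected profile entries by ``(1 + effect_size)`` and
renormalizes; each donor's personal profile is a Dirichlet draw around the
cohort profile with a concentration controlling inter-donor spread; and
the donor's unique-clonotype counts are a multinomial draw from that
profile. This is the minimal model reproducing the structure the pipeline
assumes — replicates cluster by donor, donors cluster by cohort — without
simulating somatic hypermutation, lineages, or read-level error.

The default feature space is the Cartesian product of 51 functional human
IGHV gene names with IGHJ1-6, i.e. 306 V-J pairs. The default baseline is
a fixed heavy-tailed (log-normal) profile, mimicking the strongly skewed
germline gene usage of real heavy-chain repertoires; the default cohort
effect perturbs the 20 most-used pairs, since highly expressed genes are
where cohort differences are observed. CDR3 amino-acid sequences are
drawn with normally distributed lengths clipped to [4, 30] and letters
from a tunable composition, which feeds the alternate-feature control and
AIRR-format output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clonotype_io import AA_LETTERS, FeatureSpace, VJCountTable

logger = logging.getLogger(__name__)

# 51 functional human germline IGHV genes; with IGHJ1-6 this yields the
# 306-pair default space.
IGHV_GENES = (
    "IGHV1-2", "IGHV1-3", "IGHV1-8", "IGHV1-18", "IGHV1-24",
    "IGHV1-45", "IGHV1-46", "IGHV1-58", "IGHV1-69", "IGHV1-69-2",
    "IGHV2-5", "IGHV2-26", "IGHV2-70",
    "IGHV3-7", "IGHV3-9", "IGHV3-11", "IGHV3-13", "IGHV3-15",
    "IGHV3-20", "IGHV3-21", "IGHV3-23", "IGHV3-30", "IGHV3-30-3",
    "IGHV3-30-5", "IGHV3-33", "IGHV3-35", "IGHV3-38", "IGHV3-43",
    "IGHV3-48", "IGHV3-49", "IGHV3-53", "IGHV3-64", "IGHV3-66",
    "IGHV3-72", "IGHV3-73", "IGHV3-74",
    "IGHV4-4", "IGHV4-28", "IGHV4-30-1", "IGHV4-30-2", "IGHV4-30-4",
    "IGHV4-31", "IGHV4-34", "IGHV4-38-2", "IGHV4-39", "IGHV4-59",
    "IGHV4-61",
    "IGHV5-10-1", "IGHV5-51",
    "IGHV6-1",
    "IGHV7-4-1",
)
IGHJ_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")

# Internal seed fixing the *shape* of the default baseline profile; the
# profile is a study parameter, not a random variable of a given run.
_BASELINE_SEED = 306


def default_feature_space() -> FeatureSpace:
    """The 306-pair V-J space: 51 IGHV genes x 6 IGHJ genes."""
    return FeatureSpace(
        pairs=tuple(f"{v}_{j}" for v in IGHV_GENES for j in IGHJ_GENES)
    )


def default_baseline_profile(
    n_features: int = 306, min_probability: float = 2e-4
) -> np.ndarray:
    """Fixed heavy-tailed usage profile (log-normal weights, normalized).

    The floor on per-pair probability emulates restricting the analysis to
    *common* V-J pairs: every pair in the space is expected tens of times
    at the default subsampling depth, so no column of the replicate matrix
    is dominated by zero/nonzero flips.
    """
    rng = np.random.default_rng(_BASELINE_SEED)
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=n_features)
    profile = weights / weights.sum()
    profile = np.maximum(profile, min_probability)
    return profile / profile.sum()


@dataclass
class CohortSpec:
    """Generative parameters for one cohort.

    ``effect_size`` (delta) multiplies the ``effect_features`` entries of
    the baseline profile by (1 + delta) before renormalization, so any
    delta >= 0 yields a valid profile. ``donor_concentration`` is the
    Dirichlet concentration: larger values pull donors tighter around the
    cohort profile (variance of each entry scales as 1/concentration).
    """

    label: str
    n_donors: int
    baseline_profile: np.ndarray = field(repr=False)
    donor_concentration: float = 100_000.0
    effect_features: tuple[int, ...] = ()
    effect_size: float = 0.0
    clonotypes_per_donor: int = 100_000

    def __post_init__(self) -> None:
        self.baseline_profile = np.asarray(self.baseline_profile, dtype=np.float64)
        if not np.isclose(self.baseline_profile.sum(), 1.0, atol=1e-9):
            raise ValueError("baseline_profile must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_donors < 1 or self.clonotypes_per_donor < 1:
            raise ValueError("n_donors and clonotypes_per_donor must be >= 1")
        if self.donor_concentration <= 0:
            raise ValueError("donor_concentration must be > 0")
        bad = [i for i in self.effect_features if not 0 <= i < self.baseline_profile.size]
        if bad:
            raise ValueError(f"effect feature indices out of range: {bad}")

    @property
    def cohort_profile(self) -> np.ndarray:
        """Baseline with the multiplicative cohort effect applied."""
        profile = self.baseline_profile.copy()
        if self.effect_features:
            profile[list(self.effect_features)] *= 1.0 + self.effect_size
            profile /= profile.sum()
        return profile


def sample_donor_profile(cohort: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw around the cohort profile.

    Alpha = concentration * cohort profile, so the draw's mean is the
    cohort profile and its spread shrinks as concentration grows.
    """
    alpha = cohort.donor_concentration * cohort.cohort_profile
    profile = rng.dirichlet(alpha)
    return profile / profile.sum()


def sample_donor_counts(
    profile: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw of n unique clonotypes over the V-J pair space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.multinomial(n, np.asarray(profile) / np.sum(profile))


def generate_cdr3_set(
    n: int,
    rng: np.random.Generator,
    length_mean: float = 15.0,
    length_sd: float = 3.0,
    aa_weights: np.ndarray | None = None,
    length_min: int = 4,
    length_max: int = 30,
) -> list[str]:
    """Draw n distinct CDR3 amino-acid strings.

    Lengths come from a discretized normal clipped to [length_min,
    length_max]; letters are drawn i.i.d. from ``aa_weights`` over the 20
    standard amino acids (uniform by default). Duplicates are rejected and
    redrawn; if n exceeds the number of distinct sequences expressible
    under the weights a ValueError is raised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if aa_weights is None:
        weights = np.full(20, 1.0 / 20)
    else:
        weights = np.asarray(aa_weights, dtype=np.float64)
        if weights.size != 20 or (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("aa_weights must be 20 nonnegative values with a positive sum")
        weights = weights / weights.sum()
    letters = np.array(list(AA_LETTERS))
    usable = int((weights > 0).sum())

    if length_sd == 0:
        lengths_possible = [int(np.clip(round(length_mean), length_min, length_max))]
    else:
        lengths_possible = list(range(length_min, length_max + 1))
    capacity = sum(float(usable) ** L for L in lengths_possible)
    if n > capacity:
        raise ValueError(
            f"requested {n} distinct sequences but only {capacity:.0f} are expressible"
        )

    # dict-as-ordered-set: insertion order is deterministic, unlike set
    # iteration under hash randomization
    sequences: dict[str, None] = {}
    attempts = 0
    max_attempts = 50 * n + 1000
    while len(sequences) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not draw {n} distinct CDR3s in {max_attempts} attempts"
            )
        batch = n - len(sequences)
        if length_sd == 0:
            lengths = np.full(batch, lengths_possible[0])
        else:
            raw = rng.normal(length_mean, length_sd, size=batch)
            lengths = np.clip(np.rint(raw), length_min, length_max).astype(int)
        for L in lengths:
            seq = "".join(rng.choice(letters, size=int(L), p=weights))
            sequences[seq] = None
            attempts += 1
    return list(sequences)[:n]


@dataclass
class SyntheticStudy:
    """A generated multi-donor study: counts, labels, and full provenance."""

    feature_space: FeatureSpace
    donor_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)
    cohorts: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    @property
    def count_table(self) -> VJCountTable:
        return VJCountTable(
            donor_ids=self.donor_ids,
            feature_space=self.feature_space,
            counts=self.counts,
        )

    def write_manifest(self, path: str | Path) -> None:
        pd.DataFrame(
            {"donor_id": list(self.donor_ids),
             "cohort": [self.cohorts[d] for d in self.donor_ids]}
        ).to_csv(path, sep="\t", index=False)

    def write_params(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.params, indent=2))


def _cohort_params(spec: CohortSpec) -> dict:
    params = asdict(spec)
    params["baseline_profile"] = "omitted (see generator defaults)"
    params["effect_features"] = list(spec.effect_features)
    return params


def generate_study(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate per-donor V-J counts for a two-cohort study.

    Bit-for-bit reproducible from (specs, seed). Donors are labeled
    ``<cohort>_<i>``; each donor's profile and counts come from an
    independent child stream of the study seed.
    """
    if spec_a.baseline_profile.size != spec_b.baseline_profile.size:
        raise ValueError("cohorts must share a feature space")
    n_features = spec_a.baseline_profile.size
    space = default_feature_space() if n_features == 306 else FeatureSpace(
        pairs=tuple(f"V{i}_J" for i in range(n_features))
    )
    donor_ids: list[str] = []
    cohorts: dict[str, str] = {}
    rows = []
    donor_index = 0
    for spec in (spec_a, spec_b):
        for i in range(spec.n_donors):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(donor_index,))
            )
            profile = sample_donor_profile(spec, rng)
            rows.append(sample_donor_counts(profile, spec.clonotypes_per_donor, rng))
            donor_id = f"{spec.label}_{i + 1}"
            donor_ids.append(donor_id)
            cohorts[donor_id] = spec.label
            donor_index += 1
    return SyntheticStudy(
        feature_space=space,
        donor_ids=tuple(donor_ids),
        counts=np.vstack(rows),
        cohorts=cohorts,
        seed=seed,
        params={
            "seed": seed,
            "cohort_a": _cohort_params(spec_a),
            "cohort_b": _cohort_params(spec_b),
        },
    )


def default_study_specs(
    effect_size: float = 1.0,
    n_effect_features: int = 20,
    n_donors_a: int = 3,
    n_donors_b: int = 5,
    donor_concentration: float = 100_000.0,
    clonotypes_per_donor: int = 100_000,
    label_a: str = "healthy",
    label_b: str = "exposed",
) -> tuple[CohortSpec, CohortSpec]:
    """Study shape mirroring a 3-vs-5-donor, 306-feature comparison.

    The cohort effect lands on the ``n_effect_features`` most-used pairs
    of the shared baseline (cohort B only).
    """
    baseline = default_baseline_profile()
    effect = tuple(np.argsort(-baseline)[:n_effect_features].tolist())
    common = dict(
        baseline_profile=baseline,
        donor_concentration=donor_concentration,
        clonotypes_per_donor=clonotypes_per_donor,
    )
    return (
        CohortSpec(label=label_a, n_donors=n_donors_a, **common),
        CohortSpec(
            label=label_b,
            n_donors=n_donors_b,
            effect_features=effect,
            effect_size=effect_size,
            **common,
        ),
    )


def write_airr_tsv(
    study: SyntheticStudy,
    out_dir: str | Path,
    seed: int | None = None,
    length_mean: float = 15.0,
    length_sd: float = 3.0,
    aa_weights: np.ndarray | None = None,
) -> list[Path]:
    """Emit one AIRR Rearrangement TSV per donor.

    Each clonotype count becomes that many rows sharing the V/J calls
    (with an allele suffix, exercising allele stripping downstream) and
    carrying distinct CDR3s, so re-ingestion through the reader and the
    quality filters reproduces the study's count table exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = study.seed if seed is None else seed
    paths = []
    for d, donor_id in enumerate(study.donor_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1_000_000 + d,))
        )
        counts = study.counts[d]
        rows = []
        for i, pair in enumerate(study.feature_space.pairs):
            c = int(counts[i])
            if c == 0:
                continue
            v_gene, j_gene = pair.rsplit("_", 1)
            for cdr3 in generate_cdr3_set(
                c, rng, length_mean=length_mean, length_sd=length_sd,
                aa_weights=aa_weights,
            ):
                rows.append(
                    {
                        "sequence_id": f"{donor_id}_{len(rows) + 1}",
                        "v_call": f"{v_gene}*01",
                        "j_call": f"{j_gene}*01",
                        "junction_aa": cdr3,
                        "v_support": 1e-30,
                        "j_support": 1e-30,
                        "productive": "T",
                        "vj_in_frame": "T",
                        "stop_codon": "F",
                    }
                )
        path = out_dir / f"{donor_id}.airr.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths.append(path)
        logger.info("wrote %d rearrangements for donor %s to %s", len(rows), donor_id, path)
    return paths
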