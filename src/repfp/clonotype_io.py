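"""Ingestion of annotated heavy-chain rearrangement tables.

Reads AIRR Rearrangement TSV files, applies record-level quality filters
(germline alignment E-value, frame, productivity, stop codons, presence of a
CDR3), collapses the surviving rows to unique V3J clonotypes — a (V gene,
J gene, CDRH3 amino-acid sequence) triple — and tabulates V-J gene-pair
counts over a fixed, ordered feature space.

Counting is done in units of unique clonotypes, never reads: two reads with
the same germline genes and the same CDRH3 amino-acid sequence contribute a
single clonotype.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids; '*' marks an in-sequence stop codon.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_CDR3_ALPHABET = frozenset(AA_LETTERS + "*")

#: Default AIRR Rearrangement column names. ``cdr3_aa`` falls back to
#: ``junction_aa`` when the former is absent.
DEFAULT_COLUMNS: dict[str, str] = {
    "v_call": "v_call",
    "j_call": "j_call",
    "cdr3_aa": "cdr3_aa",
    "cdr3_fallback": "junction_aa",
    "v_evalue": "v_support",
    "j_evalue": "j_support",
    "productive": "productive",
    "in_frame": "vj_in_frame",
    "stop_codon": "stop_codon",
}


class FormatError(ValueError):
    """A rearrangement table is missing a required column."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One annotated rearrangement row.

    Boolean flags are ``None`` when the source table lacked the column;
    filtering treats a missing flag as passing (permissive default for
    heterogeneous AIRR dialects).
    """

    donor_id: str
    v_call: str
    j_call: str
    cdr3_aa: str | None
    v_evalue: float | None = None
    j_evalue: float | None = None
    in_frame: bool | None = None
    productive: bool | None = None
    has_stop_codon: bool | None = None


@dataclass(frozen=True)
class FilterSpec:
    """Record-level quality criteria.

    Defaults follow the standard annotation-pipeline filters: germline
    alignment E-value below 1e-6 for both V and J, in-frame junction,
    productive rearrangement, no stop codons, and a defined CDR3.
    """

    max_evalue: float = 1e-6
    require_in_frame: bool = True
    require_productive: bool = True
    reject_stop_codons: bool = True
    require_cdr3: bool = True

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError(f"max_evalue must be > 0, got {self.max_evalue}")


@dataclass(frozen=True, order=True)
class V3JClonotype:
    """A unique (V gene, J gene, CDRH3) triple; the unit of counting."""

    v_gene: str
    j_gene: str
    cdr3_aa: str

    @property
    def pair_name(self) -> str:
        return f"{self.v_gene}_{self.j_gene}"


@dataclass
class Repertoire:
    """A donor's set of unique V3J clonotypes."""

    donor_id: str
    clonotypes: frozenset[V3JClonotype]
    cohort: str | None = None

    def __len__(self) -> int:
        return len(self.clonotypes)


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered list of V-J pair names ("Vgene_Jgene") defining matrix columns."""

    pairs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            dupes = [p for p, c in Counter(self.pairs).items() if c > 1]
            raise ValueError(f"duplicate pair names in feature space: {dupes}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.pairs)}

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureSpace":
        pairs = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        return cls(pairs=tuple(pairs))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.pairs) + "\n")


def _parse_bool(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in {"t", "true", "1", "yes", "y"}:
        return True
    if text in {"f", "false", "0", "no", "n"}:
        return False
    if text in {"", "na", "nan", "none"}:
        return None
    raise ValueError(f"unparseable boolean value: {value!r}")


def _parse_float(value: object) -> float | None:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None
    return float(text)


def read_rearrangement_table(
    path: str | Path,
    donor_id: str,
    columns: Mapping[str, str] | None = None,
) -> list[ClonotypeRecord]:
    """Read an AIRR Rearrangement TSV into :class:`ClonotypeRecord` rows.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    donor_id:
        Label attached to every record.
    columns:
        Overrides for :data:`DEFAULT_COLUMNS` (e.g. a pipeline that writes
        ``v_identity_evalue`` instead of ``v_support``).

    Raises
    ------
    FormatError
        If the v_call, j_call, or CDR3 column is missing.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    frame = pd.read_csv(path, sep="\t", dtype=str)

    for key in ("v_call", "j_call"):
        if cols[key] not in frame.columns:
            raise FormatError(f"required column {cols[key]!r} missing from {path}")
    cdr3_col = cols["cdr3_aa"]
    if cdr3_col not in frame.columns:
        cdr3_col = cols["cdr3_fallback"]
        if cdr3_col not in frame.columns:
            raise FormatError(
                f"no CDR3 column ({cols['cdr3_aa']!r} or "
                f"{cols['cdr3_fallback']!r}) in {path}"
            )

    optional = {
        "v_evalue": cols["v_evalue"],
        "j_evalue": cols["j_evalue"],
        "in_frame": cols["in_frame"],
        "productive": cols["productive"],
        "stop_codon": cols["stop_codon"],
    }
    for key, col in optional.items():
        if col not in frame.columns:
            logger.warning(
                "column %r absent from %s; records treated as passing the "
                "%s criterion",
                col, path, key,
            )

    def _get(row: pd.Series, col: str) -> object:
        return row[col] if col in frame.columns else None

    records: list[ClonotypeRecord] = []
    for _, row in frame.iterrows():
        cdr3 = row[cdr3_col]
        cdr3 = None if pd.isna(cdr3) or str(cdr3).strip() == "" else str(cdr3).strip()
        records.append(
            ClonotypeRecord(
                donor_id=donor_id,
                v_call=str(row[cols["v_call"]]),
                j_call=str(row[cols["j_call"]]),
                cdr3_aa=cdr3,
                v_evalue=_parse_float(_get(row, optional["v_evalue"])),
                j_evalue=_parse_float(_get(row, optional["j_evalue"])),
                in_frame=_parse_bool(_get(row, optional["in_frame"])),
                productive=_parse_bool(_get(row, optional["productive"])),
                has_stop_codon=_parse_bool(_get(row, optional["stop_codon"])),
            )
        )
    logger.info("parsed %d records from %s (donor %s)", len(records), path, donor_id)
    return records


def _passes(record: ClonotypeRecord, spec: FilterSpec) -> str | None:
    """Return the name of the first violated criterion, or None if passing."""
    if record.v_evalue is not None and not record.v_evalue < spec.max_evalue:
        return "v_evalue"
    if record.j_evalue is not None and not record.j_evalue < spec.max_evalue:
        return "j_evalue"
    if spec.require_in_frame and record.in_frame is False:
        return "in_frame"
    if spec.require_productive and record.productive is False:
        return "productive"
    if spec.reject_stop_codons:
        if record.has_stop_codon is True:
            return "stop_codon"
        if record.cdr3_aa is not None and "*" in record.cdr3_aa:
            return "stop_codon"
    if spec.require_cdr3 and (record.cdr3_aa is None or record.cdr3_aa == ""):
        return "cdr3_missing"
    return None


def apply_quality_filters(
    records: Sequence[ClonotypeRecord],
    spec: FilterSpec | None = None,
) -> list[ClonotypeRecord]:
    """Retain records passing every enabled criterion.

    E-value criteria are strict: the alignment support must be strictly
    below ``spec.max_evalue`` for both V and J. Per-criterion rejection
    counts are logged. Filtering is idempotent.
    """
    spec = spec or FilterSpec()
    kept: list[ClonotypeRecord] = []
    rejections: Counter[str] = Counter()
    for record in records:
        reason = _passes(record, spec)
        if reason is None:
            kept.append(record)
        else:
            rejections[reason] += 1
    logger.info(
        "quality filters: %d/%d records kept; rejections: %s",
        len(kept), len(records), dict(rejections) or "none",
    )
    return kept


def strip_allele(gene_call: str) -> str:
    """Collapse a germline gene call to the gene level.

    Drops the allele suffix (everything from the first ``'*'``) and resolves
    multi-assignment calls (comma-separated) to the first listed call.

    >>> strip_allele("IGHV1-2*02")
    'IGHV1-2'
    >>> strip_allele("IGHV3-30*18,IGHV3-30-5*01")
    'IGHV3-30'
    """
    if gene_call is None or not gene_call.strip():
        raise ValueError("empty gene call")
    first = gene_call.split(",")[0].strip()
    gene = first.split("*")[0].strip()
    if not gene:
        raise ValueError(f"gene call {gene_call!r} reduces to an empty name")
    return gene


def extract_v3j_clonotypes(
    records: Sequence[ClonotypeRecord],
    donor_id: str | None = None,
    cohort: str | None = None,
) -> Repertoire:
    """Collapse filtered records to a donor's unique V3J clonotypes.

    Gene calls are allele-stripped and CDR3s upper-cased before
    deduplication, so records differing only in allele collapse together.
    """
    if donor_id is None:
        donor_id = records[0].donor_id if records else "unknown"
    clonotypes = set()
    for record in records:
        if record.cdr3_aa is None:
            continue
        clonotypes.add(
            V3JClonotype(
                v_gene=strip_allele(record.v_call),
                j_gene=strip_allele(record.j_call),
                cdr3_aa=record.cdr3_aa.upper(),
            )
        )
    logger.info(
        "donor %s: %d records collapsed to %d unique V3J clonotypes",
        donor_id, len(records), len(clonotypes),
    )
    return Repertoire(donor_id=donor_id, clonotypes=frozenset(clonotypes), cohort=cohort)


def count_vj_pairs(
    repertoire: Repertoire, space: FeatureSpace
) -> tuple[np.ndarray, int]:
    """Tally unique clonotypes per V-J pair over a feature space.

    Returns ``(counts, n_excluded)`` where ``counts[i]`` is the number of
    unique clonotypes whose pair equals ``space.pairs[i]`` and
    ``n_excluded`` is the number of clonotypes whose pair lies outside the
    space (dropped, mirroring a fixed common-pair design).
    """
    if len(space) == 0:
        raise ValueError("feature space is empty")
    index = space.index
    counts = np.zeros(len(space), dtype=np.int64)
    excluded = 0
    for clonotype in repertoire.clonotypes:
        i = index.get(clonotype.pair_name)
        if i is None:
            excluded += 1
        else:
            counts[i] += 1
    if excluded:
        logger.info(
            "donor %s: %d clonotypes outside the feature space excluded",
            repertoire.donor_id, excluded,
        )
    return counts, excluded


def build_feature_space(
    source: Iterable[Repertoire] | str | Path,
    mode: str = "union",
) -> FeatureSpace:
    """Build the ordered V-J pair feature space.

    ``mode='from_file'`` reads one pair name per line, preserving file
    order; ``'union'`` / ``'intersection'`` combine the pair sets of the
    given repertoires and sort lexicographically for determinism.
    """
    if mode == "from_file":
        space = FeatureSpace.from_file(source)  # type: ignore[arg-type]
        if len(space) == 0:
            raise ValueError(f"feature-space file {source} is empty")
        return space
    if mode not in {"union", "intersection"}:
        raise ValueError(f"unknown mode {mode!r}")
    pair_sets = [
        {c.pair_name for c in repertoire.clonotypes} for repertoire in source  # type: ignore[union-attr]
    ]
    if not pair_sets:
        raise ValueError("no repertoires given")
    if mode == "union":
        pairs = set().union(*pair_sets)
    else:
        pairs = set.intersection(*pair_sets)
    if not pairs:
        raise ValueError(f"{mode} of donor pair sets is empty")
    return FeatureSpace(pairs=tuple(sorted(pairs)))


@dataclass
class VJCountTable:
    """Donors × V-J pairs matrix of unique-clonotype counts."""

    donor_ids: tuple[str, ...]
    feature_space: FeatureSpace
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.donor_ids), len(self.feature_space)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.donor_ids)} donors x {len(self.feature_space)} pairs"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_repertoires(
        cls, repertoires: Sequence[Repertoire], space: FeatureSpace
    ) -> "VJCountTable":
        rows = [count_vj_pairs(r, space)[0] for r in repertoires]
        return cls(
            donor_ids=tuple(r.donor_id for r in repertoires),
            feature_space=space,
            counts=np.vstack(rows),
        )

    def row(self, donor_id: str) -> np.ndarray:
        return self.counts[self.donor_ids.index(donor_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.donor_ids, name="donor_id"),
            columns=list(self.feature_space.pairs),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VJCountTable":
        frame = pd.read_csv(path, sep="\t", index_col="donor_id")
        return cls(
            donor_ids=tuple(frame.index.astype(str)),
            feature_space=FeatureSpace(pairs=tuple(frame.columns)),
            counts=frame.to_numpy(dtype=np.int64),
        )
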