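"""Per-read, per-rank truth comparison: the five-way status scheme.

Every (read, rank) pair receives exactly one status:

* ``truth_unknown`` — the read's source genome has no taxonomic label at
  this rank, so correctness is undefined here regardless of what the
  classifier did.
* ``unclassified_at_any_level`` — the read received no classification at
  all (taxid 0).
* ``unclassified_at_this_level`` — the read was assigned a taxon whose
  lineage has no label at this rank (it was classified elsewhere in the
  hierarchy).
* ``correct`` / ``incorrect`` — the assigned taxon's ancestor at this rank
  equals / differs from the truth taxon's ancestor at this rank.

The cascade is evaluated in that order; in particular the truth side takes
priority over the classifier side, since a read without a truth label can
never be scored for correctness.  Percentages are always over *all*
simulated reads, so the five statuses sum to 100 per rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import TaxonomyDB

__all__ = [
    "ReadStatus",
    "EvaluationSummary",
    "TaxonSetComparison",
    "OverlapCounts",
    "DEFAULT_EVAL_RANKS",
    "assign_status",
    "evaluate",
    "taxon_set_comparison",
    "collection_overlap",
]

#: Ranks at which read-level accuracy is reported.
DEFAULT_EVAL_RANKS: tuple[str, ...] = ("phylum", "family", "genus", "species")


class ReadStatus(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    UNCLASSIFIED_AT_THIS_LEVEL = "unclassified_at_this_level"
    UNCLASSIFIED_AT_ANY_LEVEL = "unclassified_at_any_level"
    TRUTH_UNKNOWN = "truth_unknown"


def assign_status(
    truth_taxid: int,
    assigned_taxid: int | None,
    rank: str,
    db: TaxonomyDB,
) -> ReadStatus:
    """Status of one read at one rank; ``assigned_taxid`` of 0 or None
    means unclassified."""
    truth_anc = db.rank_ancestor(truth_taxid, rank)
    if truth_anc is None:
        return ReadStatus.TRUTH_UNKNOWN
    if assigned_taxid is None or assigned_taxid == 0:
        return ReadStatus.UNCLASSIFIED_AT_ANY_LEVEL
    assigned_anc = db.rank_ancestor(assigned_taxid, rank)
    if assigned_anc is None:
        return ReadStatus.UNCLASSIFIED_AT_THIS_LEVEL
    if assigned_anc == truth_anc:
        return ReadStatus.CORRECT
    return ReadStatus.INCORRECT


@dataclass
class EvaluationSummary:
    """Per-rank status percentages plus classification rates.

    ``status_percent[rank][status]`` sums to 100 over the five statuses at
    every rank.  ``classified_pct[rank]`` uses classification-rate
    semantics: the percentage of reads assigned a taxid whose lineage has a
    label at that rank, regardless of correctness; ``overall_classified_pct``
    is the percentage of reads assigned any taxid at all.
    """

    n_reads: int
    ranks: tuple[str, ...]
    status_percent: dict[str, dict[ReadStatus, float]]
    status_count: dict[str, dict[ReadStatus, int]]
    classified_pct: dict[str, float]
    unclassified_pct: dict[str, float]
    overall_classified_pct: float

    def to_frame(self) -> pd.DataFrame:
        """Long-form (rank, status, percent) table."""
        rows = [
            {"rank": rank, "status": status.value,
             "percent": self.status_percent[rank][status],
             "count": self.status_count[rank][status]}
            for rank in self.ranks
            for status in ReadStatus
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "overall_classified_pct": self.overall_classified_pct,
            "ranks": {
                rank: {
                    "status_percent": {
                        s.value: self.status_percent[rank][s] for s in ReadStatus
                    },
                    "classified_pct": self.classified_pct[rank],
                    "unclassified_pct": self.unclassified_pct[rank],
                }
                for rank in self.ranks
            },
        }


def evaluate(
    truth: pd.DataFrame,
    classified: pd.DataFrame,
    db: TaxonomyDB,
    ranks: Sequence[str] = DEFAULT_EVAL_RANKS,
) -> EvaluationSummary:
    """Score a classification table against its ground truth.

    Both tables need ``read_id`` and ``taxid`` columns; the truth must be
    total (every classified read present in the truth and vice versa —
    missing reads on either side are a hard error, surfacing harness bugs
    rather than silently treating absences as unclassified).
    """
    truth_ids = set(truth["read_id"])
    class_ids = set(classified["read_id"])
    if len(truth_ids) != len(truth):
        raise ValueError("duplicate read_ids in truth table")
    extra = class_ids - truth_ids
    if extra:
        raise ValueError(
            "classified reads absent from ground truth: "
            + ", ".join(sorted(extra)[:5])
            + ("..." if len(extra) > 5 else "")
        )
    missing = truth_ids - class_ids
    if missing:
        raise ValueError(
            "truth reads missing from classification table: "
            + ", ".join(sorted(missing)[:5])
            + ("..." if len(missing) > 5 else "")
        )

    merged = truth.merge(
        classified, on="read_id", suffixes=("_truth", "_assigned")
    )
    n = len(merged)
    truth_col = merged["taxid_truth"].to_numpy()
    assigned_col = merged["taxid_assigned"].to_numpy()

    for taxid in pd.unique(merged["taxid_truth"]):
        db[int(taxid)]  # raises on unknown taxid
    for taxid in pd.unique(merged["taxid_assigned"]):
        if taxid != 0:
            db[int(taxid)]

    status_percent: dict[str, dict[ReadStatus, float]] = {}
    status_count: dict[str, dict[ReadStatus, int]] = {}
    classified_pct: dict[str, float] = {}
    unclassified_pct: dict[str, float] = {}
    for rank in ranks:
        # Ancestor lookups cached per distinct taxid; the read loop is then
        # pure dictionary work.
        anc: dict[int, int | None] = {0: None}
        for taxid in set(truth_col) | set(assigned_col):
            if taxid != 0:
                anc[int(taxid)] = db.rank_ancestor(int(taxid), rank)
        counts = {status: 0 for status in ReadStatus}
        classified_at_rank = 0
        for t, a in zip(truth_col, assigned_col):
            t_anc = anc[int(t)]
            a_anc = anc[int(a)]
            if a != 0 and a_anc is not None:
                classified_at_rank += 1
            if t_anc is None:
                counts[ReadStatus.TRUTH_UNKNOWN] += 1
            elif a == 0:
                counts[ReadStatus.UNCLASSIFIED_AT_ANY_LEVEL] += 1
            elif a_anc is None:
                counts[ReadStatus.UNCLASSIFIED_AT_THIS_LEVEL] += 1
            elif a_anc == t_anc:
                counts[ReadStatus.CORRECT] += 1
            else:
                counts[ReadStatus.INCORRECT] += 1
        status_count[rank] = counts
        status_percent[rank] = {
            status: 100.0 * c / n for status, c in counts.items()
        }
        classified_pct[rank] = 100.0 * classified_at_rank / n
        unclassified_pct[rank] = 100.0 - classified_pct[rank]

    overall = 100.0 * (assigned_col != 0).sum() / n
    return EvaluationSummary(
        n_reads=n,
        ranks=tuple(ranks),
        status_percent=status_percent,
        status_count=status_count,
        classified_pct=classified_pct,
        unclassified_pct=unclassified_pct,
        overall_classified_pct=float(overall),
    )


@dataclass(frozen=True)
class TaxonSetComparison:
    """Taxa spuriously present in (FP) or absent from (FN) a classification."""

    rank: str
    false_positive_taxa: frozenset[int]
    false_negative_taxa: frozenset[int]

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positive_taxa)

    @property
    def n_false_negatives(self) -> int:
        return len(self.false_negative_taxa)


def taxon_set_comparison(
    truth_counts: Mapping[int, int],
    classified_counts: Mapping[int, int],
    rank: str,
    classified_rank: str | None = None,
) -> TaxonSetComparison:
    """False-positive / false-negative taxa between two per-rank count maps.

    A false positive is a taxon with classified reads but no truth reads; a
    false negative has truth reads but no classified reads.  When the count
    maps come from tables that carry their own rank, pass both ranks so a
    mismatch is caught.
    """
    if classified_rank is not None and classified_rank != rank:
        raise ValueError(
            f"rank mismatch: truth at {rank!r}, classified at {classified_rank!r}"
        )
    truth_present = {t for t, c in truth_counts.items() if c > 0}
    class_present = {t for t, c in classified_counts.items() if c > 0}
    return TaxonSetComparison(
        rank=rank,
        false_positive_taxa=frozenset(class_present - truth_present),
        false_negative_taxa=frozenset(truth_present - class_present),
    )


@dataclass(frozen=True)
class OverlapCounts:
    """Three-way partition of two collections' rank-label sets."""

    rank: str
    only_a: int
    only_b: int
    both: int
    labels_only_a: frozenset[int] = field(default=frozenset())
    labels_only_b: frozenset[int] = field(default=frozenset())
    labels_both: frozenset[int] = field(default=frozenset())


def collection_overlap(
    taxids_a: Iterable[int],
    taxids_b: Iterable[int],
    db: TaxonomyDB,
    rank: str,
) -> OverlapCounts:
    """Compare two genome collections by their label sets at one rank.

    Each collection is projected to its set of rank-level ancestor taxids
    (members without a label at the rank are dropped); the result is the
    three-way partition of those label sets — the shape of comparison used
    to expose taxa annotated in one reference collection but missing from
    another.
    """
    def labels(taxids: Iterable[int]) -> set[int]:
        out = set()
        for taxid in taxids:
            anc = db.rank_ancestor(taxid, rank)
            if anc is not None:
                out.add(anc)
        return out

    a, b = labels(taxids_a), labels(taxids_b)
    return OverlapCounts(
        rank=rank,
        only_a=len(a - b),
        only_b=len(b - a),
        both=len(a & b),
        labels_only_a=frozenset(a - b),
        labels_only_b=frozenset(b - a),
        labels_both=frozenset(a & b),
    )
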