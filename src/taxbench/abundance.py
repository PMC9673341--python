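"""Per-rank taxon abundance tables and truth-vs-classified concordance.

Abundance is expressed as the percentage of reads attributed to each taxon
at a rank.  The truth side uses all simulated reads as denominator; the
classified side uses reads that received any classification — mirroring
how truth and classified profiles are normalised differently when a
classifier leaves reads unassigned.

Concordance between a truth and a classified profile is computed on
log10-percentage pairs of taxa nonzero in both tables, and two R²
statistics are reported side by side: the coefficient of determination of
the ordinary least-squares fit (``r_squared_ols``, the headline value),
and the deviation of points from the identity line y = x
(``r_squared_identity`` = 1 − Σ(y−x)²/Σ(y−ȳ)²).  The two differ exactly
when the classified profile is globally biased: a constant log-factor
under-call keeps the OLS fit perfect while the identity statistic drops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import TaxonomyDB

__all__ = [
    "AbundanceTable",
    "ConcordanceResult",
    "abundance_table",
    "abundance_table_from_report",
    "concordance",
    "top_n_comparison",
]


@dataclass
class AbundanceTable:
    """Per-rank taxon -> (read count, percent) table."""

    rank: str
    counts: dict[int, int]
    denominator: int
    source: str  # "truth" or "classified"

    @property
    def percent(self) -> dict[int, float]:
        if self.denominator == 0:
            return {t: 0.0 for t in self.counts}
        return {
            t: 100.0 * c / self.denominator for t, c in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percent
        return pd.DataFrame(
            {
                "taxid": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [pct[t] for t in self.counts],
            }
        ).sort_values("percent", ascending=False, ignore_index=True)


def abundance_table(
    read_taxids: pd.DataFrame,
    db: TaxonomyDB,
    rank: str,
    source: str = "truth",
) -> AbundanceTable:
    """Aggregate a read->taxid table to rank-level abundance.

    Reads whose taxon has no label at *rank* contribute to the denominator
    but to no entry — they are invisible at this level, which is exactly
    how incomplete lineages depress per-rank profiles.  For ``source=
    "classified"`` the denominator is the number of reads with any
    classification (taxid != 0); for truth it is all reads.
    """
    if rank not in db.canonical_ranks:
        raise ValueError(f"unknown rank {rank!r}")
    if source not in ("truth", "classified"):
        raise ValueError(f"source must be 'truth' or 'classified', got {source!r}")
    taxids = read_taxids["taxid"].to_numpy()
    if source == "classified":
        taxids = taxids[taxids != 0]
        denominator = len(taxids)
    else:
        denominator = len(taxids)

    anc: dict[int, int | None] = {}
    counts: dict[int, int] = {}
    for taxid, n in pd.Series(taxids).value_counts().items():
        taxid = int(taxid)
        if taxid not in anc:
            anc[taxid] = db.rank_ancestor(taxid, rank)
        label = anc[taxid]
        if label is not None:
            counts[label] = counts.get(label, 0) + int(n)
    return AbundanceTable(
        rank=rank, counts=counts, denominator=denominator, source=source
    )


_REPORT_RANK_CODES = {
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


def abundance_table_from_report(
    report: pd.DataFrame, rank: str
) -> AbundanceTable:
    """Classified abundance from a parsed Kraken report table.

    Uses clade read counts of rows whose rank code matches *rank*; the
    denominator is the root clade count (all classified reads).  The
    report DataFrame is the output of
    :func:`taxbench.kraken_io.read_kraken_report`.
    """
    code = _REPORT_RANK_CODES.get(rank)
    if code is None:
        raise ValueError(f"unknown rank {rank!r}")
    root_rows = report[report["taxid"] == 1]
    denominator = int(root_rows["clade_reads"].iloc[0]) if len(root_rows) else 0
    at_rank = report[report["rank_code"] == code]
    counts = {
        int(t): int(c)
        for t, c in zip(at_rank["taxid"], at_rank["clade_reads"])
        if c > 0
    }
    return AbundanceTable(
        rank=rank, counts=counts, denominator=denominator, source="classified"
    )


@dataclass
class ConcordanceResult:
    """Log10 truth-vs-classified regression over shared nonzero taxa."""

    rank: str
    n_points: int
    points: pd.DataFrame  # columns: taxid, log10_truth, log10_classified
    insufficient_data: bool
    slope: float | None = None
    intercept: float | None = None
    r_squared_ols: float | None = None
    r_squared_identity: float | None = None

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "n_points": self.n_points,
            "insufficient_data": self.insufficient_data,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared_ols": self.r_squared_ols,
            "r_squared_identity": self.r_squared_identity,
        }


def concordance(
    truth_table: AbundanceTable,
    classified_table: AbundanceTable,
    pseudocount_percent: float | None = None,
) -> ConcordanceResult:
    """Pair the two profiles on log10 percentages and fit OLS.

    Taxa with zero percent in either table are excluded (they have no
    position on a log scatter); pass ``pseudocount_percent`` to instead
    offset every percentage by a constant before the log transform.
    Fewer than 3 shared nonzero taxa yields an insufficient-data result
    with no statistics rather than a meaningless fit.
    """
    if truth_table.rank != classified_table.rank:
        raise ValueError(
            f"rank mismatch: {truth_table.rank!r} vs {classified_table.rank!r}"
        )
    tp, cp = truth_table.percent, classified_table.percent
    if pseudocount_percent is not None:
        shared = sorted(set(tp) | set(cp))
        pairs = [
            (t, tp.get(t, 0.0) + pseudocount_percent,
             cp.get(t, 0.0) + pseudocount_percent)
            for t in shared
        ]
        pairs = [(t, x, y) for t, x, y in pairs if x > 0 and y > 0]
    else:
        shared = sorted(t for t in tp if tp[t] > 0 and cp.get(t, 0.0) > 0)
        pairs = [(t, tp[t], cp[t]) for t in shared]

    points = pd.DataFrame(
        {
            "taxid": [t for t, _, _ in pairs],
            "log10_truth": [math.log10(x) for _, x, _ in pairs],
            "log10_classified": [math.log10(y) for _, _, y in pairs],
        }
    )
    if len(points) < 3:
        return ConcordanceResult(
            rank=truth_table.rank,
            n_points=len(points),
            points=points,
            insufficient_data=True,
        )
    x = points["log10_truth"].to_numpy()
    y = points["log10_classified"].to_numpy()
    if np.allclose(x, x[0]):
        # Degenerate: no variance in truth; OLS slope undefined.
        return ConcordanceResult(
            rank=truth_table.rank,
            n_points=len(points),
            points=points,
            insufficient_data=True,
        )
    fit = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_identity = float(np.sum((y - x) ** 2))
    r2_identity = 1.0 - ss_identity / ss_tot if ss_tot > 0 else float("nan")
    return ConcordanceResult(
        rank=truth_table.rank,
        n_points=len(points),
        points=points,
        insufficient_data=False,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared_ols=float(fit.rvalue**2),
        r_squared_identity=r2_identity,
    )


def top_n_comparison(
    truth_table: AbundanceTable,
    classified_table: AbundanceTable,
    n: int = 10,
    db: TaxonomyDB | None = None,
) -> pd.DataFrame:
    """The n most truth-abundant taxa with truth and classified percents.

    Ordered by truth percent descending, ties broken by taxid ascending;
    taxa absent from the classified table show 0 — surfacing abundant taxa
    a reference database failed to recover at all.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if truth_table.rank != classified_table.rank:
        raise ValueError(
            f"rank mismatch: {truth_table.rank!r} vs {classified_table.rank!r}"
        )
    tp, cp = truth_table.percent, classified_table.percent
    ordered = sorted(tp.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    rows = [
        {
            "taxid": taxid,
            "name": db[taxid].name if db is not None else None,
            "truth_percent": pct,
            "classified_percent": cp.get(taxid, 0.0),
        }
        for taxid, pct in ordered
    ]
    frame = pd.DataFrame(
        rows, columns=["taxid", "name", "truth_percent", "classified_percent"]
    )
    if db is None:
        frame = frame.drop(columns=["name"])
    return frame
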