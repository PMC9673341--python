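"""Readers and writers for the pipeline's file dialects.

Covered formats: Kraken standard 5-column per-read output, Kraken 6-column
report files, the two-column ground-truth TSV, FASTA (80-column wrap) and
4-line FASTQ.  All readers raise with a line number on malformed input;
writers round-trip losslessly for every field the pipeline consumes, and
unknown trailing columns of Kraken output records are preserved verbatim.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .classifier import KrakenRecord
from .taxonomy import TaxonomyDB

__all__ = [
    "read_kraken_output",
    "write_kraken_output",
    "records_to_frame",
    "frame_to_records",
    "read_kraken_report",
    "write_kraken_report",
    "kraken_report_frame",
    "read_truth",
    "write_truth",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]


# -- Kraken 5-column output dialect ------------------------------------------

def read_kraken_output(path: str | Path) -> list[KrakenRecord]:
    """Parse Kraken-dialect per-read output.

    Columns: C/U flag, read id, taxid, length field, k-mer LCA map; the
    last two are optional.  A "C" record with taxid 0 or a "U" record with
    a nonzero taxid is a hard error.
    """
    records: list[KrakenRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                taxid = int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer taxid {fields[2]!r}"
                ) from None
            try:
                records.append(
                    KrakenRecord(
                        status=fields[0],
                        read_id=fields[1],
                        taxid=taxid,
                        length_field=fields[3] if len(fields) > 3 else "",
                        lca_map=fields[4] if len(fields) > 4 else "",
                        extra=tuple(fields[5:]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_kraken_output(
    records: Iterable[KrakenRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fields = [
                rec.status,
                rec.read_id,
                str(rec.taxid),
                rec.length_field,
                rec.lca_map,
                *rec.extra,
            ]
            fh.write("\t".join(fields) + "\n")


def records_to_frame(records: Iterable[KrakenRecord]) -> pd.DataFrame:
    """Reduce records to the (read_id, taxid) table the evaluator consumes."""
    recs = list(records)
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in recs],
            "taxid": [r.taxid for r in recs],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[KrakenRecord]:
    """Lift a (read_id, taxid) table into minimal Kraken records."""
    return [
        KrakenRecord(
            status="C" if taxid != 0 else "U",
            read_id=str(read_id),
            taxid=int(taxid),
        )
        for read_id, taxid in zip(frame["read_id"], frame["taxid"])
    ]


# -- Kraken report dialect ----------------------------------------------------

_RANK_CODE = {
    "root": "R",
    "superkingdom": "D",
    "kingdom": "K",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


def _rank_code(db: TaxonomyDB, taxid: int) -> str:
    """Kraken-style rank code; uncoded ranks get the nearest coded
    ancestor's code plus the distance to it (e.g. a strain under a species
    is "S1")."""
    if taxid == db.root_taxid:
        return "R"
    rank = db[taxid].rank
    if rank in _RANK_CODE:
        return _RANK_CODE[rank]
    path = db.path_to_root(taxid)
    for steps, anc in enumerate(path[1:], 1):
        if anc == db.root_taxid:
            return f"R{steps}"
        anc_rank = db[anc].rank
        if anc_rank in _RANK_CODE:
            return f"{_RANK_CODE[anc_rank]}{steps}"
    return "-"


def kraken_report_frame(
    records: Iterable[KrakenRecord], db: TaxonomyDB
) -> pd.DataFrame:
    """Clade-aggregated report table from per-read records.

    One row per taxon with any reads in its clade, in depth-first order,
    plus the unclassified pseudo-row (taxid 0).  Clade counts sum direct
    counts over the subtree; percentages are of all reads.
    """
    recs = list(records)
    total = len(recs)
    direct: dict[int, int] = {}
    for rec in recs:
        direct[rec.taxid] = direct.get(rec.taxid, 0) + 1
    clade: dict[int, int] = {}

    def fill(taxid: int) -> int:
        count = direct.get(taxid, 0)
        for child in db.children(taxid):
            count += fill(child)
        clade[taxid] = count
        return count

    fill(db.root_taxid)

    rows: list[dict] = []
    n_unclassified = direct.get(0, 0)
    rows.append(
        {
            "percent": 100.0 * n_unclassified / total if total else 0.0,
            "clade_reads": n_unclassified,
            "direct_reads": n_unclassified,
            "rank_code": "U",
            "taxid": 0,
            "name": "unclassified",
            "depth": 0,
        }
    )

    def emit(taxid: int, depth: int) -> None:
        if clade.get(taxid, 0) == 0:
            return
        rows.append(
            {
                "percent": 100.0 * clade[taxid] / total if total else 0.0,
                "clade_reads": clade[taxid],
                "direct_reads": direct.get(taxid, 0),
                "rank_code": _rank_code(db, taxid),
                "taxid": taxid,
                "name": db[taxid].name,
                "depth": depth,
            }
        )
        for child in sorted(db.children(taxid)):
            emit(child, depth + 1)

    emit(db.root_taxid, 0)
    return pd.DataFrame(rows)


def write_kraken_report(
    records_or_frame: Iterable[KrakenRecord] | pd.DataFrame,
    path: str | Path,
    db: TaxonomyDB | None = None,
) -> None:
    """Write a Kraken-dialect report (name column indented two spaces per
    depth level)."""
    if isinstance(records_or_frame, pd.DataFrame):
        frame = records_or_frame
    else:
        if db is None:
            raise ValueError("db is required when writing from records")
        frame = kraken_report_frame(records_or_frame, db)
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.percent:6.2f}\t{row.clade_reads}\t{row.direct_reads}\t"
                f"{row.rank_code}\t{row.taxid}\t{'  ' * row.depth}{row.name}\n"
            )


def read_kraken_report(path: str | Path) -> pd.DataFrame:
    """Parse a Kraken report into a DataFrame with a ``depth`` column
    recovered from the name indentation."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name_field = fields[5]
            stripped = name_field.lstrip(" ")
            depth = (len(name_field) - len(stripped)) // 2
            try:
                rows.append(
                    {
                        "percent": float(fields[0]),
                        "clade_reads": int(fields[1]),
                        "direct_reads": int(fields[2]),
                        "rank_code": fields[3],
                        "taxid": int(fields[4]),
                        "name": stripped,
                        "depth": depth,
                    }
                )
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric field"
                ) from None
    return pd.DataFrame(rows)


# -- ground-truth TSV ---------------------------------------------------------

def read_truth(path: str | Path) -> pd.DataFrame:
    """Two-column headerless TSV: read_id, taxid."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["read_id", "taxid"],
        dtype={"read_id": str, "taxid": int},
    )
    return frame


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[["read_id", "taxid"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# -- sequence formats ---------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(records)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ reduced to (read id, sequence) pairs; qualities are ignored
    throughout the pipeline."""
    return [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """4-line records with constant 'I' qualities (qualities are never
    consumed downstream)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
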