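"""A minimal exact-k-mer LCA read classifier with Kraken-dialect output.

This is the in-repo stand-in for a production k-mer classifier: it indexes
every canonical k-mer of a genome set, storing for each k-mer the lowest
common ancestor (LCA) of all genomes containing it, and classifies a read
pair by root-to-leaf path scoring over its k-mer hits.  Exact k-mers are
used rather than minimizers, which keeps the brute-force test oracle
tractable and makes the self-classification soundness property provable:
with an index built from exactly the source genomes and error-free reads,
every assignment lies on the truth taxon's root path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqRecord import SeqRecord

from .taxonomy import TaxonomyDB
from .synthetic import parse_genome_header, revcomp

__all__ = [
    "KmerIndex",
    "KrakenRecord",
    "build_index",
    "classify_read",
    "classify_pairs",
    "canonical_kmers",
]

_ACGT = frozenset("ACGT")


def canonical_kmers(sequence: str, k: int) -> list[str]:
    """Canonical (lexicographic min of strand pair) k-mers of a sequence.

    K-mers containing non-ACGT symbols are skipped.  Sequences shorter
    than k yield an empty list.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        return []
    rc = revcomp(seq)
    bad_positions = [i for i, c in enumerate(seq) if c not in _ACGT]
    out: list[str] = []
    if not bad_positions:
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            rev = rc[n - k - i : n - i]
            out.append(fwd if fwd <= rev else rev)
        return out
    bad = set(bad_positions)
    for i in range(n - k + 1):
        if any(p in bad for p in range(i, i + k)):
            continue
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        out.append(fwd if fwd <= rev else rev)
    return out


@dataclass
class KmerIndex:
    """Canonical-k-mer -> taxid map over a genome set.

    Each stored taxid is the LCA of all source genomes containing that
    k-mer.
    """

    k: int
    kmer_to_taxid: dict[str, int]
    db: TaxonomyDB

    def __len__(self) -> int:
        return len(self.kmer_to_taxid)

    def save(self, path: str | Path) -> None:
        """Plain-text index dump: a ``#k`` header then kmer<TAB>taxid lines."""
        with open(path, "w") as fh:
            fh.write(f"#k\t{self.k}\n")
            for kmer in sorted(self.kmer_to_taxid):
                fh.write(f"{kmer}\t{self.kmer_to_taxid[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path, db: TaxonomyDB) -> "KmerIndex":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) != 2 or header[0] != "#k":
                raise ValueError(f"{path}: missing '#k' header line")
            k = int(header[1])
            mapping: dict[str, int] = {}
            for lineno, line in enumerate(fh, 2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed index line")
                mapping[fields[0]] = int(fields[1])
        return cls(k=k, kmer_to_taxid=mapping, db=db)


@dataclass
class KrakenRecord:
    """One per-pair record of the Kraken 5-column output dialect.

    ``lca_map`` (column 5) is the space-separated "taxid:count" run-length
    encoding of per-k-mer assignments, with a literal "|:|" token between
    mates; it is opaque to the evaluation layer and preserved verbatim by
    the readers/writers.  ``extra`` holds any unknown trailing columns.
    """

    status: str  # "C" or "U"
    read_id: str
    taxid: int
    length_field: str = ""
    lca_map: str = ""
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ("C", "U"):
            raise ValueError(f"status must be 'C' or 'U', got {self.status!r}")
        if (self.status == "U") != (self.taxid == 0):
            raise ValueError(
                f"record {self.read_id!r}: status {self.status!r} inconsistent "
                f"with taxid {self.taxid}"
            )


def build_index(
    genomes: Sequence[SeqRecord], db: TaxonomyDB, k: int = 21
) -> KmerIndex:
    """Index a genome set: each k-mer maps to the LCA of its source genomes.

    Genome headers must carry ``taxid|<id>|<name>``; k must be odd and in
    [3, 31] (odd k avoids self-reverse-complement palindromic k-mers).
    """
    if not (3 <= k <= 31) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [3, 31], got {k}")
    mapping: dict[str, int] = {}
    for rec in genomes:
        taxid, _ = parse_genome_header(rec.description)
        if taxid not in db:
            raise ValueError(f"genome taxid {taxid} not present in taxonomy")
        for kmer in set(canonical_kmers(str(rec.seq), k)):
            current = mapping.get(kmer)
            if current is None:
                mapping[kmer] = taxid
            elif current != taxid:
                mapping[kmer] = db.lca((current, taxid))
    return KmerIndex(k=k, kmer_to_taxid=mapping, db=db)


def _hit_taxids(index: KmerIndex, kmers: Iterable[str]) -> Counter:
    hits: Counter = Counter()
    get = index.kmer_to_taxid.get
    for kmer in kmers:
        taxid = get(kmer)
        if taxid is not None:
            hits[taxid] += 1
    return hits


def _resolve(hits: Counter, db: TaxonomyDB) -> int:
    """Root-to-leaf path scoring over the taxa with direct k-mer hits.

    score(t) = sum of hit counts over t's root path; the winner is the
    taxon with the maximal score among taxa holding >=1 direct hit.  Two
    taxa on a common root path can never tie (the deeper one strictly
    dominates), so remaining ties are between incomparable taxa and
    resolve to their LCA.
    """
    if not hits:
        return 0
    best_score = -1
    winners: list[int] = []
    for taxid in hits:
        score = sum(hits.get(node, 0) for node in db.path_to_root(taxid))
        if score > best_score:
            best_score = score
            winners = [taxid]
        elif score == best_score:
            winners.append(taxid)
    return winners[0] if len(winners) == 1 else db.lca(winners)


def classify_read(
    index: KmerIndex,
    db: TaxonomyDB,
    sequence: str | tuple[str, str],
) -> int:
    """Classify a sequence or mate pair; returns a taxid, 0 if unclassified.

    Hits are pooled over the canonical k-mers of both mates (the paired
    analog of classifying the pair as one unit).
    """
    mates = (sequence,) if isinstance(sequence, str) else tuple(sequence)
    hits: Counter = Counter()
    for mate in mates:
        hits.update(_hit_taxids(index, canonical_kmers(mate, index.k)))
    return _resolve(hits, db)


def _lca_map_tokens(index: KmerIndex, sequence: str) -> str:
    """Run-length "taxid:count" tokens over a mate's k-mer assignments."""
    tokens: list[str] = []
    prev: int | None = None
    run = 0
    for kmer in canonical_kmers(sequence, index.k):
        taxid = index.kmer_to_taxid.get(kmer, 0)
        if taxid == prev:
            run += 1
        else:
            if prev is not None:
                tokens.append(f"{prev}:{run}")
            prev, run = taxid, 1
    if prev is not None:
        tokens.append(f"{prev}:{run}")
    return " ".join(tokens)


def classify_pairs(
    index: KmerIndex,
    db: TaxonomyDB,
    reads_r1: Sequence[tuple[str, str]],
    reads_r2: Sequence[tuple[str, str]],
) -> list[KrakenRecord]:
    """Classify paired reads into Kraken-dialect records, one per pair.

    Mates must be in consistent order; the pair id is the read id with any
    ``/1``/``/2`` suffix removed.
    """
    if len(reads_r1) != len(reads_r2):
        raise ValueError(
            f"mate count mismatch: {len(reads_r1)} vs {len(reads_r2)}"
        )
    records: list[KrakenRecord] = []
    for (id1, seq1), (id2, seq2) in zip(reads_r1, reads_r2):
        base1 = id1.rsplit("/", 1)[0]
        base2 = id2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        taxid = classify_read(index, db, (seq1, seq2))
        lca_map = (
            _lca_map_tokens(index, seq1) + " |:| " + _lca_map_tokens(index, seq2)
        )
        records.append(
            KrakenRecord(
                status="C" if taxid != 0 else "U",
                read_id=base1,
                taxid=taxid,
                length_field=f"{len(seq1)}|{len(seq2)}",
                lca_map=lca_map,
            )
        )
    return records
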