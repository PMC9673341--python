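"""Rank-aware taxonomy trees in the NCBI taxdump dialect.

The central object is :class:`TaxonomyDB`, a rooted tree of taxa, each
carrying a rank string from an open vocabulary ("phylum", "no rank",
"strain", ...).  The queries that matter downstream are *rank-aware*:
``rank_ancestor`` walks from a taxon towards the root and returns the first
node of a given canonical rank, or reports that no such node exists on the
path.  Absent ranks are a feature of real reference taxonomies, not an
error — metagenome-assembled genomes are routinely deposited with a species
label but no genus or family node in their lineage, and that absence is
exactly what the evaluation layer's "truth unknown" and "unclassified at
this level" categories key on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CANONICAL_RANKS",
    "Taxon",
    "TaxonomyDB",
    "Lineage",
    "CompletenessReport",
    "TaxonomyError",
    "load_taxdump",
    "write_taxdump",
    "is_informal_name",
    "INFORMAL_NAME_TOKENS",
]

#: Default canonical ranks, ordered from most to least inclusive.  Kingdom
#: and superkingdom are deliberately absent: every per-rank figure the
#: evaluation layer produces runs phylum -> species.
CANONICAL_RANKS: tuple[str, ...] = (
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class TaxonomyError(ValueError):
    """Raised for structural problems: unknown taxids, cycles, bad dumps."""


@dataclass(frozen=True)
class Taxon:
    """A single taxonomy node.

    The root is the unique node whose ``parent_taxid`` equals its own
    ``taxid``, following NCBI convention (taxid 1 points to itself).
    """

    taxid: int
    parent_taxid: int
    rank: str
    name: str


@dataclass(frozen=True)
class Lineage:
    """Partial rank -> (taxid, name) map for one source taxon.

    Only canonical ranks actually present on the root path appear as keys;
    a missing key means the lineage has no node of that rank.
    """

    source_taxid: int
    by_rank: Mapping[str, tuple[int, str]]

    def has_rank(self, rank: str) -> bool:
        return rank in self.by_rank


@dataclass(frozen=True)
class CompletenessReport:
    """Per-rank missing-label counts over a set of taxa."""

    n_taxa: int
    missing_by_rank: Mapping[str, int]
    informal_name_count: int


# Tokens whose presence (as a whole word, case-insensitive) marks a name as
# informal, plus structural patterns: names ending in "bacterium"/"archaeon"
# with an optional strain tag, and names containing "sp." placeholders.
INFORMAL_NAME_TOKENS: tuple[str, ...] = ("uncultured", "candidate", "candidatus")

_INFORMAL_SUFFIX_RE = re.compile(
    r"\b(bacterium|archaeon)(\s+[A-Za-z0-9_.-]+)?$", re.IGNORECASE
)
_INFORMAL_SP_RE = re.compile(r"\bsp\.(\s|$)", re.IGNORECASE)


def is_informal_name(name: str, tokens: Sequence[str] = INFORMAL_NAME_TOKENS) -> bool:
    """Heuristic test for informal / placeholder species names.

    A name is informal if it contains any of *tokens* as a whole word
    (case-insensitive), ends in "bacterium"/"archaeon" optionally followed
    by a strain tag, or contains a "sp." placeholder.  Covers the naming
    style of uncultured MAG deposits ("uncultured Lachnospiraceae bacterium
    RUG10034", "Ruminococcaceae bacterium", "uncultured Bifidobacterium
    sp.") while leaving formal binomials ("Kandleria vitulina") alone.
    """
    if not name:
        raise ValueError("name must be a nonempty string")
    lowered = name.lower()
    for token in tokens:
        if re.search(rf"\b{re.escape(token.lower())}\b", lowered):
            return True
    if _INFORMAL_SUFFIX_RE.search(name):
        return True
    if _INFORMAL_SP_RE.search(name):
        return True
    return False


class TaxonomyDB:
    """A rooted taxonomy supporting rank-ancestor, lineage and LCA queries.

    Parameters
    ----------
    taxa:
        The taxon set; taxids must be unique, every parent must resolve,
        and exactly one node must be its own parent (the root).
    canonical_ranks:
        Ordered rank names (most to least inclusive) used by rank-aware
        queries.  Non-canonical rank strings on nodes are kept verbatim and
        simply never match a canonical query.
    """

    def __init__(
        self,
        taxa: Iterable[Taxon],
        canonical_ranks: Sequence[str] = CANONICAL_RANKS,
    ) -> None:
        self._taxa: dict[int, Taxon] = {}
        for t in taxa:
            if t.taxid in self._taxa:
                raise TaxonomyError(f"duplicate taxid {t.taxid}")
            if t.taxid <= 0:
                raise TaxonomyError(f"taxid must be positive, got {t.taxid}")
            self._taxa[t.taxid] = t
        if not self._taxa:
            raise TaxonomyError("taxonomy must contain at least one taxon")
        roots = [t.taxid for t in self._taxa.values() if t.parent_taxid == t.taxid]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root (parent == self), found {len(roots)}"
            )
        self.root_taxid: int = roots[0]
        for t in self._taxa.values():
            if t.parent_taxid not in self._taxa:
                raise TaxonomyError(
                    f"taxid {t.taxid} has unknown parent taxid {t.parent_taxid}"
                )
        self.canonical_ranks: tuple[str, ...] = tuple(canonical_ranks)
        self._path_cache: dict[int, tuple[int, ...]] = {}
        self._rank_anc_cache: dict[tuple[int, str], int | None] = {}
        self._children: dict[int, list[int]] | None = None
        # Cycle check doubles as path-cache warm-up for small trees.
        for taxid in self._taxa:
            self.path_to_root(taxid)

    # -- container protocol -------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._taxa

    def __len__(self) -> int:
        return len(self._taxa)

    def __getitem__(self, taxid: int) -> Taxon:
        try:
            return self._taxa[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def __iter__(self):
        return iter(self._taxa.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyDB):
            return NotImplemented
        return (
            self._taxa == other._taxa
            and self.canonical_ranks == other.canonical_ranks
        )

    @property
    def taxids(self) -> Iterable[int]:
        return self._taxa.keys()

    def children(self, taxid: int) -> list[int]:
        """Child taxids of *taxid* (root excluded from its own children)."""
        if self._children is None:
            self._children = {tid: [] for tid in self._taxa}
            for t in self._taxa.values():
                if t.taxid != t.parent_taxid:
                    self._children[t.parent_taxid].append(t.taxid)
        self[taxid]
        return self._children[taxid]

    # -- path machinery -----------------------------------------------------

    def path_to_root(self, taxid: int) -> tuple[int, ...]:
        """Taxids from *taxid* (inclusive) up to and including the root."""
        cached = self._path_cache.get(taxid)
        if cached is not None:
            return cached
        path: list[int] = []
        seen: set[int] = set()
        node = self[taxid].taxid
        while True:
            if node in seen:
                raise TaxonomyError(f"cycle detected at taxid {node}")
            seen.add(node)
            path.append(node)
            parent = self._taxa[node].parent_taxid
            if parent == node:
                break
            cached_tail = self._path_cache.get(parent)
            if cached_tail is not None:
                path.extend(cached_tail)
                break
            node = parent
        result = tuple(path)
        # Every suffix is itself a root path; cache them all.
        for i, tid in enumerate(result):
            if tid not in self._path_cache:
                self._path_cache[tid] = result[i:]
        return result

    def depth(self, taxid: int) -> int:
        """Number of edges from *taxid* to the root."""
        return len(self.path_to_root(taxid)) - 1

    # -- rank-aware queries -------------------------------------------------

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """First node of rank *rank* on the path from *taxid* to the root.

        The walk is inclusive: a species node queried at "species" returns
        itself.  Returns ``None`` when no node of that rank lies on the
        path — the lineage simply has no label at that level.
        """
        if rank not in self.canonical_ranks:
            raise TaxonomyError(f"unknown rank {rank!r}; not in canonical_ranks")
        key = (taxid, rank)
        if key in self._rank_anc_cache:
            return self._rank_anc_cache[key]
        result: int | None = None
        for node in self.path_to_root(taxid):
            if self._taxa[node].rank == rank:
                result = node
                break
        self._rank_anc_cache[key] = result
        return result

    def lineage(self, taxid: int) -> Lineage:
        """Partial canonical-rank lineage of *taxid*."""
        by_rank: dict[str, tuple[int, str]] = {}
        for rank in self.canonical_ranks:
            anc = self.rank_ancestor(taxid, rank)
            if anc is not None:
                by_rank[rank] = (anc, self._taxa[anc].name)
        return Lineage(source_taxid=taxid, by_rank=by_rank)

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor: deepest node on every member's root path."""
        ids = list(taxids)
        if not ids:
            raise TaxonomyError("lca of an empty collection is undefined")
        common = self.path_to_root(ids[0])
        common_set = set(common)
        for tid in ids[1:]:
            common_set &= set(self.path_to_root(tid))
        for node in common:  # ordered deepest-first along the first path
            if node in common_set:
                return node
        raise TaxonomyError("taxa share no common ancestor (corrupt tree)")

    def completeness_report(self, taxids: Iterable[int]) -> CompletenessReport:
        """Count, per canonical rank, how many inputs lack a label there.

        Also counts inputs whose own scientific name matches the informal
        name predicate — the MAG-style "uncultured X bacterium" deposits.
        """
        ids = list(taxids)
        missing = {rank: 0 for rank in self.canonical_ranks}
        informal = 0
        for tid in ids:
            lin = self.lineage(tid)
            for rank in self.canonical_ranks:
                if rank not in lin.by_rank:
                    missing[rank] += 1
            if is_informal_name(self[tid].name):
                informal += 1
        return CompletenessReport(
            n_taxa=len(ids), missing_by_rank=missing, informal_name_count=informal
        )

    def taxids_with_rank(self, rank: str) -> list[int]:
        """All taxids whose own rank string equals *rank*, sorted."""
        return sorted(t.taxid for t in self._taxa.values() if t.rank == rank)


# -- taxdump dialect ---------------------------------------------------------

_FIELD_SEP = "\t|\t"
_LINE_TERM = "\t|"


def _parse_dmp_line(line: str, lineno: int, path: str) -> list[str]:
    stripped = line.rstrip("\n")
    if not stripped.endswith(_LINE_TERM):
        raise TaxonomyError(
            f"{path}:{lineno}: malformed line (missing '\\t|' terminator)"
        )
    return stripped[: -len(_LINE_TERM)].split(_FIELD_SEP)


def load_taxdump(
    nodes_source: str | Path,
    names_source: str | Path,
    canonical_ranks: Sequence[str] = CANONICAL_RANKS,
) -> TaxonomyDB:
    """Load a taxonomy from NCBI-dialect ``nodes.dmp`` / ``names.dmp`` files.

    Only the first three fields of each nodes record (taxid, parent taxid,
    rank) and the "scientific name" class of the names file are consumed.
    Nodes without a scientific-name record get the placeholder name
    ``taxid:<id>``.
    """
    nodes_path, names_path = Path(nodes_source), Path(names_source)
    records: dict[int, tuple[int, str]] = {}
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, lineno, str(nodes_path))
            if len(fields) < 3:
                raise TaxonomyError(
                    f"{nodes_path}:{lineno}: expected >=3 fields, got {len(fields)}"
                )
            try:
                taxid = int(fields[0])
                parent = int(fields[1])
            except ValueError:
                raise TaxonomyError(
                    f"{nodes_path}:{lineno}: non-integer taxid fields"
                ) from None
            if taxid in records:
                raise TaxonomyError(f"duplicate taxid {taxid} in {nodes_path}")
            records[taxid] = (parent, fields[2])

    names: dict[int, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line, lineno, str(names_path))
            if len(fields) < 4:
                raise TaxonomyError(
                    f"{names_path}:{lineno}: expected >=4 fields, got {len(fields)}"
                )
            if fields[3] == "scientific name":
                try:
                    taxid = int(fields[0])
                except ValueError:
                    raise TaxonomyError(
                        f"{names_path}:{lineno}: non-integer taxid"
                    ) from None
                names[taxid] = fields[1]

    for taxid, (parent, _) in records.items():
        if parent not in records:
            raise TaxonomyError(
                f"taxid {taxid} references parent taxid {parent} "
                f"absent from {nodes_path}"
            )
    taxa = [
        Taxon(
            taxid=taxid,
            parent_taxid=parent,
            rank=rank,
            name=names.get(taxid, f"taxid:{taxid}"),
        )
        for taxid, (parent, rank) in records.items()
    ]
    return TaxonomyDB(taxa, canonical_ranks=canonical_ranks)


def write_taxdump(
    db: TaxonomyDB, nodes_dest: str | Path, names_dest: str | Path
) -> None:
    """Write *db* in the taxdump dialect (first-fields bit-exact with NCBI).

    NCBI nodes records carry trailing flag fields after rank; these carry no
    information this pipeline uses, so a constant-filled tail is emitted to
    keep the column count NCBI-shaped.
    """
    ordered = sorted(db.taxids)
    with open(nodes_dest, "w") as fh:
        for taxid in ordered:
            t = db[taxid]
            fields = [str(t.taxid), str(t.parent_taxid), t.rank, ""]
            fh.write(_FIELD_SEP.join(fields) + _LINE_TERM + "\n")
    with open(names_dest, "w") as fh:
        for taxid in ordered:
            t = db[taxid]
            fields = [str(t.taxid), t.name, "", "scientific name"]
            fh.write(_FIELD_SEP.join(fields) + _LINE_TERM + "\n")
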