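"""Synthetic communities with controllable lineage incompleteness.

Everything the benchmark consumes can be generated here: a taxonomy whose
species may lack genus and/or family nodes (the defining pathology of
metagenome-assembled-genome reference sets), random genomes, abundance-
weighted paired-end reads with a per-read ground-truth table, and — for
exercising the evaluation layer without a classifier — directly simulated
classification output with injected error structure.

All generators are pure functions of (config, seed): the same inputs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import CANONICAL_RANKS, Taxon, TaxonomyDB

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityConfig",
    "ErrorSpec",
    "ReadSimulation",
    "generate_taxonomy",
    "generate_genomes",
    "simulate_reads",
    "simulate_classifier_output",
    "parse_genome_header",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CommunityConfig:
    """Parameters of a simulated community and its sequencing run.

    The defaults describe a desk-scale analog of a short-read rumen
    metagenome simulation: exponential genome abundances, 150 bp paired-end
    reads from ~350 bp inserts, and a low per-base substitution rate typical
    of Illumina chemistry.  Lineage-incompleteness fractions default to zero
    (complete lineages); presets for isolate-collection-like and MAG-like
    reference sets are exposed as classmethods.
    """

    n_species: int = 100
    mean_genome_length: int = 20_000
    abundance_model: str = "exponential"  # exponential | lognormal | uniform
    n_read_pairs: int = 50_000
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 30
    substitution_rate: float = 0.001
    missing_family_frac: float = 0.0
    missing_genus_frac: float = 0.0
    informal_species_frac: float = 0.0
    seed: int = 0
    dataset_id: str = "sim"

    _ABUNDANCE_MODELS = ("exponential", "lognormal", "uniform")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_read_pairs < 1:
            raise ValueError("n_read_pairs must be >= 1")
        if self.read_length < 1 or self.read_length > self.mean_genome_length:
            raise ValueError("read_length must be in [1, mean_genome_length]")
        if self.abundance_model not in self._ABUNDANCE_MODELS:
            raise ValueError(
                f"abundance_model must be one of {self._ABUNDANCE_MODELS}"
            )
        for name in (
            "substitution_rate",
            "missing_family_frac",
            "missing_genus_frac",
            "informal_species_frac",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")

    @classmethod
    def isolate_collection_like(cls, **overrides) -> "CommunityConfig":
        """Lineage completeness shaped like a cultured-isolate collection.

        Roughly 2% of species lack a family label and 16% lack a genus
        label, with formal binomial names throughout.
        """
        defaults = dict(
            missing_family_frac=8 / 460,
            missing_genus_frac=73 / 460,
            informal_species_frac=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def mag_collection_like(cls, **overrides) -> "CommunityConfig":
        """Lineage completeness shaped like a rumen MAG collection.

        About 35% of species lack a family label, 78% lack a genus label,
        and 87% carry informal placeholder species names.
        """
        defaults = dict(
            missing_family_frac=1753 / 4941,
            missing_genus_frac=3849 / 4941,
            informal_species_frac=4293 / 4941,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ErrorSpec:
    """Error structure injected into simulated classification output.

    Per read, mutually exclusive outcomes drawn in this order: unclassified;
    misassignment at each configured rank (the read is assigned a uniform
    random *other* species whose ancestor at that rank exists and differs
    from the truth's); under-resolution (a strict ancestor of the truth
    taxon); over-resolution (a below-species child node of the truth taxon);
    otherwise the truth taxid itself.
    """

    unclassified_frac: float = 0.0
    misassignment_frac: Mapping[str, float] = field(default_factory=dict)
    under_resolution_frac: float = 0.0
    over_resolution_frac: float = 0.0

    def __post_init__(self) -> None:
        parts = [
            self.unclassified_frac,
            self.under_resolution_frac,
            self.over_resolution_frac,
            *self.misassignment_frac.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in parts):
            raise ValueError("all ErrorSpec fractions must be probabilities")
        if sum(parts) > 1.0 + 1e-12:
            raise ValueError(
                f"ErrorSpec fractions sum to {sum(parts):.4f} > 1"
            )


@dataclass
class ReadSimulation:
    """Output bundle of :func:`simulate_reads`."""

    reads_r1: list[tuple[str, str]]  # (read id with /1 suffix, sequence)
    reads_r2: list[tuple[str, str]]
    truth: pd.DataFrame  # columns: read_id, taxid (one row per pair)
    genome_counts: dict[int, int]  # source species taxid -> read pairs
    truth_counts: dict[str, dict[int, int]]  # rank -> taxid -> read pairs
    abundances: dict[int, float]  # source species taxid -> relative abundance


# -- name generation ---------------------------------------------------------

_SYLLABLES = (
    "ba", "co", "ru", "mi", "lac", "ther", "vi", "pre", "fib", "cel",
    "lu", "do", "sa", "me", "tro", "pha", "ne", "ri", "ga", "to",
)

_GENUS_SUFFIXES = ("ococcus", "ovibrio", "omonas", "ibacter", "ospira", "ella")
_EPITHET_SUFFIXES = ("ensis", "icus", "alis", "osum", "ivorans", "aris")
_FAMILY_SUFFIX = "aceae"
_ORDER_SUFFIX = "ales"
_CLASS_SUFFIX = "ia"
_PHYLUM_SUFFIX = "ota"


def _stem(rng: np.random.Generator, n_syllables: int = 2) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _latin_name(rng: np.random.Generator, suffixes: Sequence[str], serial: int) -> str:
    stem = _stem(rng)
    suffix = suffixes[serial % len(suffixes)] if isinstance(suffixes, tuple) else suffixes
    return (stem + suffix).capitalize() + ("" if serial == 0 else f"-{serial}")


# -- taxonomy generation -----------------------------------------------------

def _stratum_sizes(n_species: int) -> dict[str, int]:
    # Branching shaped like a bacterial reference taxonomy: a handful of
    # phyla fanning out to roughly half as many genera as species.
    sizes = {
        "phylum": max(2, round(n_species**0.30)),
        "class": round(n_species**0.42),
        "order": round(n_species**0.55),
        "family": round(n_species**0.70),
        "genus": round(n_species**0.85),
    }
    prev = 2
    for rank in ("phylum", "class", "order", "family", "genus"):
        sizes[rank] = max(sizes[rank], prev)
        prev = sizes[rank]
    return sizes


def generate_taxonomy(
    config: CommunityConfig, seed: int | None = None
) -> tuple[TaxonomyDB, list[int]]:
    """Generate a rooted taxonomy and the species taxids of the community.

    The tree has phylum/class/order/family/genus/species strata plus one
    below-species "strain" child per species (so over-resolved assignments
    have a real node to land on).  Independently per species, the genus
    node is omitted with probability ``missing_genus_frac`` (the species is
    parented to its family, or to its order if the family is also omitted)
    and the family node with probability ``missing_family_frac``.  A
    fraction ``informal_species_frac`` of species receive informal
    placeholder names of the kind carried by uncultured MAG deposits.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = _stratum_sizes(config.n_species)

    taxa: list[Taxon] = [Taxon(1, 1, "no rank", "root")]
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        taxa.append(Taxon(next_id, parent, rank, name))
        next_id += 1
        return next_id - 1

    strata: dict[str, list[int]] = {}
    parent_of: dict[int, int] = {}
    rank_specs = (
        ("phylum", _PHYLUM_SUFFIX, None),
        ("class", _CLASS_SUFFIX, "phylum"),
        ("order", _ORDER_SUFFIX, "class"),
        ("family", _FAMILY_SUFFIX, "order"),
        ("genus", _GENUS_SUFFIXES, "family"),
    )
    for rank, suffix, parent_rank in rank_specs:
        strata[rank] = []
        for i in range(sizes[rank]):
            if parent_rank is None:
                parent = 1
            else:
                parent = int(rng.choice(strata[parent_rank]))
            name = _latin_name(rng, suffix, i)
            tid = add(parent, rank, name)
            strata[rank].append(tid)
            parent_of[tid] = parent

    names_by_id = {t.taxid: t.name for t in taxa}
    species_ids: list[int] = []
    for i in range(config.n_species):
        genus = int(rng.choice(strata["genus"]))
        family = parent_of[genus]
        order = parent_of[family]
        drop_family = rng.random() < config.missing_family_frac
        drop_genus = rng.random() < config.missing_genus_frac
        informal = rng.random() < config.informal_species_frac

        if not drop_family and not drop_genus:
            parent = genus
        elif not drop_family and drop_genus:
            parent = family
        elif drop_family and drop_genus:
            parent = order
        else:
            # Family omitted but genus kept: a genus node hanging directly
            # off the order, as deposited MAG lineages sometimes do.
            orphan_name = names_by_id[genus] + f" og{i}"
            parent = add(order, "genus", orphan_name)
            names_by_id[parent] = orphan_name

        if informal:
            context = names_by_id[family if not drop_family else order]
            style = int(rng.integers(3))
            if style == 0:
                name = f"uncultured {context} bacterium RUG{10000 + i}"
            elif style == 1:
                name = f"{context} bacterium"
            else:
                name = f"uncultured {names_by_id[genus]} sp."
        else:
            genus_word = names_by_id[genus].split()[0].split("-")[0]
            epithet = _stem(rng) + _EPITHET_SUFFIXES[i % len(_EPITHET_SUFFIXES)]
            name = f"{genus_word} {epithet}{'' if i == 0 else f'-{i}'}"

        sp = add(parent, "species", name)
        names_by_id[sp] = name
        species_ids.append(sp)
        add(sp, "strain", f"{name} strain st{i}")

    return TaxonomyDB(taxa, canonical_ranks=CANONICAL_RANKS), species_ids


# -- genome generation --------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def parse_genome_header(description: str) -> tuple[int, str]:
    """Parse a ``taxid|<id>|<name>`` FASTA header into (taxid, name)."""
    parts = description.split("|", 2)
    if len(parts) != 3 or parts[0] != "taxid":
        raise ValueError(f"unparseable genome header: {description!r}")
    try:
        taxid = int(parts[1])
    except ValueError:
        raise ValueError(f"non-integer taxid in header: {description!r}") from None
    return taxid, parts[2]


def generate_genomes(
    db: TaxonomyDB,
    genome_taxids: Sequence[int],
    config: CommunityConfig,
    seed: int | None = None,
) -> list[SeqRecord]:
    """One i.i.d.-uniform A/C/G/T genome per taxid.

    Lengths are uniform in ±20% of ``mean_genome_length``; headers encode
    the source taxid as ``taxid|<id>|<name>``.
    """
    config.validate()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    lo = int(round(0.8 * config.mean_genome_length))
    hi = int(round(1.2 * config.mean_genome_length))
    records = []
    for taxid in genome_taxids:
        name = db[taxid].name
        length = int(rng.integers(lo, hi + 1))
        seq = _random_dna(rng, length)
        desc = f"taxid|{taxid}|{name}"
        records.append(
            SeqRecord(Seq(seq), id=desc.split()[0], description=desc)
        )
    return records


# -- read simulation -----------------------------------------------------------

def _draw_abundances(
    rng: np.random.Generator, model: str, n: int
) -> np.ndarray:
    if model == "exponential":
        raw = rng.exponential(1.0, size=n)
    elif model == "lognormal":
        raw = rng.lognormal(0.0, 1.0, size=n)
    elif model == "uniform":
        raw = np.ones(n)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown abundance model {model!r}")
    return raw / raw.sum()


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_sub = rng.binomial(len(seq), rate)
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        current = out[pos]
        choices = [b for b in "ACGT" if b != current]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_reads(
    genomes: Sequence[SeqRecord],
    db: TaxonomyDB,
    config: CommunityConfig,
    seed: int | None = None,
) -> ReadSimulation:
    """Simulate paired-end reads with a known per-read source taxon.

    Genome abundances are drawn from ``abundance_model`` and normalised;
    read-pair counts are multinomial over genomes; fragments are uniform
    along each genome with Gaussian insert sizes; mate 2 is the reverse
    complement end of the fragment; substitution errors are applied per
    base.  Genomes shorter than the read length are skipped with a warning.
    """
    config.validate()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_029
    )
    usable: list[tuple[int, str]] = []
    for rec in genomes:
        taxid, _ = parse_genome_header(rec.description)
        if taxid not in db:
            raise ValueError(f"genome taxid {taxid} not present in taxonomy")
        seq = str(rec.seq)
        if len(seq) < config.read_length:
            logger.warning(
                "skipping genome taxid %d: length %d < read length %d",
                taxid, len(seq), config.read_length,
            )
            continue
        usable.append((taxid, seq))
    if not usable:
        raise ValueError("all genomes shorter than the read length")

    probs = _draw_abundances(rng, config.abundance_model, len(usable))
    counts = rng.multinomial(config.n_read_pairs, probs)

    reads_r1: list[tuple[str, str]] = []
    reads_r2: list[tuple[str, str]] = []
    truth_ids: list[str] = []
    truth_taxids: list[int] = []
    serial = 0
    genome_counts: dict[int, int] = {}
    for (taxid, seq), n_pairs in zip(usable, counts):
        genome_counts[taxid] = int(n_pairs)
        glen = len(seq)
        for _ in range(int(n_pairs)):
            insert = int(
                np.clip(
                    round(rng.normal(config.insert_mean, config.insert_sd)),
                    config.read_length,
                    glen,
                )
            )
            start = int(rng.integers(0, glen - insert + 1))
            frag = seq[start : start + insert]
            r1 = frag[: config.read_length]
            r2 = revcomp(frag)[: config.read_length]
            if config.substitution_rate > 0:
                r1 = _mutate(r1, rng, config.substitution_rate)
                r2 = _mutate(r2, rng, config.substitution_rate)
            read_id = f"{config.dataset_id}_{serial}"
            serial += 1
            reads_r1.append((read_id + "/1", r1))
            reads_r2.append((read_id + "/2", r2))
            truth_ids.append(read_id)
            truth_taxids.append(taxid)

    truth = pd.DataFrame({"read_id": truth_ids, "taxid": truth_taxids})
    truth_counts: dict[str, dict[int, int]] = {}
    for rank in db.canonical_ranks:
        per_rank: dict[int, int] = {}
        for taxid, n_pairs in genome_counts.items():
            anc = db.rank_ancestor(taxid, rank)
            if anc is not None:
                per_rank[anc] = per_rank.get(anc, 0) + n_pairs
        truth_counts[rank] = per_rank

    abundances = {taxid: float(p) for (taxid, _), p in zip(usable, probs)}
    return ReadSimulation(
        reads_r1=reads_r1,
        reads_r2=reads_r2,
        truth=truth,
        genome_counts=genome_counts,
        truth_counts=truth_counts,
        abundances=abundances,
    )


# -- simulated classifier output ------------------------------------------------

def simulate_classifier_output(
    truth: pd.DataFrame,
    db: TaxonomyDB,
    error_spec: ErrorSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Classification table with the given error structure injected.

    Returns a DataFrame with columns ``read_id`` and ``taxid`` (0 for
    unclassified), one row per truth record, deterministic given *seed*.
    See :class:`ErrorSpec` for the outcome semantics.
    """
    rng = np.random.default_rng(seed)
    ranks = list(error_spec.misassignment_frac)
    for rank in ranks:
        if rank not in db.canonical_ranks:
            raise ValueError(f"misassignment rank {rank!r} is not canonical")

    # Candidate pools: species that actually carry each rank, keyed by it.
    species = db.taxids_with_rank("species")
    pools: dict[str, list[int]] = {}
    anc_of: dict[str, dict[int, int | None]] = {}
    for rank in ranks:
        anc_map = {sp: db.rank_ancestor(sp, rank) for sp in species}
        pools[rank] = [sp for sp, a in anc_map.items() if a is not None]
        anc_of[rank] = anc_map
        if not pools[rank]:
            raise ValueError(f"no species carries rank {rank!r}")

    cuts = np.cumsum(
        [error_spec.unclassified_frac]
        + [error_spec.misassignment_frac[r] for r in ranks]
        + [error_spec.under_resolution_frac, error_spec.over_resolution_frac]
    )
    draws = rng.random(len(truth))
    outcomes = np.searchsorted(cuts, draws, side="left")
    n_categories = len(cuts)  # outcome == n_categories means "truth"

    assigned: list[int] = []
    for truth_taxid, outcome in zip(truth["taxid"].to_numpy(), outcomes):
        truth_taxid = int(truth_taxid)
        if truth_taxid not in db:
            raise ValueError(f"truth taxid {truth_taxid} not in taxonomy")
        if outcome == 0:
            assigned.append(0)
        elif outcome <= len(ranks):
            rank = ranks[outcome - 1]
            pool = pools[rank]
            own_anc = db.rank_ancestor(truth_taxid, rank)
            pick = int(pool[int(rng.integers(len(pool)))])
            tries = 0
            while own_anc is not None and anc_of[rank][pick] == own_anc:
                pick = int(pool[int(rng.integers(len(pool)))])
                tries += 1
                if tries > 100:
                    candidates = [
                        sp for sp in pool if anc_of[rank][sp] != own_anc
                    ]
                    if not candidates:
                        raise ValueError(
                            f"no species with a different {rank} ancestor exists"
                        )
                    pick = int(candidates[int(rng.integers(len(candidates)))])
                    break
            assigned.append(pick)
        elif outcome == len(ranks) + 1:  # under-resolution
            path = db.path_to_root(truth_taxid)
            # Strict ancestors, root excluded (a root assignment carries no
            # taxonomic information at any canonical rank anyway).
            ancestors = [a for a in path[1:-1]] or [path[-1]]
            assigned.append(int(ancestors[int(rng.integers(len(ancestors)))]))
        elif outcome == len(ranks) + 2:  # over-resolution
            kids = db.children(truth_taxid)
            assigned.append(
                int(kids[int(rng.integers(len(kids)))]) if kids else truth_taxid
            )
        else:
            assigned.append(truth_taxid)

    return pd.DataFrame({"read_id": truth["read_id"].to_numpy(), "taxid": assigned})
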