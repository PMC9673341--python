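"""Shared fixtures: a hand-built 12-node taxonomy exercising every lineage
pathology, random-tree generators for property tests, and the
representative-database positive-control run (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest

import taxbench as tb
from taxbench.taxonomy import CANONICAL_RANKS, Taxon, TaxonomyDB


@pytest.fixture(scope="session")
def toy_db() -> TaxonomyDB:
    """Twelve nodes covering complete lineages, a species with no family or
    genus label (KHT7-style), and a species with family but no genus
    (RUG10048-style, informal name)."""
    taxa = [
        Taxon(1, 1, "no rank", "root"),
        Taxon(2, 1, "phylum", "Bacteroidota"),
        Taxon(3, 2, "class", "Bacteroidia"),
        Taxon(4, 3, "order", "Bacteroidales"),
        Taxon(5, 4, "family", "Ruminococcaceae"),
        Taxon(6, 5, "genus", "Kandleria"),
        Taxon(7, 6, "species", "Kandleria vitulina"),
        Taxon(8, 4, "species", "Bacteroidales bacterium KHT7"),
        Taxon(9, 5, "genus", "Prevotella"),
        Taxon(10, 9, "species", "Prevotella ruminicola"),
        Taxon(11, 5, "species", "Ruminococcaceae bacterium"),
        Taxon(12, 7, "strain", "Kandleria vitulina strain DSM"),
    ]
    return TaxonomyDB(taxa)


# Node roles in toy_db, for readable tests.
TOY = dict(
    root=1, phylum=2, klass=3, order=4, family=5,
    genus=6, full_species=7, kht7_species=8, genus2=9,
    full_species2=10, rug_species=11, strain=12,
)


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> TaxonomyDB:
    """Random rooted tree with a mix of canonical and non-canonical ranks."""
    ranks = list(CANONICAL_RANKS) + ["no rank", "strain", "clade"]
    taxa = [Taxon(1, 1, "no rank", "root")]
    for taxid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, taxid))
        rank = ranks[int(rng.integers(len(ranks)))]
        taxa.append(Taxon(taxid, parent, rank, f"node {taxid}"))
    return TaxonomyDB(taxa)


def oracle_path_to_root(db: TaxonomyDB, taxid: int) -> list[int]:
    """Independent parent-walk, bypassing the library's path cache."""
    path = [taxid]
    while db[path[-1]].parent_taxid != path[-1]:
        path.append(db[path[-1]].parent_taxid)
    return path


@pytest.fixture(scope="session")
def small_community():
    """A small complete-lineage community with reads and an index built
    from its own genomes."""
    cfg = tb.CommunityConfig(
        n_species=20,
        mean_genome_length=5_000,
        n_read_pairs=1_000,
        substitution_rate=0.0,
        seed=42,
    )
    db, species = tb.generate_taxonomy(cfg)
    genomes = tb.generate_genomes(db, species, cfg)
    sim = tb.simulate_reads(genomes, db, cfg)
    index = tb.build_index(genomes, db, k=21)
    return dict(cfg=cfg, db=db, species=species, genomes=genomes, sim=sim,
                index=index)


@pytest.fixture(scope="session")
def positive_control():
    """Fully representative database control: 100 complete-lineage species,
    50,000 error-free pairs classified against an index of exactly the
    source genomes."""
    cfg = tb.CommunityConfig(
        n_species=100,
        mean_genome_length=20_000,
        n_read_pairs=50_000,
        substitution_rate=0.0,
        abundance_model="exponential",
        seed=20_26,
    )
    db, species = tb.generate_taxonomy(cfg)
    genomes = tb.generate_genomes(db, species, cfg)
    sim = tb.simulate_reads(genomes, db, cfg)
    index = tb.build_index(genomes, db, k=21)
    records = tb.classify_pairs(index, db, sim.reads_r1, sim.reads_r2)
    from taxbench.kraken_io import records_to_frame

    summary = tb.evaluate(sim.truth, records_to_frame(records), db)
    return dict(cfg=cfg, db=db, sim=sim, records=records, summary=summary)
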