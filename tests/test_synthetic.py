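"""Generator properties: determinism, lineage-incompleteness fractions,
abundance distributions, read fidelity, and injected error structure."""

import numpy as np
import pytest
from scipy import stats

import taxbench as tb
from taxbench.synthetic import parse_genome_header, revcomp


def _config(**kw):
    defaults = dict(
        n_species=10, mean_genome_length=3_000, n_read_pairs=200,
        substitution_rate=0.0, seed=1,
    )
    defaults.update(kw)
    return tb.CommunityConfig(**defaults)


class TestConfigValidation:
    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            _config(n_species=0)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            _config(missing_genus_frac=1.5)

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            _config(read_length=5_000, mean_genome_length=3_000)


class TestGenerateTaxonomy:
    def test_complete_lineages_by_default(self):
        cfg = _config(n_species=30)
        db, species = tb.generate_taxonomy(cfg)
        rep = db.completeness_report(species)
        assert all(v == 0 for v in rep.missing_by_rank.values())
        assert rep.informal_name_count == 0

    def test_all_species_missing_genus_at_boundary(self):
        cfg = _config(n_species=25, missing_genus_frac=1.0)
        db, species = tb.generate_taxonomy(cfg)
        rep = db.completeness_report(species)
        assert rep.missing_by_rank["genus"] == 25

    def test_missing_fraction_recovered(self):
        # Binomial at n=200, p=0.5: 3 SE = 3 * sqrt(200*0.25) ~ 21.2
        cfg = _config(n_species=200, missing_genus_frac=0.5, seed=9)
        db, species = tb.generate_taxonomy(cfg)
        rep = db.completeness_report(species)
        assert abs(rep.missing_by_rank["genus"] - 100) <= 21.3

    def test_mag_like_fraction_recovered(self):
        # MAG-collection preset: 3849/4941 ~ 0.78 of species lack a genus.
        p = 3849 / 4941
        cfg = tb.CommunityConfig(
            n_species=500, mean_genome_length=3000, missing_genus_frac=p, seed=4
        )
        db, species = tb.generate_taxonomy(cfg)
        rep = db.completeness_report(species)
        se = np.sqrt(500 * p * (1 - p))
        assert abs(rep.missing_by_rank["genus"] - 500 * p) <= 3 * se

    def test_family_and_genus_independent(self):
        cfg = _config(
            n_species=300, missing_family_frac=0.3, missing_genus_frac=0.0,
            seed=2,
        )
        db, species = tb.generate_taxonomy(cfg)
        rep = db.completeness_report(species)
        # Dropping family never drops genus under independent draws.
        assert rep.missing_by_rank["genus"] == 0
        assert 90 - 3 * np.sqrt(300 * 0.21) <= rep.missing_by_rank["family"]

    def test_informal_names_flagged(self):
        cfg = _config(n_species=50, informal_species_frac=1.0)
        db, species = tb.generate_taxonomy(cfg)
        assert all(tb.is_informal_name(db[s].name) for s in species)

    def test_deterministic(self):
        a = tb.generate_taxonomy(_config(seed=5))
        b = tb.generate_taxonomy(_config(seed=5))
        assert a[0] == b[0] and a[1] == b[1]


class TestGenerateGenomes:
    def test_lengths_within_band(self):
        cfg = _config(n_species=3, mean_genome_length=1_000, read_length=100)
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        assert len(genomes) == 3
        assert all(800 <= len(g.seq) <= 1200 for g in genomes)

    def test_header_roundtrip(self):
        cfg = _config(n_species=3)
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        for rec, taxid in zip(genomes, species):
            parsed_taxid, name = parse_genome_header(rec.description)
            assert parsed_taxid == taxid
            assert name == db[taxid].name

    def test_deterministic(self):
        cfg = _config(seed=8)
        db, species = tb.generate_taxonomy(cfg)
        a = tb.generate_genomes(db, species, cfg)
        b = tb.generate_genomes(db, species, cfg)
        assert [str(x.seq) for x in a] == [str(x.seq) for x in b]

    def test_dinucleotide_uniformity(self):
        cfg = _config(n_species=1, mean_genome_length=100_000, seed=3)
        db, species = tb.generate_taxonomy(cfg)
        seq = str(tb.generate_genomes(db, species, cfg)[0].seq)
        counts = {}
        for i in range(len(seq) - 1):
            counts[seq[i:i+2]] = counts.get(seq[i:i+2], 0) + 1
        observed = [counts.get(a + b, 0) for a in "ACGT" for b in "ACGT"]
        assert stats.chisquare(observed).pvalue > 0.01


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        cfg = _config(n_species=1, n_read_pairs=10, read_length=50)
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        genome = str(genomes[0].seq)
        sim = tb.simulate_reads(genomes, db, cfg)
        for _, seq in sim.reads_r1:
            assert seq in genome
        for _, seq in sim.reads_r2:
            assert revcomp(seq) in genome

    def test_uniform_abundance_counts(self):
        cfg = _config(
            n_species=4, n_read_pairs=10_000, abundance_model="uniform",
            seed=13,
        )
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        sim = tb.simulate_reads(genomes, db, cfg)
        se = np.sqrt(10_000 * 0.25 * 0.75)
        for count in sim.genome_counts.values():
            assert abs(count - 2500) <= 3 * se

    def test_exponential_abundances_fit_qq_line(self):
        cfg = tb.CommunityConfig(
            n_species=100, mean_genome_length=2_000, n_read_pairs=100,
            abundance_model="exponential", seed=17, substitution_rate=0.0,
        )
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        sim = tb.simulate_reads(genomes, db, cfg)
        values = np.sort(np.array(list(sim.abundances.values())))
        n = len(values)
        theoretical = stats.expon.ppf((np.arange(1, n + 1) - 0.5) / n)
        r = stats.pearsonr(theoretical, values).statistic
        assert r**2 >= 0.9

    def test_truth_ids_match_fastq_ids(self):
        cfg = _config(n_read_pairs=50)
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        sim = tb.simulate_reads(genomes, db, cfg)
        r1_bases = {rid.rsplit("/", 1)[0] for rid, _ in sim.reads_r1}
        assert set(sim.truth["read_id"]) == r1_bases

    def test_truth_counts_aggregate_through_lineage(self):
        cfg = _config(
            n_species=40, n_read_pairs=500, missing_genus_frac=0.5, seed=21
        )
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        sim = tb.simulate_reads(genomes, db, cfg)
        # Species-level totals equal all pairs (species labels complete)...
        assert sum(sim.truth_counts["species"].values()) == cfg.n_read_pairs
        # ...while the genus-level shortfall is exactly the reads of
        # genus-less source genomes.
        genusless = sum(
            n for taxid, n in sim.genome_counts.items()
            if db.rank_ancestor(taxid, "genus") is None
        )
        assert (
            cfg.n_read_pairs - sum(sim.truth_counts["genus"].values())
            == genusless
        )

    def test_substitution_rate_perturbs_reads(self):
        cfg_clean = _config(n_species=1, n_read_pairs=200, seed=6)
        db, species = tb.generate_taxonomy(cfg_clean)
        genomes = tb.generate_genomes(db, species, cfg_clean)
        cfg_noisy = _config(
            n_species=1, n_read_pairs=200, seed=6, substitution_rate=0.05
        )
        noisy = tb.simulate_reads(genomes, db, cfg_noisy)
        genome = str(genomes[0].seq)
        mismatching = sum(
            1 for _, seq in noisy.reads_r1 if seq not in genome
        )
        # P(read untouched) = 0.95^150 ~ 5e-4; essentially all differ.
        assert mismatching >= 195

    def test_all_genomes_too_short_rejected(self):
        cfg = _config(n_species=2, mean_genome_length=3_000, read_length=150)
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        for rec in genomes:
            rec.seq = rec.seq[:50]
        with pytest.raises(ValueError, match="shorter than the read length"):
            tb.simulate_reads(genomes, db, cfg)

    def test_deterministic(self):
        cfg = _config(seed=99, substitution_rate=0.01)
        db, species = tb.generate_taxonomy(cfg)
        genomes = tb.generate_genomes(db, species, cfg)
        a = tb.simulate_reads(genomes, db, cfg)
        b = tb.simulate_reads(genomes, db, cfg)
        assert a.reads_r1 == b.reads_r1 and a.reads_r2 == b.reads_r2
        assert a.truth.equals(b.truth)


@pytest.fixture(scope="module")
def community():
    cfg = _config(n_species=30, n_read_pairs=2_000, seed=3)
    db, species = tb.generate_taxonomy(cfg)
    genomes = tb.generate_genomes(db, species, cfg)
    sim = tb.simulate_reads(genomes, db, cfg)
    return db, sim


class TestSimulateClassifierOutput:
    def test_identity_with_zero_errors(self, community):
        db, sim = community
        out = tb.simulate_classifier_output(sim.truth, db, tb.ErrorSpec(), seed=1)
        assert (out["taxid"].to_numpy() == sim.truth["taxid"].to_numpy()).all()

    def test_all_unclassified_at_boundary(self, community):
        db, sim = community
        spec = tb.ErrorSpec(unclassified_frac=1.0)
        out = tb.simulate_classifier_output(sim.truth, db, spec, seed=1)
        assert (out["taxid"] == 0).all()

    def test_under_resolution_assigns_strict_ancestors(self, community):
        db, sim = community
        spec = tb.ErrorSpec(under_resolution_frac=1.0)
        out = tb.simulate_classifier_output(sim.truth, db, spec, seed=2)
        for truth_taxid, assigned in zip(sim.truth["taxid"], out["taxid"]):
            path = db.path_to_root(int(truth_taxid))
            assert int(assigned) in path[1:]

    def test_over_resolution_assigns_descendants(self, community):
        db, sim = community
        spec = tb.ErrorSpec(over_resolution_frac=1.0)
        out = tb.simulate_classifier_output(sim.truth, db, spec, seed=2)
        for truth_taxid, assigned in zip(sim.truth["taxid"], out["taxid"]):
            assert int(truth_taxid) in db.path_to_root(int(assigned))
            assert int(assigned) != int(truth_taxid)

    def test_fractions_exceeding_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            tb.ErrorSpec(unclassified_frac=0.7, under_resolution_frac=0.5)

    def test_misassignment_changes_rank_ancestor(self, community):
        db, sim = community
        spec = tb.ErrorSpec(misassignment_frac={"genus": 1.0})
        out = tb.simulate_classifier_output(sim.truth, db, spec, seed=5)
        for truth_taxid, assigned in zip(sim.truth["taxid"], out["taxid"]):
            t_anc = db.rank_ancestor(int(truth_taxid), "genus")
            a_anc = db.rank_ancestor(int(assigned), "genus")
            assert a_anc is not None
            assert a_anc != t_anc

    def test_deterministic(self, community):
        db, sim = community
        spec = tb.ErrorSpec(
            unclassified_frac=0.2, misassignment_frac={"genus": 0.1},
            under_resolution_frac=0.15,
        )
        a = tb.simulate_classifier_output(sim.truth, db, spec, seed=7)
        b = tb.simulate_classifier_output(sim.truth, db, spec, seed=7)
        assert a.equals(b)
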