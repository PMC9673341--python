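"""Five-way status semantics, summary percentages, taxon-set FP/FN and
collection overlap."""

import numpy as np
import pandas as pd
import pytest

import taxbench as tb
from taxbench.evaluation import (
    ReadStatus,
    assign_status,
    collection_overlap,
    evaluate,
    taxon_set_comparison,
)

from conftest import TOY

# Hand-written canonical lineages of every toy_db node (rank -> ancestor
# taxid), independent of the library's path-walking code.
HAND_LINEAGES = {
    1: {},
    2: {"phylum": 2},
    3: {"phylum": 2, "class": 3},
    4: {"phylum": 2, "class": 3, "order": 4},
    5: {"phylum": 2, "class": 3, "order": 4, "family": 5},
    6: {"phylum": 2, "class": 3, "order": 4, "family": 5, "genus": 6},
    7: {"phylum": 2, "class": 3, "order": 4, "family": 5, "genus": 6,
        "species": 7},
    8: {"phylum": 2, "class": 3, "order": 4, "species": 8},
    9: {"phylum": 2, "class": 3, "order": 4, "family": 5, "genus": 9},
    10: {"phylum": 2, "class": 3, "order": 4, "family": 5, "genus": 9,
         "species": 10},
    11: {"phylum": 2, "class": 3, "order": 4, "family": 5, "species": 11},
    12: {"phylum": 2, "class": 3, "order": 4, "family": 5, "genus": 6,
         "species": 7},
}


def hand_status(truth: int, assigned: int, rank: str) -> ReadStatus:
    """The status cascade written out against the hand lineage table."""
    if rank not in HAND_LINEAGES[truth]:
        return ReadStatus.TRUTH_UNKNOWN
    if assigned == 0:
        return ReadStatus.UNCLASSIFIED_AT_ANY_LEVEL
    if rank not in HAND_LINEAGES[assigned]:
        return ReadStatus.UNCLASSIFIED_AT_THIS_LEVEL
    if HAND_LINEAGES[assigned][rank] == HAND_LINEAGES[truth][rank]:
        return ReadStatus.CORRECT
    return ReadStatus.INCORRECT


class TestAssignStatus:
    def test_truth_without_family_label_is_truth_unknown(self, toy_db):
        # Reads from a genome with no family label can never be scored at
        # family level, whatever the classifier did.
        for assigned in (0, TOY["full_species"], TOY["kht7_species"]):
            assert (
                assign_status(TOY["kht7_species"], assigned, "family", toy_db)
                is ReadStatus.TRUTH_UNKNOWN
            )

    def test_genusless_assignment_is_unclassified_at_genus(self, toy_db):
        # Truth has a genus; the assigned species carries family but no
        # genus node — classified elsewhere, unclassified at this level.
        status = assign_status(
            TOY["full_species"], TOY["rug_species"], "genus", toy_db
        )
        assert status is ReadStatus.UNCLASSIFIED_AT_THIS_LEVEL

    def test_identity_is_correct(self, toy_db):
        for rank in ("phylum", "family", "genus", "species"):
            assert (
                assign_status(TOY["full_species"], TOY["full_species"], rank, toy_db)
                is ReadStatus.CORRECT
            )

    def test_family_level_ancestor_assignment(self, toy_db):
        # Assigned the family node itself: correct at family, unclassified
        # at genus (the family node has no genus on its path).
        truth = TOY["full_species"]
        assert (
            assign_status(truth, TOY["family"], "family", toy_db)
            is ReadStatus.CORRECT
        )
        assert (
            assign_status(truth, TOY["family"], "genus", toy_db)
            is ReadStatus.UNCLASSIFIED_AT_THIS_LEVEL
        )

    def test_exhaustive_enumeration_matches_hand_table(self, toy_db):
        # Every (truth, assigned + unclassified, rank) triple on the
        # 12-node tree yields exactly the hand-derived status.
        for truth in range(1, 13):
            for assigned in range(0, 13):
                for rank in ("phylum", "family", "genus", "species"):
                    assert (
                        assign_status(truth, assigned, rank, toy_db)
                        is hand_status(truth, assigned, rank)
                    ), (truth, assigned, rank)


def _tables(pairs):
    truth = pd.DataFrame(
        {"read_id": [f"r{i}" for i in range(len(pairs))],
         "taxid": [t for t, _ in pairs]}
    )
    classified = pd.DataFrame(
        {"read_id": [f"r{i}" for i in range(len(pairs))],
         "taxid": [a for _, a in pairs]}
    )
    return truth, classified


class TestEvaluate:
    def test_percentages_sum_to_100(self, toy_db):
        pairs = [(7, 7), (7, 0), (8, 7), (10, 11), (11, 10), (7, 12)]
        truth, classified = _tables(pairs)
        summary = evaluate(truth, classified, toy_db)
        for rank in summary.ranks:
            assert sum(summary.status_percent[rank].values()) == pytest.approx(
                100.0, abs=1e-9
            )

    def test_overall_rate_complements_unclassified_any(self, toy_db):
        pairs = [(7, 7), (7, 0), (10, 0), (10, 10)]
        truth, classified = _tables(pairs)
        summary = evaluate(truth, classified, toy_db)
        assert summary.overall_classified_pct == pytest.approx(50.0)
        for rank in summary.ranks:
            # Truth lineages complete here, so the status-side unclassified
            # percentage matches the overall complement exactly.
            assert (
                summary.status_percent[rank][ReadStatus.UNCLASSIFIED_AT_ANY_LEVEL]
                == pytest.approx(100.0 - summary.overall_classified_pct)
            )

    def test_strain_assignment_projects_to_species(self, toy_db):
        truth, classified = _tables([(7, 12)])
        summary = evaluate(truth, classified, toy_db)
        assert summary.status_percent["species"][ReadStatus.CORRECT] == 100.0

    def test_read_order_invariance(self, toy_db):
        pairs = [(7, 7), (8, 0), (10, 11), (11, 7), (7, 10)]
        truth, classified = _tables(pairs)
        shuffled = classified.sample(frac=1.0, random_state=3)
        a = evaluate(truth, classified, toy_db)
        b = evaluate(truth, shuffled, toy_db)
        assert a.status_percent == b.status_percent

    def test_classified_read_missing_from_truth_rejected(self, toy_db):
        truth, classified = _tables([(7, 7)])
        classified = pd.concat(
            [classified, pd.DataFrame({"read_id": ["ghost"], "taxid": [7]})]
        )
        with pytest.raises(ValueError, match="ghost"):
            evaluate(truth, classified, toy_db)

    def test_truth_read_missing_from_classification_rejected(self, toy_db):
        truth, classified = _tables([(7, 7), (10, 10)])
        with pytest.raises(ValueError, match="missing"):
            evaluate(truth, classified.iloc[:1], toy_db)

    def test_hierarchical_consistency_on_complete_lineages(self, small_community):
        db, sim, index = (
            small_community["db"],
            small_community["sim"],
            small_community["index"],
        )
        from taxbench.kraken_io import records_to_frame

        records = tb.classify_pairs(index, db, sim.reads_r1, sim.reads_r2)
        classified = records_to_frame(records)
        merged = sim.truth.merge(
            classified, on="read_id", suffixes=("_t", "_a")
        )
        for t, a in zip(merged["taxid_t"], merged["taxid_a"]):
            if assign_status(int(t), int(a), "species", db) is ReadStatus.CORRECT:
                for rank in ("genus", "family", "phylum"):
                    assert (
                        assign_status(int(t), int(a), rank, db)
                        is ReadStatus.CORRECT
                    )

    def test_injected_rates_recovered_single_seed(self, toy_db):
        # 20k reads from the two complete-lineage species; inject 20%
        # unclassified, 10% genus misassignment, 15% under-resolution and
        # read the rates back off the status table.
        rng = np.random.default_rng(0)
        n = 20_000
        taxids = rng.choice([7, 10], size=n)
        truth = pd.DataFrame(
            {"read_id": [f"r{i}" for i in range(n)], "taxid": taxids}
        )
        spec = tb.ErrorSpec(
            unclassified_frac=0.20,
            misassignment_frac={"genus": 0.10},
            under_resolution_frac=0.15,
        )
        out = tb.simulate_classifier_output(truth, toy_db, spec, seed=1)
        summary = evaluate(truth, out, toy_db)
        se = lambda p: 100 * np.sqrt(p * (1 - p) / n)
        assert summary.status_percent["genus"][
            ReadStatus.UNCLASSIFIED_AT_ANY_LEVEL
        ] == pytest.approx(20.0, abs=3 * se(0.20))
        assert summary.status_percent["genus"][
            ReadStatus.INCORRECT
        ] == pytest.approx(10.0, abs=3 * se(0.10))
        assert summary.status_percent["species"][
            ReadStatus.UNCLASSIFIED_AT_THIS_LEVEL
        ] == pytest.approx(15.0, abs=3 * se(0.15))


class TestTaxonSetComparison:
    def test_identical_maps_no_fp_fn(self):
        counts = {6: 10, 9: 5}
        cmp = taxon_set_comparison(counts, dict(counts), "genus")
        assert cmp.n_false_positives == 0 and cmp.n_false_negatives == 0

    def test_extra_classified_taxon_is_fp(self):
        cmp = taxon_set_comparison({6: 10}, {6: 8, 9: 2}, "genus")
        assert cmp.false_positive_taxa == frozenset({9})

    def test_rank_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rank mismatch"):
            taxon_set_comparison({}, {}, "genus", classified_rank="family")

    def test_equals_set_difference_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            taxa = list(range(1, 30))
            truth = {t: int(rng.integers(0, 3)) for t in rng.choice(taxa, 10)}
            classified = {t: int(rng.integers(0, 3)) for t in rng.choice(taxa, 10)}
            cmp = taxon_set_comparison(truth, classified, "species")
            t_set = {t for t, c in truth.items() if c > 0}
            c_set = {t for t, c in classified.items() if c > 0}
            assert cmp.false_positive_taxa == c_set - t_set
            assert cmp.false_negative_taxa == t_set - c_set


class TestCollectionOverlap:
    def test_identical_collections(self, toy_db):
        members = [TOY["full_species"], TOY["full_species2"]]
        counts = collection_overlap(members, members, toy_db, "genus")
        assert counts.only_a == counts.only_b == 0
        assert counts.both == 2  # two distinct genera

    def test_label_less_members_dropped(self, toy_db):
        # KHT7-style member contributes nothing at genus level.
        counts = collection_overlap(
            [TOY["kht7_species"]], [TOY["full_species"]], toy_db, "genus"
        )
        assert counts.only_a == 0
        assert counts.only_b == 1
        assert counts.both == 0

    def test_matches_bruteforce_partition(self):
        cfg = tb.CommunityConfig(
            n_species=60, mean_genome_length=2000, missing_genus_frac=0.4,
            seed=15,
        )
        db, species = tb.generate_taxonomy(cfg)
        rng = np.random.default_rng(2)
        set_a = [int(s) for s in rng.choice(species, 25, replace=False)]
        set_b = [int(s) for s in rng.choice(species, 25, replace=False)]
        for rank in ("family", "genus"):
            counts = collection_overlap(set_a, set_b, db, rank)
            la = {db.rank_ancestor(t, rank) for t in set_a} - {None}
            lb = {db.rank_ancestor(t, rank) for t in set_b} - {None}
            assert counts.only_a == len(la - lb)
            assert counts.only_b == len(lb - la)
            assert counts.both == len(la & lb)
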