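"""Peptide→protein mapping, experiment construction, set algebra, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligandkit import (
    ExperimentSet,
    Tissue,
    build_experiment,
    group_by_metadata,
    map_peptide_to_protein,
    peptides_in_all,
    peptides_per_protein,
    peptides_union,
    proteins_in_all,
    proteins_union,
    top_n_proteins,
)

from conftest import make_db, make_table, synthetic_expset, synthetic_experiment


def naive_occurrences(peptide, protein):
    """Independent O(nm) scan oracle for substring intervals."""
    k = len(peptide)
    return [
        (i, i + k)
        for i in range(len(protein) - k + 1)
        if protein[i : i + k] == peptide
    ]


class TestMapPeptideToProtein:
    def test_single_occurrence(self):
        assert map_peptide_to_protein("KLV", "MKLVA") == [(1, 4)]

    def test_overlapping_occurrences_all_reported(self):
        assert map_peptide_to_protein("AA", "AAAA") == [(0, 2), (1, 3), (2, 4)]

    def test_no_match_is_empty_list(self):
        assert map_peptide_to_protein("WWW", "MKLVA") == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            map_peptide_to_protein("", "MKLV")

    @given(
        peptide=st.text(alphabet="AC", min_size=1, max_size=4),
        protein=st.text(alphabet="AC", min_size=1, max_size=40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_naive_scan(self, peptide, protein):
        assert map_peptide_to_protein(peptide, protein) == naive_occurrences(
            peptide, protein
        )

    def test_planted_peptides_recovered(self):
        rng = np.random.default_rng(11)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300))
        peptide = "WWYYWWYYW"
        planted_at = [10, 100, 250]
        seq = list(protein)
        for p in planted_at:
            seq[p : p + len(peptide)] = peptide
        seq = "".join(seq)
        assert map_peptide_to_protein(peptide, seq) == naive_occurrences(peptide, seq)


class TestBuildExperiment:
    def test_two_rows_two_proteins(self, tiny_db):
        table = make_table(("KLV", "P1"), ("ABC", "P2"))
        exp = build_experiment(table, tiny_db, "e")
        assert exp.n_peptides == 2
        assert exp.protein_accessions() == {"P1", "P2"}
        assert exp.peptides["KLV"].mappings == [("P1", 1, 4)]

    def test_shared_peptide_maps_to_both_proteins(self, tiny_db):
        exp = build_experiment(make_table(("KLV", "P1"), ("KLV", "P2")), tiny_db, "e")
        assert exp.peptides["KLV"].accessions() == {"P1", "P2"}

    def test_missing_accession_dropped_and_counted(self, tiny_db):
        exp = build_experiment(make_table(("KLV", "P1"), ("KLV", "P9")), tiny_db, "e")
        assert exp.drop_report["missing_accession"] == 1
        assert exp.protein_accessions() == {"P1"}

    def test_non_occurring_peptide_dropped(self, tiny_db):
        exp = build_experiment(make_table(("KLV", "P1"), ("WWW", "P1")), tiny_db, "e")
        assert exp.drop_report["no_match"] == 1
        assert exp.n_peptides == 1

    def test_zero_surviving_peptides_is_error(self, tiny_db):
        with pytest.raises(ValueError, match="no peptides survived"):
            build_experiment(make_table(("WWW", "P1")), tiny_db, "e")

    def test_trusted_coordinates_select_one_repeat_site(self):
        db = make_db(P1="AAKLVAAKLVAA")
        exp = build_experiment(make_table(("KLV", "P1", 7, 10)), db, "e")
        assert exp.peptides["KLV"].mappings == [("P1", 7, 10)]
        # without coordinates, both repeat sites are found
        exp2 = build_experiment(make_table(("KLV", "P1")), db, "e")
        assert exp2.peptides["KLV"].mappings == [("P1", 2, 5), ("P1", 7, 10)]

    def test_wrong_coordinates_fall_back_to_search(self):
        db = make_db(P1="AAKLVAA")
        exp = build_experiment(make_table(("KLV", "P1", 0, 3)), db, "e")
        assert exp.peptides["KLV"].mappings == [("P1", 2, 5)]

    def test_deterministic_and_row_order_invariant(self, tiny_db):
        rows = [("KLV", "P1"), ("ABC", "P2"), ("VAQ", "P1")]
        exp_a = build_experiment(make_table(*rows), tiny_db, "e")
        exp_b = build_experiment(make_table(*rows[::-1]), tiny_db, "e")
        assert exp_a == exp_b

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_planted_graph(self, seed):
        db, exp, truth = synthetic_experiment(seed)
        built_edges = {
            (pep.sequence, acc, s, e)
            for pep in exp.peptides.values()
            for acc, s, e in pep.mappings
        }
        assert set(truth.mappings) <= built_edges
        assert exp.peptide_sequences() == {m[0] for m in truth.mappings}


class TestSetAlgebra:
    def _set_of(self, peptide_lists, db):
        exps = [
            build_experiment(make_table(*[(p, "P1") for p in peps]), db, f"e{i}")
            for i, peps in enumerate(peptide_lists)
        ]
        return ExperimentSet.from_experiments(exps)

    def test_two_experiment_example(self):
        db = make_db(P1="AAABBBCCC")
        expset = self._set_of([["AAA", "BBB"], ["BBB", "CCC"]], db)
        assert peptides_in_all(expset) == {"BBB"}
        assert peptides_union(expset) == {"AAA", "BBB", "CCC"}

    def test_single_experiment_identity(self):
        db = make_db(P1="AAABBB")
        expset = self._set_of([["AAA", "BBB"]], db)
        assert peptides_in_all(expset) == peptides_union(expset) == {"AAA", "BBB"}

    def test_against_brute_force_over_synthetic_set(self):
        _, expset = synthetic_expset(5, base_seed=3)
        pep_sets = [e.peptide_sequences() for e in expset]
        prot_sets = [e.protein_accessions() for e in expset]
        assert peptides_in_all(expset) == set.intersection(*pep_sets)
        assert peptides_union(expset) == set.union(*pep_sets)
        assert proteins_in_all(expset) == set.intersection(*prot_sets)
        assert proteins_union(expset) == set.union(*prot_sets)


class TestGrouping:
    def _tagged(self, labels, key="site"):
        db = make_db(P1="AAABBB")
        exps = []
        for i, label in enumerate(labels):
            exp = build_experiment(make_table(("AAA", "P1")), db, f"e{i}")
            exp.metadata[key] = label
            exp.tissue = Tissue(name=label)
            exps.append(exp)
        return ExperimentSet.from_experiments(exps)

    def test_partition_by_tissue(self):
        groups = group_by_metadata(self._tagged(["lung", "lung", "colon"]), "tissue")
        assert {k: len(v) for k, v in groups.items()} == {"lung": 2, "colon": 1}

    def test_single_group_when_all_equal(self):
        assert len(group_by_metadata(self._tagged(["x", "x"]), "site")) == 1

    def test_missing_key_names_experiment(self):
        expset = self._tagged(["a", "b"])
        with pytest.raises(KeyError, match="e0"):
            group_by_metadata(expset, "absent")

    @pytest.mark.parametrize("seed", range(10))
    def test_group_sizes_sum_to_set_size(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"g{rng.integers(3)}" for _ in range(6)]
        expset = self._tagged(labels)
        groups = group_by_metadata(expset, "site")
        assert sum(len(g) for g in groups.values()) == len(expset)
        for value, group in groups.items():
            assert all(e.metadata["site"] == value for e in group)


class TestPeptidesPerProtein:
    def test_counts_and_top(self):
        db = make_db(P1="AAACCC", P2="CCCGGG")
        exp = build_experiment(
            make_table(("AAA", "P1"), ("CCC", "P1"), ("CCC", "P2")), db, "e"
        )
        # shared peptide CCC counted once per protein it maps to
        assert peptides_per_protein(exp) == {"P1": 2, "P2": 1}
        assert top_n_proteins(exp, 1) == [("P1", 2)]

    def test_ties_broken_by_accession(self):
        db = make_db(P2="AAA", P1="CCC")
        exp = build_experiment(make_table(("AAA", "P2"), ("CCC", "P1")), db, "e")
        assert top_n_proteins(exp, 2) == [("P1", 1), ("P2", 1)]

    def test_top_n_exceeding_protein_count_returns_all(self):
        db = make_db(P1="AAA")
        exp = build_experiment(make_table(("AAA", "P1")), db, "e")
        assert top_n_proteins(exp, 10) == [("P1", 1)]

    @pytest.mark.parametrize("seed", [0, 5])
    def test_recount_oracle_and_shared_peptide_inequality(self, seed):
        _, exp, _ = synthetic_experiment(seed)
        counts = peptides_per_protein(exp)
        brute = {acc: 0 for acc in exp.proteins}
        for pep in exp.peptides.values():
            for acc in {a for a, _, _ in pep.mappings}:
                brute[acc] += 1
        assert counts == brute
        n_shared = sum(1 for p in exp.peptides.values() if len(p.accessions()) > 1)
        assert sum(counts.values()) >= exp.n_peptides
        if n_shared == 0:
            assert sum(counts.values()) == exp.n_peptides


class TestGraphShape:
    def test_bipartite_edges_only_peptide_to_protein(self):
        _, exp, _ = synthetic_experiment(4)
        for pep in exp.peptides.values():
            for acc, start, end in pep.mappings:
                assert acc in exp.proteins
                assert exp.proteins[acc].sequence[start:end] == pep.sequence
        # every inferred protein carries at least one peptide
        mapped = {a for p in exp.peptides.values() for a in p.accessions()}
        assert mapped == exp.protein_accessions()
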