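"""Coverage arrays, the L1 coverage distance, and its metric properties."""

import numpy as np
import pytest

from ligandkit import (
    CoverageArray,
    ExperimentSet,
    build_experiment,
    compute_coverage,
    coverage_color_scale,
    distance_matrix,
    experiment_distance,
    n_coverage_table,
    protein_coverage_distance,
)

from conftest import make_db, make_table, synthetic_expset, synthetic_experiment


def brute_force_coverage(exp, accession):
    """Independent per-cell recount from the experiment's peptide mappings."""
    length = exp.proteins[accession].length
    cells = [0] * length
    for pep in exp.peptides.values():
        for acc, start, end in pep.mappings:
            if acc == accession:
                for i in range(start, end):
                    cells[i] += 1
    return cells


class TestComputeCoverage:
    def test_overlap_example(self):
        db = make_db(PX="ABCDEF")
        exp = build_experiment(make_table(("ABC", "PX"), ("CDE", "PX")), db, "e")
        assert compute_coverage(exp, "PX").values.tolist() == [1, 1, 2, 1, 1, 0]

    def test_repeated_occurrence_counts_per_site(self):
        db = make_db(PX="KLVAAKLVA")
        exp = build_experiment(make_table(("KLV", "PX")), db, "e")
        assert compute_coverage(exp, "PX").values.tolist() == [1, 1, 1, 0, 0, 1, 1, 1, 0]

    def test_unknown_accession_is_error(self, tiny_db):
        exp = build_experiment(make_table(("KLV", "P1")), tiny_db, "e")
        with pytest.raises(KeyError):
            compute_coverage(exp, "P2")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_per_cell_oracle_and_conservation(self, seed):
        _, exp, _ = synthetic_experiment(seed, n_peptides=100)
        for acc in exp.proteins:
            cov = compute_coverage(exp, acc)
            assert cov.values.tolist() == brute_force_coverage(exp, acc)
            occ_lengths = sum(
                e - s
                for pep in exp.peptides.values()
                for a, s, e in pep.mappings
                if a == acc
            )
            assert cov.total == occ_lengths


class TestProteinCoverageDistance:
    def test_elementwise_example(self):
        c1 = CoverageArray("P", np.array([1, 1, 0, 0]))
        c2 = CoverageArray("P", np.array([0, 1, 1, 0]))
        assert protein_coverage_distance(c1, c2) == 2

    def test_identity(self):
        c = CoverageArray("P", np.array([3, 0, 2]))
        assert protein_coverage_distance(c, c) == 0

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            protein_coverage_distance(
                CoverageArray("P", np.array([1])), CoverageArray("P", np.array([1, 2]))
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_random_arrays_match_elementwise_sum(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.integers(0, 10, (2, 50))
        d = protein_coverage_distance(CoverageArray("P", a), CoverageArray("P", b))
        assert d == sum(abs(int(x) - int(y)) for x, y in zip(a, b))


class TestExperimentDistance:
    def test_identical_experiments_distance_zero(self, tiny_db):
        e1 = build_experiment(make_table(("KLV", "P1")), tiny_db, "a")
        e2 = build_experiment(make_table(("KLV", "P1")), tiny_db, "b")
        assert experiment_distance(e1, e2) == 0.0

    def test_absent_protein_contributes_zero_array(self):
        db = make_db(P="KLVA", Q="WWWW")
        e1 = build_experiment(make_table(("KL", "P")), db, "a")  # covers [1,1,0,0]
        e2 = build_experiment(make_table(("WW", "Q")), db, "b")
        assert experiment_distance(e1, e2, protein_universe={"P"}) == 2.0

    def test_flat_vector_oracle(self):
        _, expset = synthetic_expset(5, base_seed=17)
        exps = list(expset)
        universe = sorted(set.union(*[e.protein_accessions() for e in exps]))
        lengths = {}
        for e in exps:
            for acc, prot in e.proteins.items():
                lengths[acc] = prot.length

        def flat(e):
            parts = []
            for acc in universe:
                if acc in e.proteins:
                    parts.extend(compute_coverage(e, acc).values.tolist())
                else:
                    parts.extend([0] * lengths[acc])
            return np.array(parts)

        for i in range(len(exps)):
            for j in range(len(exps)):
                expected = np.abs(flat(exps[i]) - flat(exps[j])).sum() / len(universe)
                got = experiment_distance(exps[i], exps[j], universe)
                assert got == pytest.approx(expected)

    def test_inconsistent_protein_length_is_error(self):
        db1 = make_db(P="KLVA")
        db2 = make_db(P="KLVAAA")
        e1 = build_experiment(make_table(("KL", "P")), db1, "a")
        e2 = build_experiment(make_table(("KL", "P")), db2, "b")
        with pytest.raises(ValueError, match="different lengths"):
            experiment_distance(e1, e2)


class TestDistanceMatrix:
    def test_identical_experiments_all_zero(self, tiny_db):
        e1 = build_experiment(make_table(("KLV", "P1")), tiny_db, "a")
        e2 = build_experiment(make_table(("KLV", "P1")), tiny_db, "b")
        dm = distance_matrix(ExperimentSet.from_experiments([e1, e2]))
        assert dm.d.tolist() == [[0, 0], [0, 0]]

    def test_metric_axioms_on_synthetic_set(self):
        _, expset = synthetic_expset(4, base_seed=23)
        dm = distance_matrix(expset)
        n = len(dm.names)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-9

    def test_relabeling_invariance(self):
        db, expset = synthetic_expset(3, base_seed=31)
        dm = distance_matrix(expset)
        perm = [2, 0, 1]
        reordered = ExperimentSet.from_experiments(
            [expset[expset.names[i]] for i in perm]
        )
        dm2 = distance_matrix(reordered)
        for a, i in enumerate(perm):
            for b, j in enumerate(perm):
                assert dm2.d[a, b] == pytest.approx(dm.d[i, j])

    def test_universe_recorded(self):
        _, expset = synthetic_expset(3, base_seed=5)
        dm = distance_matrix(expset)
        union = set.union(*[e.protein_accessions() for e in expset])
        assert set(dm.protein_universe) == union


class TestNCoverageTable:
    def test_single_experiment_reduces_to_compute_coverage(self, tiny_db):
        exp = build_experiment(make_table(("KLV", "P1")), tiny_db, "a")
        table = n_coverage_table(ExperimentSet.from_experiments([exp]), "P1")
        assert table.loc["a"].tolist() == compute_coverage(exp, "P1").values.tolist()

    def test_shape_and_zero_rows(self):
        db = make_db(P="KLVA", Q="WWWW")
        e1 = build_experiment(make_table(("KL", "P")), db, "a")
        e2 = build_experiment(make_table(("WW", "Q")), db, "b")
        table = n_coverage_table(ExperimentSet.from_experiments([e1, e2]), "P")
        assert table.shape == (2, 4)
        assert table.loc["b"].tolist() == [0, 0, 0, 0]

    def test_row_sums_equal_occurrence_length_sums(self):
        _, expset = synthetic_expset(3, base_seed=41)
        acc = sorted(next(iter(expset)).proteins)[0]
        table = n_coverage_table(expset, acc)
        for exp in expset:
            expected = sum(
                e - s
                for pep in exp.peptides.values()
                for a, s, e in pep.mappings
                if a == acc
            )
            assert table.loc[exp.name].sum() == expected

    def test_unknown_accession_is_error(self, tiny_db):
        exp = build_experiment(make_table(("KLV", "P1")), tiny_db, "a")
        with pytest.raises(KeyError):
            n_coverage_table(ExperimentSet.from_experiments([exp]), "NOPE")


class TestColorScale:
    def test_max_normalization(self):
        assert coverage_color_scale(CoverageArray("P", np.array([0, 27]))).tolist() == [
            0.0,
            1.0,
        ]

    def test_all_zero_stays_zero(self):
        assert coverage_color_scale(CoverageArray("P", np.zeros(4, int))).tolist() == [
            0.0
        ] * 4

    def test_scale_invariance(self):
        values = np.array([0, 1, 3, 9])
        base = coverage_color_scale(CoverageArray("P", values))
        scaled = coverage_color_scale(CoverageArray("P", 4 * values))
        assert np.allclose(base, scaled)

    def test_monotone_in_coverage(self):
        scale = coverage_color_scale(CoverageArray("P", np.array([0, 2, 5, 5])))
        assert scale[0] < scale[1] < scale[2] == scale[3] == 1.0
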