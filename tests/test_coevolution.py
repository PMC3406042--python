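import numpy as np
import pytest

from ppicontext.coevolution import (
    DistanceMatrix,
    coevolution_score,
    common_submatrix,
    correct_matrix,
    genome_distance_from_table,
    genome_distance_matrix,
    matrix_correlation,
    msa_to_distance_matrix,
    scaling_factor,
)
from ppicontext.orthology import OrthologTable


def _dm(labels, values, kind="protein"):
    return DistanceMatrix(tuple(labels), np.array(values, dtype=float), kind)


def _random_dm(rng, labels, scale=1.0, kind="protein"):
    n = len(labels)
    raw = rng.uniform(0.05, scale, size=(n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 0.0)
    return _dm(labels, values, kind)


class TestMsaDistances:
    def test_identical_sequences_have_zero_distance(self):
        dm = msa_to_distance_matrix([("g1", "ACDE"), ("g2", "ACDE")])
        assert dm.values[0, 1] == 0.0

    def test_p_distance_counts_mismatched_columns(self):
        dm = msa_to_distance_matrix([("g1", "AAAA"), ("g2", "AATT")])
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_gapped_columns_are_excluded_pairwise(self):
        dm = msa_to_distance_matrix([("g1", "AA-A"), ("g2", "ATTA")])
        # columns 1,2,4 vs gap at 3 -> compare AAT/ATA over cols 1,2,4: mism 1 of 3
        assert dm.values[0, 1] == pytest.approx(1 / 3)

    def test_zero_overlap_pair_is_an_error_naming_the_pair(self):
        with pytest.raises(ValueError, match="g1.*g2"):
            msa_to_distance_matrix([("g1", "AA--"), ("g2", "--TT")])

    def test_kimura_correction_applies_formula(self):
        dm_p = msa_to_distance_matrix([("g1", "AAAAAAAAAA"), ("g2", "AAAAAAAATT")])
        dm_k = msa_to_distance_matrix(
            [("g1", "AAAAAAAAAA"), ("g2", "AAAAAAAATT")], model="kimura"
        )
        p = dm_p.values[0, 1]
        assert dm_k.values[0, 1] == pytest.approx(-np.log(1 - p - p * p / 5))

    def test_full_matrix_matches_pairwise_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACDG-"), size=30)) for _ in range(4)]
        msa = [(f"g{i}", s) for i, s in enumerate(seqs)]
        dm = msa_to_distance_matrix(msa)
        for i in range(4):
            for j in range(i + 1, 4):
                both = [
                    (a, b)
                    for a, b in zip(seqs[i], seqs[j])
                    if a != "-" and b != "-"
                ]
                expected = sum(a != b for a, b in both) / len(both)
                assert dm.values[i, j] == pytest.approx(expected)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            msa_to_distance_matrix([("a", "AC"), ("b", "AC")], model="jtt")


class TestCommonSubmatrix:
    def test_identical_label_sets_pass_through(self, rng):
        # zero-padded labels: sorted intersection order == input order
        dm1 = _random_dm(rng, [f"g{i:02d}" for i in range(16)])
        dm2 = _random_dm(rng, [f"g{i:02d}" for i in range(16)])
        sub1, sub2 = common_submatrix(dm1, dm2)
        np.testing.assert_array_equal(sub1.values, dm1.values)
        np.testing.assert_array_equal(sub2.values, dm2.values)

    def test_overlap_below_minimum_signals_insufficient(self, rng):
        dm1 = _random_dm(rng, [f"g{i}" for i in range(14)])
        dm2 = _random_dm(rng, [f"g{i}" for i in range(14)])
        assert common_submatrix(dm1, dm2, min_common=15) is None
        assert common_submatrix(dm1, dm2, min_common=14) is not None

    def test_intersection_matches_index_oracle(self, rng):
        labels1 = [f"g{i:02d}" for i in range(25)]
        labels2 = [f"g{i:02d}" for i in range(5, 30)]
        dm1 = _random_dm(rng, labels1)
        dm2 = _random_dm(rng, labels2)
        sub1, sub2 = common_submatrix(dm1, dm2, min_common=2)
        shared = sorted(set(labels1) & set(labels2))
        assert list(sub1.labels) == shared == list(sub2.labels)
        for a in shared[:5]:
            for b in shared[:5]:
                i1, j1 = labels1.index(a), labels1.index(b)
                assert sub1.values[shared.index(a), shared.index(b)] == dm1.values[i1, j1]


class TestMatrixCorrelation:
    def test_identical_matrices_correlate_one(self, rng):
        dm = _random_dm(rng, list("abcdef"))
        assert matrix_correlation(dm, dm) == pytest.approx(1.0)

    def test_affine_transform_preserves_correlation(self, rng):
        dm = _random_dm(rng, list("abcdef"))
        scaled = _dm(dm.labels, 3.0 * dm.values + 0.1 * (1 - np.eye(6)))
        assert matrix_correlation(dm, scaled) == pytest.approx(1.0)

    def test_matches_flattened_upper_triangle_pcc(self, rng):
        dm1 = _random_dm(rng, list("abcdef"))
        dm2 = _random_dm(rng, list("abcdef"))
        iu = np.triu_indices(6, k=1)
        expected = np.corrcoef(dm1.values[iu], dm2.values[iu])[0, 1]
        assert matrix_correlation(dm1, dm2) == pytest.approx(expected, abs=1e-12)

    def test_constant_triangle_has_no_score(self):
        const = _dm("abc", 0.3 * (1 - np.eye(3)))
        varying = _dm("abc", [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        assert matrix_correlation(const, varying) is None

    def test_label_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            matrix_correlation(_random_dm(rng, "abc"), _random_dm(rng, "abd"))


class TestGenomeDistance:
    def test_identical_fully_shared_proteomes_have_zero_distance(self):
        dm = genome_distance_matrix({"A": 500, "B": 500}, {("A", "B"): 500})
        assert dm.values[0, 1] == 0.0

    def test_disjoint_proteomes_have_distance_one(self):
        dm = genome_distance_matrix({"A": 10, "B": 20}, {("A", "B"): 0})
        assert dm.values[0, 1] == 1.0

    def test_arithmetic_example(self):
        dm = genome_distance_matrix({"A": 800, "B": 600}, {("A", "B"): 400})
        assert dm.values[0, 1] == pytest.approx(1 - 400 / 1000)

    def test_missing_pair_count_is_an_error(self):
        with pytest.raises(KeyError):
            genome_distance_matrix({"A": 10, "B": 10, "C": 10}, {("A", "B"): 5})

    def test_from_table_matches_set_arithmetic(self, toy_table):
        dm = genome_distance_from_table(toy_table)
        sets = {g: toy_table.ortholog_set(g) for g in dm.labels}
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    expected = 1 - len(sets[a] & sets[b]) / len(sets[a] | sets[b])
                    assert dm.values[i, j] == pytest.approx(expected)


class TestScalingFactor:
    def test_reference_identical_to_a_family_gives_one(self, rng):
        ref = _random_dm(rng, [f"g{i}" for i in range(16)], kind="rrna")
        others = [_random_dm(rng, ref.labels) for _ in range(3)]
        assert scaling_factor(ref, [others[0], ref, others[1]]) == pytest.approx(1.0)

    def test_equals_max_of_individual_correlations(self, rng):
        labels = [f"g{i}" for i in range(16)]
        ref = _random_dm(rng, labels, kind="rrna")
        families = [_random_dm(rng, labels) for _ in range(5)]
        expected = max(matrix_correlation(ref, fam) for fam in families)
        assert scaling_factor(ref, families) == pytest.approx(expected)

    def test_no_eligible_family_raises(self, rng):
        ref = _random_dm(rng, [f"g{i}" for i in range(16)], kind="rrna")
        small = _random_dm(rng, [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            scaling_factor(ref, [small], min_common=15)


class TestCorrectMatrix:
    def test_reference_equal_to_matrix_zeroes_it(self, rng):
        dm = _random_dm(rng, list("abcd"))
        ref = _dm(dm.labels, dm.values, kind="rrna")
        corrected = correct_matrix(dm, ref, factor=0.7)
        np.testing.assert_allclose(corrected.values, 0.0)

    def test_zero_reference_and_unit_factor_is_identity(self, rng):
        dm = _random_dm(rng, list("abcd"))
        ref = _dm(dm.labels, np.zeros((4, 4)), kind="rrna")
        np.testing.assert_allclose(correct_matrix(dm, ref, 1.0).values, dm.values)

    def test_elementwise_arithmetic(self, rng):
        dm = _random_dm(rng, list("abcd"))
        ref = _random_dm(rng, list("abcde"), kind="rrna")
        corrected = correct_matrix(dm, ref, 0.5)
        expected = (dm.values - ref.restrict(dm.labels).values) / 0.5
        np.testing.assert_allclose(corrected.values, expected)

    def test_uncovered_labels_rejected(self, rng):
        dm = _random_dm(rng, list("abcd"))
        ref = _random_dm(rng, list("abc"), kind="rrna")
        with pytest.raises(ValueError):
            correct_matrix(dm, ref, 1.0)


class TestCoevolutionScore:
    def test_matrices_from_same_tree_score_one(self, rng):
        dm = _random_dm(rng, [f"g{i}" for i in range(16)])
        assert coevolution_score(dm, dm) == pytest.approx(1.0)

    def test_tol_with_reference_equal_to_both_matrices_is_degenerate(self, rng):
        dm = _random_dm(rng, [f"g{i}" for i in range(16)])
        ref = _dm(dm.labels, dm.values, kind="rrna")
        assert coevolution_score(dm, dm, variant="tol", ref=ref, factor=0.8) is None

    def test_tol_with_zero_reference_and_unit_factor_equals_mirrortree(self, rng):
        labels = [f"g{i}" for i in range(16)]
        dm1, dm2 = _random_dm(rng, labels), _random_dm(rng, labels)
        ref = _dm(labels, np.zeros((16, 16)), kind="rrna")
        plain = coevolution_score(dm1, dm2)
        tol = coevolution_score(dm1, dm2, variant="tol", ref=ref, factor=1.0)
        assert tol == pytest.approx(plain, abs=1e-12)

    def test_insufficient_overlap_gives_none(self, rng):
        dm1 = _random_dm(rng, [f"g{i}" for i in range(10)])
        dm2 = _random_dm(rng, [f"g{i}" for i in range(5, 15)])
        assert coevolution_score(dm1, dm2, min_common=15) is None

    def test_score_symmetric_in_pair(self, rng):
        labels = [f"g{i}" for i in range(16)]
        dm1, dm2 = _random_dm(rng, labels), _random_dm(rng, labels)
        assert coevolution_score(dm1, dm2) == pytest.approx(
            coevolution_score(dm2, dm1), abs=1e-12
        )


class TestDistanceMatrixIO:
    def test_phylip_round_trip(self, rng, tmp_path):
        dm = _random_dm(rng, [f"g{i}" for i in range(6)])
        path = tmp_path / "dm.phylip"
        dm.to_phylip(path)
        loaded = DistanceMatrix.from_phylip(path)
        assert loaded.labels == dm.labels
        np.testing.assert_allclose(loaded.values, dm.values, atol=1e-6)

    def test_tsv_round_trip(self, rng, tmp_path):
        dm = _random_dm(rng, [f"g{i}" for i in range(5)])
        path = tmp_path / "dm.tsv"
        dm.to_tsv(path)
        loaded = DistanceMatrix.from_tsv(path)
        np.testing.assert_allclose(loaded.values, dm.values)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            _dm("ab", [[0.0, 0.5], [0.4, 0.0]])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            _dm("ab", [[0.1, 0.5], [0.5, 0.0]])
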