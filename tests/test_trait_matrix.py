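"""Trait tables, Jaccard counts/matrices and the off-diagonal vectorization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import jaccard as scipy_jaccard

from culturedrift import (
    Code,
    JaccardCounts,
    MissingPolicy,
    PairwiseMatrix,
    Polarity,
    TraitTable,
    jaccard_counts,
    jaccard_matrix,
    offdiag_vector,
    read_pairwise_csv,
    read_trait_table,
    write_pairwise_csv,
    write_trait_table,
)

from conftest import jaccard_bruteforce, random_trait_table

P, A, Q = int(Code.PRESENT), int(Code.ABSENT), int(Code.QUESTIONABLE)


# ---------------------------------------------------------------- containers

class TestTraitTable:
    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate group"):
            TraitTable(["x", "x"], ["t1"], np.zeros((2, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="duplicate trait"):
            TraitTable(["x", "y"], ["t", "t"], np.zeros((2, 2), dtype=np.int8))

    def test_rejects_bad_code_and_shape(self):
        with pytest.raises(ValueError, match="invalid cell code"):
            TraitTable(["x", "y"], ["t1"], np.array([[3], [0]], dtype=np.int8))
        with pytest.raises(ValueError, match="inconsistent"):
            TraitTable(["x", "y"], ["t1"], np.zeros((2, 2), dtype=np.int8))

    def test_csv_round_trip(self, rng, tmp_path):
        table = random_trait_table(rng, 9, 82)
        path = tmp_path / "traits.csv"
        write_trait_table(table, path)
        back = read_trait_table(path)
        assert back.group_labels == table.group_labels
        assert back.trait_labels == table.trait_labels
        assert np.array_equal(back.cells, table.cells)

    def test_read_maps_codes_and_errors(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("group,t1,t2\na,1,0\nb,?,1\n")
        table = read_trait_table(path)
        assert table.cells[1, 0] == Q and table.cells[0, 0] == P
        path.write_text("group,t1\na,2\n")
        with pytest.raises(ValueError, match="unmappable cell '2'"):
            read_trait_table(path)
        path.write_text("group\n")
        with pytest.raises(ValueError, match="no data"):
            read_trait_table(path)


class TestPairwiseMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="not symmetric"):
            PairwiseMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="negative"):
            PairwiseMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            PairwiseMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))

    def test_reorder_and_as_distance(self):
        m = PairwiseMatrix(
            ["a", "b", "c"],
            np.array([[100.0, 80, 5], [80, 100, 50], [5, 50, 100]]),
            Polarity.SIMILARITY,
        )
        r = m.reorder(["c", "a", "b"])
        assert r.values[0, 1] == m.values[0, 2]
        d = m.as_distance(scale=100.0)
        assert d.polarity is Polarity.DISTANCE
        assert d.values[0, 2] == 95.0 and d.values[0, 0] == 0.0

    def test_csv_round_trip_keeps_polarity(self, tmp_path, rng):
        from conftest import random_distance_matrix

        m = random_distance_matrix(rng, 5)
        path = tmp_path / "m.csv"
        write_pairwise_csv(m, path)
        back = read_pairwise_csv(path)
        assert back.labels == m.labels
        assert back.polarity is Polarity.DISTANCE
        np.testing.assert_allclose(back.values, m.values)

    def test_plain_square_csv_accepted(self, tmp_path):
        path = tmp_path / "dep.csv"
        path.write_text("group,a,b\na,0,0.4\nb,0.4,0\n")
        m = read_pairwise_csv(path)
        assert m.values[0, 1] == 0.4 and m.polarity is Polarity.DISTANCE


# ------------------------------------------------------------------ counting

@pytest.mark.parametrize(
    "x, y, policy, expected",
    [
        ([P, P, A, P], [P, A, A, P], MissingPolicy.PAIRWISE_DELETE, (2, 1, 0, 1, 0)),
        ([P, Q, A], [P, P, P], MissingPolicy.PAIRWISE_DELETE, (1, 0, 1, 0, 1)),
        ([P, Q, A], [P, P, P], MissingPolicy.RECODE_PRESENT, (2, 0, 1, 0, 0)),
        ([Q, Q], [Q, A], MissingPolicy.PAIRWISE_DELETE, (0, 0, 0, 0, 2)),
    ],
)
def test_jaccard_counts_policies(x, y, policy, expected):
    counts = jaccard_counts(np.array(x), np.array(y), policy)
    assert (counts.a, counts.b, counts.c, counts.d, counts.n_deleted) == expected
    assert counts.total == len(x)


def test_jaccard_counts_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        jaccard_counts(np.array([P, A]), np.array([P]))


def test_jaccard_counts_undefined_similarity():
    counts = JaccardCounts(a=0, b=0, c=0, d=4)
    with pytest.raises(ZeroDivisionError):
        counts.similarity


@given(
    st.lists(
        st.tuples(st.sampled_from([P, A, Q]), st.sampled_from([P, A, Q])),
        min_size=1,
        max_size=60,
    ),
    st.sampled_from(list(MissingPolicy)),
)
def test_jaccard_counts_match_bruteforce(pairs, policy):
    x = np.array([p[0] for p in pairs], dtype=np.int8)
    y = np.array([p[1] for p in pairs], dtype=np.int8)
    counts = jaccard_counts(x, y, policy)
    a, b, c, d, deleted = jaccard_bruteforce(
        x, y, pairwise_delete=(policy is MissingPolicy.PAIRWISE_DELETE)
    )
    assert (counts.a, counts.b, counts.c, counts.d, counts.n_deleted) == (
        a, b, c, d, deleted,
    )


# ------------------------------------------------------------------ matrices

class TestJaccardMatrix:
    def test_identity_disjoint_and_formula(self):
        cells = np.array(
            [
                [P, P, A, A],   # identical to row 1
                [P, P, A, A],
                [A, A, P, P],   # disjoint from rows 0-1
                [P, P, P, A],   # vs row 0: a=2 b=0 c=1
            ],
            dtype=np.int8,
        )
        t = TraitTable(list("wxyz"), ["t1", "t2", "t3", "t4"], cells)
        m = jaccard_matrix(t)
        assert m.values[0, 1] == 0.0
        assert m.values[0, 2] == 1.0
        assert m.values[0, 3] == pytest.approx(1 - 2 / 3)

    def test_halfway_formula(self):
        # a=2, b=1, c=1 -> S = 0.5, D = 0.5
        cells = np.array([[P, P, P, A], [P, P, A, P]], dtype=np.int8)
        t = TraitTable(["u", "v"], list("abcd"), cells)
        m = jaccard_matrix(t, polarity=Polarity.SIMILARITY)
        assert m.values[0, 1] == 0.5
        assert jaccard_matrix(t).values[0, 1] == 0.5

    def test_matches_bruteforce_all_pairs(self, rng):
        t = random_trait_table(rng, 9, 82)
        for policy in MissingPolicy:
            m = jaccard_matrix(t, policy)
            for i in range(9):
                for j in range(i + 1, 9):
                    a, b, c, _, _ = jaccard_bruteforce(
                        t.cells[i], t.cells[j],
                        pairwise_delete=(policy is MissingPolicy.PAIRWISE_DELETE),
                    )
                    assert m.values[i, j] == pytest.approx(1 - a / (a + b + c))

    def test_matches_scipy_when_binary(self, rng):
        cells = (rng.random((6, 40)) < 0.5).astype(np.int8)
        t = TraitTable([f"g{i}" for i in range(6)], [f"t{j}" for j in range(40)], cells)
        m = jaccard_matrix(t)
        for i in range(6):
            for j in range(i + 1, 6):
                assert m.values[i, j] == pytest.approx(
                    scipy_jaccard(cells[i].astype(bool), cells[j].astype(bool))
                )

    def test_policies_agree_without_questionables(self, rng):
        t = random_trait_table(rng, 7, 50, p_questionable=0.0)
        m1 = jaccard_matrix(t, MissingPolicy.PAIRWISE_DELETE)
        m2 = jaccard_matrix(t, MissingPolicy.RECODE_PRESENT)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_invariant_to_joint_absence_columns(self, rng):
        t = random_trait_table(rng, 6, 30, p_questionable=0.0)
        padded = TraitTable(
            list(t.group_labels),
            list(t.trait_labels) + ["pad1", "pad2"],
            np.hstack([t.cells, np.zeros((6, 2), dtype=np.int8)]),
        )
        np.testing.assert_allclose(
            jaccard_matrix(t).values, jaccard_matrix(padded).values
        )

    def test_row_reorder_consistency(self, rng):
        t = random_trait_table(rng, 6, 40)
        order = ["g3", "g0", "g5", "g1", "g4", "g2"]
        direct = jaccard_matrix(t.reorder_groups(order))
        reordered = jaccard_matrix(t).reorder(order)
        np.testing.assert_allclose(direct.values, reordered.values)

    def test_no_shared_scorable_presences_raises(self):
        cells = np.array([[Q, A], [P, Q]], dtype=np.int8)
        t = TraitTable(["u", "v"], ["t1", "t2"], cells)
        with pytest.raises(ValueError, match=r"\('u', 'v'\)"):
            jaccard_matrix(t)

    def test_distance_bounds_and_symmetry(self, rng):
        m = jaccard_matrix(random_trait_table(rng, 8, 60))
        v = m.offdiag()
        assert ((v >= 0) & (v <= 1)).all()
        np.testing.assert_array_equal(m.values, m.values.T)


# -------------------------------------------------------------- vectorization

def test_offdiag_order_and_length(rng):
    m = PairwiseMatrix(
        ["a", "b", "c"],
        np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]]),
    )
    np.testing.assert_array_equal(offdiag_vector(m), [1.0, 2.0, 3.0])
    from conftest import random_distance_matrix

    m9 = random_distance_matrix(rng, 9)
    assert offdiag_vector(m9).size == 36


def test_offdiag_deterministic_under_same_label_order(rng):
    from conftest import random_distance_matrix

    m = random_distance_matrix(rng, 5)
    other = PairwiseMatrix(list(m.labels), m.values.copy())
    np.testing.assert_array_equal(offdiag_vector(m), offdiag_vector(other))
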