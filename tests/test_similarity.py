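import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import sw_score_dp
from pktarget import GeneratorConfig, generate
from pktarget.io_formats import LabeledMatrix, SequenceSet
from pktarget.similarity import (
    average_similarity,
    normalized_sequence_similarity,
    pearson_similarity,
    protein_expression_profiles,
    smith_waterman_score,
    tanimoto_similarity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def lm(values, prefix_r="c", prefix_c="f"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return LabeledMatrix(
        [f"{prefix_r}{i}" for i in range(values.shape[0])],
        [f"{prefix_c}{j}" for j in range(values.shape[1])],
        values,
    )


class TestPearson:
    def test_perfect_linear(self):
        s = pearson_similarity(lm([[1, 2, 3], [2, 4, 6]]))
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelated(self):
        s = pearson_similarity(lm([[1, 2, 3], [3, 2, 1]]))
        assert s.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # centered dot product 4.0 over sqrt(5 * 5)
        s = pearson_similarity(lm([[1, 2, 3, 4], [1, 3, 2, 4]]))
        assert s.values[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_row_gets_zero_but_unit_diagonal(self):
        s = pearson_similarity(lm([[1, 1, 1], [1, 2, 3]]))
        assert s.values[0, 1] == 0.0
        assert s.values[0, 0] == 1.0

    def test_cross_matches_square(self, rng):
        m = lm(rng.normal(size=(6, 10)))
        square = pearson_similarity(m)
        cross = pearson_similarity(m.take_rows(m.row_ids[:2]), m)
        np.testing.assert_allclose(cross.values, square.values[:2, :], atol=1e-12)

    def test_too_few_features(self):
        with pytest.raises(ValueError):
            pearson_similarity(lm([[1.0], [2.0]]))

    def test_psd_within_tolerance(self, rng):
        s = pearson_similarity(lm(rng.normal(size=(15, 8))))
        assert np.linalg.eigvalsh(s.values).min() >= -1e-8


class TestTanimoto:
    def test_identical_vectors(self):
        s = tanimoto_similarity(lm([[1, 2, 3], [1, 2, 3]]))
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_support(self):
        s = tanimoto_similarity(lm([[1, 1, 0], [0, 0, 2]]))
        assert s.values[0, 1] == 0.0

    def test_hand_computed_example(self):
        s = tanimoto_similarity(lm([[1, 1, 0], [1, 0, 0]]))
        assert s.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_negative_descriptor_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tanimoto_similarity(lm([[1, -1], [1, 1]]))

    def test_all_zero_row_names_compound(self):
        with pytest.raises(ValueError, match="c1"):
            tanimoto_similarity(lm([[1, 1], [0, 0]]))

    def test_minmax_variant(self):
        s = tanimoto_similarity(lm([[2, 0], [1, 1]]), variant="minmax")
        assert s.values[0, 1] == pytest.approx(1 / 3)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.0, 50.0), min_size=4, max_size=4), min_size=2, max_size=6))
    def test_bounds_and_symmetry(self, rows):
        vals = np.array(rows) + 1e-3  # keep rows nonzero
        s = tanimoto_similarity(lm(vals))
        assert np.allclose(s.values, s.values.T)
        assert s.values.min() >= 0.0 and s.values.max() <= 1.0 + 1e-12

    def test_psd_within_tolerance(self, rng):
        s = tanimoto_similarity(lm(rng.uniform(0.1, 5.0, size=(15, 8))))
        assert np.linalg.eigvalsh(s.values).min() >= -1e-8


class TestSmithWaterman:
    def test_identical_short_sequence(self):
        assert smith_waterman_score("AAA", "AAA") == pytest.approx(12.0)

    def test_no_positive_alignment_scores_zero(self):
        assert smith_waterman_score("AAAA", "WWWW") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman_score("", "MKT")

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 25)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 25)))
            assert smith_waterman_score(a, b) == smith_waterman_score(b, a)

    def test_agrees_with_dp_oracle_on_random_sequences(self, rng):
        for _ in range(15):
            a = "".join(rng.choice(list(AA), size=rng.integers(4, 18)))
            b = "".join(rng.choice(list(AA), size=rng.integers(4, 18)))
            assert smith_waterman_score(a, b) == pytest.approx(sw_score_dp(a, b))

    def test_gap_cost_convention_matches_oracle(self):
        # alignments that force gaps of length > 1
        a, b = "MKTAYIAKQR", "MKTAKQR"
        assert smith_waterman_score(a, b) == pytest.approx(sw_score_dp(a, b))


class TestNormalizedSW:
    def test_identical_sequences_score_one(self):
        s = normalized_sequence_similarity(SequenceSet({"a": "MKTV", "b": "MKTV"}))
        assert s.values[0, 1] == pytest.approx(1.0)

    def test_unrelated_sequences_score_zero(self):
        s = normalized_sequence_similarity(SequenceSet({"a": "AAAA", "b": "WWWW"}))
        assert s.values[0, 1] == 0.0

    def test_unit_diagonal_and_unit_interval(self, rng):
        seqs = SequenceSet(
            {f"p{i}": "".join(rng.choice(list(AA), size=30)) for i in range(8)}
        )
        s = normalized_sequence_similarity(seqs)
        np.testing.assert_array_equal(np.diag(s.values), 1.0)
        assert s.values.min() >= 0.0 and s.values.max() <= 1.0 + 1e-12

    def test_cross_form_consistent_with_square(self, rng):
        seqs = SequenceSet(
            {f"p{i}": "".join(rng.choice(list(AA), size=25)) for i in range(5)}
        )
        square = normalized_sequence_similarity(seqs)
        cross = normalized_sequence_similarity(seqs.subset(["p0", "p3"]), seqs)
        np.testing.assert_allclose(cross.values, square.values[[0, 3], :], atol=1e-12)


class TestAverage:
    def test_elementwise_average_and_idempotence(self, rng):
        m = lm(rng.normal(size=(5, 9)))
        s = pearson_similarity(m)
        assert np.allclose(average_similarity(s, s).values, s.values)
        d = tanimoto_similarity(lm(rng.uniform(0.1, 2.0, size=(5, 4))))
        avg = average_similarity(s, d)
        np.testing.assert_allclose(avg.values, (s.values + d.values) / 2)
        np.testing.assert_array_equal(np.diag(avg.values), 1.0)

    def test_id_mismatch_lists_symmetric_difference(self, rng):
        s1 = pearson_similarity(lm(rng.normal(size=(3, 5))))
        s2 = pearson_similarity(lm(rng.normal(size=(3, 5)), prefix_r="x"))
        with pytest.raises(ValueError, match="x0"):
            average_similarity(s1, s2)


def test_protein_profiles_are_gene_columns(default_dataset):
    ds = default_dataset
    profiles = protein_expression_profiles(ds.expression, ds.protein_gene_map)
    assert profiles.row_ids == list(ds.protein_gene_map)
    p0, g0 = next(iter(ds.protein_gene_map.items()))
    np.testing.assert_array_equal(
        profiles.values[profiles.row_ids.index(p0)],
        ds.expression.values[:, ds.expression.col_ids.index(g0)],
    )


def test_unmapped_proteins_dropped_with_warning(default_dataset, caplog):
    ds = default_dataset
    pgm = dict(ds.protein_gene_map)
    pgm["ghost"] = "no-such-gene"
    import logging

    with caplog.at_level(logging.WARNING):
        profiles = protein_expression_profiles(ds.expression, pgm)
    assert "ghost" not in profiles.row_ids
    assert any("ghost" in r.message for r in caplog.records)


def test_expression_and_structure_similarities_uncorrelated_without_coherence():
    """With structure_coherence = 0 the chemical and transcriptomic channels
    are independent by construction, so off-diagonal compound expression
    similarities and Tanimoto similarities are uncorrelated."""
    ds = generate(GeneratorConfig(seed=13, structure_coherence=0.0))
    x = ds.expression
    expr = pearson_similarity(LabeledMatrix(x.row_ids, x.col_ids, np.abs(x.values)))
    chem = tanimoto_similarity(ds.descriptors)
    iu = np.triu_indices(len(x.row_ids), k=1)
    r = np.corrcoef(expr.values[iu], chem.values[iu])[0, 1]
    assert abs(r) <= 0.1
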