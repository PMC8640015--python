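from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hmm4d as h
from hmm4d.params import (
    ConfusionMatrix,
    composite_labels,
    read_matrix_csv,
    write_matrix_csv,
)


class TestTransitionBuilders:
    def test_default_dissolving_to_product_is_ten_percent(self, roles):
        t = h.build_transition_default(4, roles)
        assert t[2, 3] == pytest.approx(0.10)

    def test_default_rows_sum_to_one(self, roles):
        t = h.build_transition_default(4, roles)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_default_without_roles_and_zero_eps_is_identity(self):
        t = h.build_transition_default(3, {}, eps=0.0)
        np.testing.assert_array_equal(t, np.eye(3))

    def test_default_is_diagonal_dominant(self, roles):
        t = h.build_transition_default(4, roles)
        assert all(t[i, i] > t[i, j] for i in range(4) for j in range(4) if i != j)

    def test_default_rejects_excessive_eps(self):
        with pytest.raises(ValueError):
            h.build_transition_default(4, {}, eps=0.5)

    def test_default_rejects_out_of_range_role(self):
        with pytest.raises(ValueError):
            h.build_transition_default(3, {5: "dissolving", 1: "product"})

    @pytest.mark.parametrize("n", [2, 4, 5])
    def test_naive_constant_and_stochastic(self, n):
        t = h.build_transition_naive(n)
        np.testing.assert_array_equal(t, np.full((n, n), 1.0 / n))
        assert np.ptp(t) == 0.0
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 7])
    def test_naive_stable_definition(self, n):
        t = h.build_transition_naive_stable(n)
        np.testing.assert_array_equal(np.diag(t), np.full(n, 0.5))
        # every off-diagonal entry is exactly 0.5/(N-1); the summed row mass
        # is 0.5 to floating-point summation precision
        off_entries = t[~np.eye(n, dtype=bool)]
        np.testing.assert_array_equal(off_entries, np.full(n * (n - 1), 0.5 / (n - 1)))
        off_mass = t.sum(axis=1) - np.diag(t)
        np.testing.assert_allclose(off_mass, 0.5, rtol=0, atol=1e-12)

    def test_naive_coincides_with_naive_stable_for_two_classes(self):
        np.testing.assert_array_equal(
            h.build_transition_naive(2), h.build_transition_naive_stable(2)
        )

    @pytest.mark.parametrize("builder", [h.build_transition_naive,
                                         h.build_transition_naive_stable])
    def test_builders_reject_single_class(self, builder):
        with pytest.raises(ValueError):
            builder(1)


class TestStart:
    @pytest.mark.parametrize("n,expected", [(4, [0.25] * 4), (1, [1.0])])
    def test_uniform(self, n, expected):
        np.testing.assert_allclose(h.build_start_uniform(n), expected)

    @pytest.mark.parametrize("n", [1, 3, 9])
    def test_sums_to_one(self, n):
        assert h.build_start_uniform(n).sum() == pytest.approx(1.0)


class TestEmissionFromConfusion:
    def test_identity_counts_give_identity_emission(self):
        cm = ConfusionMatrix(counts=100 * np.eye(4, dtype=int))
        np.testing.assert_array_equal(h.emission_from_confusion(cm), np.eye(4))

    def test_forced_arithmetic_row(self):
        cm = ConfusionMatrix(counts=np.array([[10, 10, 0, 0], [0, 0, 5, 5],
                                              [1, 1, 1, 1], [0, 0, 0, 4]]))
        e = h.emission_from_confusion(cm)
        np.testing.assert_allclose(e[0], [0.5, 0.5, 0.0, 0.0])

    def test_random_counts_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 1000, size=(5, 5))
        counts[:, 0] += 1  # guarantee positive rows
        e = h.emission_from_confusion(ConfusionMatrix(counts=counts))
        np.testing.assert_allclose(e.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_error_names_the_class(self):
        counts = np.array([[5, 5], [0, 0]])
        cm = ConfusionMatrix(counts=counts, row_labels=("air", "gas_pocket"))
        with pytest.raises(ValueError, match="gas_pocket"):
            h.emission_from_confusion(cm)

    def test_round_trip_recovers_integer_counts(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(4, 12))
        counts[:, 0] += 1
        cm = ConfusionMatrix(counts=counts)
        e = h.emission_from_confusion(cm)
        recovered = e * counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(recovered, counts, atol=1e-9)


class TestConfidenceBin:
    @pytest.mark.parametrize(
        "p,n,b,expected",
        [
            (0.6, 4, 3, 1),   # mid-confidence: (50%, 75%) for N=4
            (1.0, 4, 3, 2),   # maximal confidence -> top bin
            (1.0, 5, 7, 6),
            (0.50, 4, 3, 1),  # lower-inclusive boundary
            (0.26, 4, 3, 0),
            (0.2, 4, 3, 0),   # p <= 1/N clamps to bin 0
            (0.9, 4, 1, 0),
        ],
    )
    def test_examples(self, p, n, b, expected):
        assert h.confidence_bin(p, n, b) == expected

    def test_rejects_invalid_probability(self):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                h.confidence_bin(p, 4, 3)

    def test_rejects_zero_bins(self):
        with pytest.raises(ValueError):
            h.confidence_bin(0.5, 4, 0)

    @given(st.integers(2, 6), st.integers(1, 5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_surjective(self, n, b):
        ps = np.linspace(1.0 / n + 1e-9, 1.0, 500)
        bins = h.confidence_bin(ps, n, b)
        assert np.all(np.diff(bins) >= 0)
        assert set(np.unique(bins)) == set(range(b))

    def test_vectorized_matches_scalar(self):
        ps = np.array([0.3, 0.5, 0.74, 0.99])
        vec = h.confidence_bin(ps, 4, 3)
        assert list(vec) == [h.confidence_bin(float(p), 4, 3) for p in ps]


class TestCompositeObservable:
    @pytest.mark.parametrize("cls,bin_,b,expected", [(0, 0, 3, 0), (3, 2, 3, 11),
                                                     (2, 0, 1, 2)])
    def test_examples(self, cls, bin_, b, expected):
        assert h.composite_observable(cls, bin_, b) == expected

    def test_bijection_over_all_pairs(self):
        n, b = 4, 3
        images = {h.composite_observable(c, k, b) for c in range(n) for k in range(b)}
        assert images == set(range(n * b))

    def test_rejects_out_of_range_bin(self):
        with pytest.raises(ValueError):
            h.composite_observable(1, 3, 3)


class TestAdjustEmissionDiagonal:
    @staticmethod
    def _column_owners(n, b):
        return np.repeat(np.arange(n), b)

    def test_already_dominant_is_fixed_point(self):
        e = np.array([[0.8, 0.2], [0.3, 0.7]])
        out = h.adjust_emission_diagonal(e)
        np.testing.assert_allclose(out, e, atol=1e-12)

    def test_foreign_dominated_column_is_corrected(self):
        # a "mid-confidence base" column dominated by the rare product class
        n, b = 4, 3
        rng = np.random.default_rng(2)
        e = rng.dirichlet(np.ones(n * b), size=n)
        col = 1 * b + 1  # class 1, mid bin
        e[3, col] = e[:, col].max() * 4
        e = e / e.sum(axis=1, keepdims=True)
        assert np.argmax(e[:, col]) == 3
        out = h.adjust_emission_diagonal(e)
        owners = self._column_owners(n, b)
        for c in range(n * b):
            assert np.argmax(out[:, c]) == owners[c]

    def test_argmax_postcondition_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n, b = rng.integers(2, 5), rng.integers(1, 4)
            e = rng.dirichlet(np.ones(n * b), size=n)
            out = h.adjust_emission_diagonal(e)
            owners = self._column_owners(n, b)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
            for c in range(n * b):
                assert np.argmax(out[:, c]) == owners[c]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        e = rng.dirichlet(np.ones(12), size=4)
        once = h.adjust_emission_diagonal(e)
        twice = h.adjust_emission_diagonal(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_zero_column_error(self):
        e = np.array([[0.5, 0.5, 0.0, 0.0], [0.2, 0.8, 0.0, 0.0]])
        with pytest.raises(ValueError, match="zero"):
            h.adjust_emission_diagonal(e)


class TestHmmSpec:
    def test_builders_compose_into_valid_spec(self, demo_spec):
        assert demo_spec.n_observables == 4

    def test_rejects_non_stochastic_transition(self):
        bad = np.full((2, 2), 0.6)
        with pytest.raises(ValueError, match="transition"):
            h.HmmSpec(2, 1, bad, np.eye(2), np.array([0.5, 0.5]))

    def test_rejects_wrong_emission_width(self):
        with pytest.raises(ValueError, match="emission"):
            h.HmmSpec(2, 3, np.eye(2), np.eye(2), np.array([0.5, 0.5]))

    def test_json_round_trip(self, tmp_path, demo_spec):
        p = tmp_path / "spec.json"
        demo_spec.to_json(p)
        back = h.HmmSpec.from_json(p)
        np.testing.assert_array_equal(back.transition, demo_spec.transition)
        np.testing.assert_array_equal(back.emission, demo_spec.emission)
        np.testing.assert_array_equal(back.start, demo_spec.start)
        assert back.n_classes == 4 and back.n_bins == 1

    def test_matrix_csv_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(5)
        mat = rng.dirichlet(np.ones(12), size=4)
        p = tmp_path / "m.csv"
        write_matrix_csv(mat, p, col_labels=composite_labels(4, 3))
        np.testing.assert_array_equal(read_matrix_csv(p), mat)

    def test_confusion_csv_round_trip(self, tmp_path):
        cm = ConfusionMatrix(
            counts=np.eye(4, dtype=int) * 9 + 1,
            row_labels=("air", "base", "mg", "gas"),
        )
        p = tmp_path / "cm.csv"
        cm.to_csv(p)
        back = ConfusionMatrix.from_csv(p)
        np.testing.assert_array_equal(back.counts, cm.counts)
        assert back.row_labels == cm.row_labels


class TestMakeSpec:
    def test_model_transition_choice(self, roles):
        cm = ConfusionMatrix(counts=np.eye(4, dtype=int) * 10)
        t = h.make_spec("hmm-t", cm, roles)
        assert t.transition[2, 3] == pytest.approx(0.10)
        naive = h.make_spec("hmm-t-naive", cm)
        assert np.ptp(naive.transition) == 0.0

    def test_hmm_tc_requires_rectangular_confusion(self):
        cm = ConfusionMatrix(counts=np.eye(4, dtype=int) * 10)
        with pytest.raises(ValueError):
            h.make_spec("hmm-tc", cm)

    def test_hmm_tc_applies_same_title_adjustment(self, roles):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 100, size=(4, 12))
        cm = ConfusionMatrix(counts=counts)
        spec = h.make_spec("hmm-tc", cm, roles)
        owners = np.repeat(np.arange(4), 3)
        for c in range(12):
            assert np.argmax(spec.emission[:, c]) == owners[c]

    def test_unknown_model_rejected(self):
        cm = ConfusionMatrix(counts=np.eye(4, dtype=int))
        with pytest.raises(ValueError, match="model"):
            h.make_spec("bogus", cm)
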