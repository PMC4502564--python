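"""Normalization, expression filtering and relative-profile geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dupliphy import (
    ExpressionMatrix,
    QuantileNormalizer,
    combine_profiles,
    filter_expressed,
    quantile_normalize,
    relative_profile,
    restrict_to_shared_tissues,
    tissue_specificity,
)
from dupliphy.config import CANONICAL_TISSUES

positive_rows = arrays(
    float,
    st.integers(2, 11),
    elements=st.floats(0.0, 1e6, allow_nan=False),
).filter(lambda r: r.sum() > 0)


class TestQuantileNormalize:
    def test_two_samples_map_to_rank_means(self):
        # order statistics (1,2,3) and (4,6,8) average to (2.5, 4, 5.5)
        qn = QuantileNormalizer().fit([np.array([1.0, 2.0, 3.0]), np.array([4.0, 6.0, 8.0])])
        out = qn.transform([np.array([1.0, 2.0, 3.0]), np.array([4.0, 6.0, 8.0])])
        np.testing.assert_allclose(out[0], [2.5, 4.0, 5.5])
        np.testing.assert_allclose(out[1], [2.5, 4.0, 5.5])

    def test_single_sample_unchanged(self):
        col = np.array([3.0, 1.0, 2.0, 2.5])
        out = QuantileNormalizer().fit([col]).transform([col])[0]
        np.testing.assert_allclose(out, col)

    def test_ties_get_mean_of_reference_values(self):
        qn = QuantileNormalizer().fit(
            [np.array([1.0, 1.0, 3.0]), np.array([10.0, 20.0, 30.0])]
        )
        out = qn.transform([np.array([1.0, 1.0, 3.0])])[0]
        # reference is ((1+10)/2, (1+20)/2, (3+30)/2) = (5.5, 10.5, 16.5);
        # the tied pair takes the mean of the two lowest reference values
        np.testing.assert_allclose(out, [8.0, 8.0, 16.5])

    def test_idempotent_on_matrices(self, rng):
        data = rng.gamma(2.0, 10.0, size=(40, 4))
        frames = [
            ExpressionMatrix(
                "human",
                pd.DataFrame(data[:, :2], columns=["cerebrum-F", "heart-F"],
                             index=[f"h{i}" for i in range(40)]),
            ),
            ExpressionMatrix(
                "mouse",
                pd.DataFrame(data[:, 2:], columns=["cerebrum-F", "heart-F"],
                             index=[f"m{i}" for i in range(40)]),
            ),
        ]
        once = quantile_normalize(frames)
        twice = quantile_normalize(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.values, b.values, rtol=0, atol=1e-12)
        # sorted values of every sample identical after normalization
        cols = [m.values[:, j] for m in once for j in range(2)]
        for col in cols[1:]:
            np.testing.assert_allclose(np.sort(col), np.sort(cols[0]))

    @given(arrays(float, (12, 3), elements=st.floats(0, 1e4, allow_nan=False)))
    def test_preserves_within_sample_rank_order(self, data):
        qn = QuantileNormalizer().fit([data[:, j] for j in range(3)])
        for j in range(3):
            out = qn._transform_column(data[:, j])
            orig_order = np.argsort(data[:, j], kind="stable")
            assert np.all(np.diff(out[orig_order]) >= -1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="no samples"):
            quantile_normalize([])
        with pytest.raises(ValueError, match="negative expression"):
            QuantileNormalizer().fit([np.array([-1.0, 2.0])])


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "row,threshold,expected",
        [
            ((0.5, 0.9, 0.99), 1.0, False),  # all below threshold
            ((0.0, 0.0, 1.0), 1.0, True),  # boundary inclusive
            ((0.5, 0.0, 0.0), 0.5, True),
        ],
    )
    def test_threshold_boundary(self, row, threshold, expected):
        m = ExpressionMatrix(
            "human",
            pd.DataFrame([row], columns=["cerebrum-F", "heart-F", "testis"], index=["g"]),
        )
        assert (["g"] if expected else []) == filter_expressed(m, threshold)

    def test_empty_result_allowed(self, small_matrix):
        assert filter_expressed(small_matrix, 1e9) == []

    def test_default_threshold(self, small_matrix):
        assert filter_expressed(small_matrix) == ["g1", "g3", "g4"]


class TestRelativeProfile:
    def test_exact_fractions(self):
        p = relative_profile([10, 30, 60], ["cerebrum-F", "heart-F", "testis"])
        np.testing.assert_allclose(p.proportions, [0.1, 0.3, 0.6])

    def test_uniform(self):
        p = relative_profile([5.0] * 11, CANONICAL_TISSUES)
        np.testing.assert_allclose(p.proportions, 1 / 11)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero total expression"):
            relative_profile([0, 0, 0], ["cerebrum-F", "heart-F", "testis"])

    @given(positive_rows, st.floats(1e-6, 1e6))
    def test_invariant_to_positive_rescaling(self, row, scale):
        labels = CANONICAL_TISSUES[: len(row)]
        p = relative_profile(row, labels)
        q = relative_profile(row * scale, labels)
        np.testing.assert_allclose(p.proportions, q.proportions, atol=1e-9)
        assert abs(p.proportions.sum() - 1) < 1e-9


class TestCombineProfiles:
    def test_disjoint_copies(self):
        p = combine_profiles([10, 0, 0], [0, 10, 0], ["cerebrum-F", "heart-F", "testis"])
        np.testing.assert_allclose(p.proportions, [0.5, 0.5, 0.0])

    def test_identical_rows_equal_single_profile(self):
        row = np.array([4.0, 1.0, 5.0])
        labels = ["cerebrum-F", "heart-F", "testis"]
        combined = combine_profiles(row, row, labels)
        np.testing.assert_allclose(
            combined.proportions, relative_profile(row, labels).proportions
        )

    def test_misaligned_error(self):
        with pytest.raises(ValueError, match="misaligned"):
            combine_profiles([1, 2], [1, 2, 3], ["cerebrum-F", "heart-F", "testis"])


class TestTissueSpecificity:
    def test_uniform_ties_break_to_first_canonical(self):
        p = relative_profile([1.0] * 11, CANONICAL_TISSUES)
        call = tissue_specificity(p)
        assert call.top_tissue == CANONICAL_TISSUES[0]
        assert call.max_proportion == pytest.approx(1 / 11)

    def test_argmax(self):
        p = relative_profile([10, 30, 60], ["cerebrum-F", "heart-F", "testis"])
        call = tissue_specificity(p)
        assert (call.max_proportion, call.top_tissue) == (pytest.approx(0.6), "testis")

    @given(positive_rows)
    def test_max_at_least_uniform(self, row):
        p = relative_profile(row, CANONICAL_TISSUES[: len(row)])
        assert tissue_specificity(p).max_proportion >= 1 / len(row) - 1e-12


class TestRestrictToSharedTissues:
    def test_identical_sets_unchanged(self):
        a, b, shared = restrict_to_shared_tissues(
            [1, 2, 3], [4, 5, 6], ["cerebrum-F", "heart-F", "testis"],
            ["cerebrum-F", "heart-F", "testis"],
        )
        np.testing.assert_allclose(a, [1, 2, 3])
        np.testing.assert_allclose(b, [4, 5, 6])
        assert shared == ("cerebrum-F", "heart-F", "testis")

    def test_renormalized_after_restriction(self):
        labels_a = list(CANONICAL_TISSUES)
        labels_b = list(CANONICAL_TISSUES[:-1])  # no testis
        row_a = np.arange(1.0, 12.0)
        row_b = np.arange(2.0, 12.0)
        a, b, shared = restrict_to_shared_tissues(row_a, row_b, labels_a, labels_b)
        assert len(shared) == 10 and "testis" not in shared
        assert abs(relative_profile(a, shared).proportions.sum() - 1) < 1e-9

    def test_disjoint_is_error(self):
        with pytest.raises(ValueError, match="no shared tissues"):
            restrict_to_shared_tissues([1], [1], ["testis"], ["heart-F"])


class TestExpressionMatrix:
    def test_rejects_unknown_tissue(self):
        with pytest.raises(ValueError, match="unknown tissue"):
            ExpressionMatrix("human", pd.DataFrame({"spleen": [1.0]}, index=["g"]))

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative expression"):
            ExpressionMatrix("human", pd.DataFrame({"testis": [-1.0]}, index=["g"]))

    def test_tsv_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "human.tsv"
        small_matrix.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        assert back.species == "human"
        np.testing.assert_allclose(back.values, small_matrix.values)
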