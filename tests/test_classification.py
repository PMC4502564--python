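"""Distances, cutoffs and the five-way retention rule table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from dupliphy import (
    DuplicateClassifier,
    GeneratorConfig,
    baseline_distances,
    classify_dataset,
    classify_trio,
    cutoff_sensitivity,
    divergence_cutoff,
    euclidean_distance,
    relative_profile,
    simulate_dataset,
)
from dupliphy.config import CLASS_LABELS, PipelineConfig
from dupliphy.expression import ExpressionMatrix, restrict_to_shared_tissues

LAB3 = ["cerebrum-F", "heart-F", "testis"]


class TestEuclideanDistance:
    def test_identity_and_maximum(self):
        p = relative_profile([1, 0, 0], LAB3)
        q = relative_profile([0, 1, 0], LAB3)
        assert euclidean_distance(p, p) == 0.0
        assert euclidean_distance(p, q) == pytest.approx(np.sqrt(2))

    def test_direct_evaluation(self):
        p = relative_profile([0.5, 0.5, 0], LAB3)
        q = relative_profile([0.25, 0.75, 0], LAB3)
        assert euclidean_distance(p, q) == pytest.approx(np.sqrt(0.125))

    def test_mismatched_tissues_error(self):
        p = relative_profile([1, 1], LAB3[:2])
        q = relative_profile([1, 1], LAB3[1:])
        with pytest.raises(ValueError, match="mismatched"):
            euclidean_distance(p, q)

    @given(
        st.lists(st.floats(1e-3, 1e3), min_size=3, max_size=3),
        st.lists(st.floats(1e-3, 1e3), min_size=3, max_size=3),
    )
    def test_bounded_by_sqrt2_and_symmetric(self, a, b):
        p = relative_profile(a, LAB3)
        q = relative_profile(b, LAB3)
        d = euclidean_distance(p, q)
        assert 0 <= d <= np.sqrt(2) + 1e-12
        assert d == pytest.approx(euclidean_distance(q, p))


class TestDivergenceCutoff:
    def test_linear_interpolation_quartiles(self):
        cut = divergence_cutoff([0.1, 0.2, 0.3, 0.4, 0.5])
        assert cut.median == pytest.approx(0.3)
        assert cut.siqr == pytest.approx(0.1)
        assert cut.cutoff == pytest.approx(0.4)

    def test_single_element(self):
        cut = divergence_cutoff([0.3])
        assert cut.median == cut.cutoff == 0.3
        assert cut.siqr == 0.0

    def test_zero_spread(self):
        cut = divergence_cutoff([0.25] * 10)
        assert cut.cutoff == pytest.approx(0.25)

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="empty baseline"):
            divergence_cutoff([])


class TestClassifyTrio:
    @pytest.mark.parametrize(
        "e_po,e_co,e_pco,cutoff,expected",
        [
            (0.1, 0.2, 0.9, 0.3, "CONSERVED"),
            (0.5, 0.1, 0.9, 0.3, "NEOFUNC_PARENT"),
            (0.1, 0.5, 0.9, 0.3, "NEOFUNC_CHILD"),
            (0.5, 0.4, 0.2, 0.3, "SUBFUNC"),
            (0.5, 0.4, 0.6, 0.3, "SPECIALIZED"),
            (0.3, 0.3, 0.9, 0.3, "CONSERVED"),  # equality counts as not diverged
        ],
    )
    def test_rule_table(self, e_po, e_co, e_pco, cutoff, expected):
        assert classify_trio(e_po, e_co, e_pco, cutoff) == expected

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            classify_trio(-0.1, 0.2, 0.3, 0.3)

    @given(
        st.floats(0, 1.5), st.floats(0, 1.5), st.floats(0, 1.5), st.floats(0.01, 1.0)
    )
    def test_regions_partition_distance_space(self, e_po, e_co, e_pco, cutoff):
        labels = [classify_trio(e_po, e_co, e_pco, cutoff)]
        assert labels[0] in CLASS_LABELS

    @given(
        st.floats(0, 1.5), st.floats(0, 1.5), st.floats(0, 1.5),
        st.floats(0.01, 1.0), st.floats(0.0, 1.0),
    )
    def test_monotone_in_cutoff(self, e_po, e_co, e_pco, cutoff, bump):
        """Raising the cutoff only ever moves labels toward CONSERVED."""
        rank = {"CONSERVED": 0, "NEOFUNC_PARENT": 1, "NEOFUNC_CHILD": 1,
                "SUBFUNC": 2, "SPECIALIZED": 3}
        low = classify_trio(e_po, e_co, e_pco, cutoff)
        high = classify_trio(e_po, e_co, e_pco, cutoff + bump)
        assert rank[high] <= rank[low]


class TestDuplicateClassifier:
    def test_fit_predict(self):
        clf = DuplicateClassifier().fit([0.1, 0.2, 0.3, 0.4, 0.5])
        assert clf.cutoff_ == pytest.approx(0.4)
        labels = clf.predict([[0.1, 0.1, 0.1], [0.5, 0.1, 0.9], [0.5, 0.5, 0.9]])
        assert list(labels) == ["CONSERVED", "NEOFUNC_PARENT", "SPECIALIZED"]

    def test_sklearn_contract(self):
        clf = DuplicateClassifier(siqr_multiplier=2.0)
        cloned = clone(clf)
        assert cloned.get_params()["siqr_multiplier"] == 2.0
        with pytest.raises(ValueError, match="not fitted"):
            clf.predict([[0.1, 0.1, 0.1]])

    def test_multiplier_scales_cutoff(self):
        base = np.linspace(0.05, 0.5, 20)
        loose = DuplicateClassifier(siqr_multiplier=0.5).fit(base)
        strict = DuplicateClassifier(siqr_multiplier=3.0).fit(base)
        assert strict.cutoff_ > loose.cutoff_


def _matrix(species, rows, labels):
    return ExpressionMatrix(
        species, pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    )


class TestBaselineDistances:
    def test_identical_profiles_give_zeros(self):
        rows = {f"g{i}": [1.0 + i, 2.0, 3.0] for i in range(4)}
        m1 = _matrix("human", rows, LAB3)
        m2 = _matrix("chimpanzee", rows, LAB3)
        d = baseline_distances([(g, g) for g in rows], m1, m2)
        np.testing.assert_allclose(d, 0.0)

    def test_matches_per_gene_direct_computation(self, rng):
        labels = LAB3
        rows1 = {f"g{i}": rng.gamma(2, 5, 3) + 1 for i in range(6)}
        rows2 = {f"g{i}": rows1[f"g{i}"] * rng.lognormal(0, 0.3, 3) for i in range(6)}
        m1 = _matrix("human", rows1, labels)
        m2 = _matrix("mouse", rows2, labels)
        pairs = [(g, g) for g in rows1]
        got = baseline_distances(pairs, m1, m2)
        expected = [
            np.linalg.norm(
                rows1[g] / rows1[g].sum() - rows2[g] / rows2[g].sum()
            )
            for g, _ in pairs
        ]
        np.testing.assert_allclose(got, expected)

    def test_empty_baseline_error(self):
        m1 = _matrix("human", {"g0": [0.1, 0.1, 0.1]}, LAB3)
        m2 = _matrix("mouse", {"g0": [0.1, 0.1, 0.1]}, LAB3)
        with pytest.raises(ValueError, match="empty baseline"):
            baseline_distances([("g0", "g0")], m1, m2)


class TestClassifyDataset:
    def test_zero_noise_dataset_recovers_every_planted_label(self):
        config = GeneratorConfig(
            seed=3, n_single_copy=40, n_trios_per_class=6,
            noise_sd=0.0, drift_per_ks=0.0, n_unresolved_families=0,
        )
        bundle = simulate_dataset(config)
        records, exclusions, _ = classify_dataset(
            bundle.trios, bundle.matrices, bundle.orthologs
        )
        assert len(exclusions) == 0
        truth = bundle.ground_truth.set_index("pair_id")["planted_class"]
        for rec in records.itertuples(index=False):
            assert rec.label == truth[rec.pair_id]

    def test_unexpressed_child_excluded_with_reason(self, tiny_bundle):
        trios = tiny_bundle.trios.copy()
        matrices = {sp: m for sp, m in tiny_bundle.matrices.items()}
        focal = trios.iloc[0]["focal_species"]
        child = trios.iloc[0]["child_gene"]
        data = matrices[focal].data.copy()
        data.loc[child] = 0.0
        matrices[focal] = ExpressionMatrix(focal, data)
        records, exclusions, _ = classify_dataset(trios, matrices, tiny_bundle.orthologs)
        assert (exclusions["reason"] == "unexpressed child").sum() == 1
        assert len(records) + len(exclusions) == len(trios)

    def test_agrees_with_straight_line_reimplementation(self, tiny_bundle):
        """Oracle: filter -> shared tissues -> profiles -> distances -> rules,
        recomputed independently per trio."""
        config = PipelineConfig()
        records, _, cutoffs = classify_dataset(
            tiny_bundle.trios, tiny_bundle.matrices, tiny_bundle.orthologs, config
        )
        matrices = tiny_bundle.matrices
        for rec in records.itertuples(index=False):
            trio = tiny_bundle.trios.set_index("pair_id").loc[rec.pair_id]
            fm = matrices[rec.focal_species]
            om = matrices[rec.outgroup_species]
            p_row, o_row, shared = restrict_to_shared_tissues(
                fm.row(trio["parent_gene"]), om.row(trio["outgroup_gene"]),
                fm.tissue_labels, om.tissue_labels,
            )
            c_row, _, _ = restrict_to_shared_tissues(
                fm.row(trio["child_gene"]), om.row(trio["outgroup_gene"]),
                fm.tissue_labels, om.tissue_labels,
            )
            def rel(r):
                return r / r.sum()
            e_po = np.linalg.norm(rel(p_row) - rel(o_row))
            e_co = np.linalg.norm(rel(c_row) - rel(o_row))
            e_pco = np.linalg.norm(rel(p_row + c_row) - rel(o_row))
            pair = tuple(sorted((rec.focal_species, rec.outgroup_species)))
            cut = cutoffs[pair].cutoff
            assert rec.e_po == pytest.approx(e_po)
            expected = (
                "CONSERVED" if e_po <= cut and e_co <= cut
                else "NEOFUNC_PARENT" if e_co <= cut
                else "NEOFUNC_CHILD" if e_po <= cut
                else "SUBFUNC" if e_pco <= cut
                else "SPECIALIZED"
            )
            assert rec.label == expected

    def test_missing_cutoff_is_error(self, tiny_bundle):
        with pytest.raises(ValueError, match="missing ortholog table"):
            classify_dataset(tiny_bundle.trios, tiny_bundle.matrices, {})


@pytest.fixture(scope="module")
def classified(tiny_bundle):
    return classify_dataset(tiny_bundle.trios, tiny_bundle.matrices, tiny_bundle.orthologs)


class TestCutoffSensitivity:
    def test_conserved_count_non_decreasing_in_multiplier(self, classified):
        records, _, cutoffs = classified
        table = cutoff_sensitivity(records, cutoffs, [0.25, 0.5, 1.0, 2.0, 4.0, 100.0])
        conserved = table["CONSERVED"].tolist()
        assert conserved == sorted(conserved)
        # an effectively infinite cutoff conserves everything
        assert conserved[-1] == len(records)

    def test_total_constant_and_unit_multiplier_consistent(self, classified):
        records, _, cutoffs = classified
        table = cutoff_sensitivity(records, cutoffs, [0.5, 1.0, 2.0])
        totals = table[list(CLASS_LABELS)].sum(axis=1)
        assert (totals == len(records)).all()
        unit = table[table["multiplier"] == 1.0].iloc[0]
        observed = records["label"].value_counts()
        for label in CLASS_LABELS:
            assert unit[label] == observed.get(label, 0)
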