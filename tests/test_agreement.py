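import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tumorbud import (RatingPanel, cohen_kappa, compute_agreement,
                      fleiss_kappa, interpret_kappa, pairwise_kappa_matrix)
from conftest import panel_from_rows
from oracles import naive_cohen_kappa, naive_fleiss_kappa, random_count_matrix


@st.composite
def count_matrices(draw):
    n = draw(st.integers(2, 8))
    big_n = draw(st.integers(1, 25))
    rows = []
    for _ in range(big_n):
        a = draw(st.integers(0, n))
        b = draw(st.integers(0, n - a))
        rows.append([a, b, n - a - b])
    return rows


class TestFleissKappa:
    def test_perfect_agreement_with_multiple_classes_is_one(self):
        counts = [[3, 0, 0], [0, 3, 0], [0, 0, 3], [3, 0, 0]]
        assert fleiss_kappa(counts) == 1.0

    def test_printed_pattern_matches_direct_formula(self):
        # fixed 4-object x 3-rater pattern, oracle value frozen from the
        # textbook formula chain (naive_fleiss_kappa)
        counts = [[2, 1, 0], [0, 3, 0], [1, 1, 1], [0, 2, 1]]
        expect = naive_fleiss_kappa(counts)
        assert fleiss_kappa(counts) == pytest.approx(expect, abs=1e-15)
        assert fleiss_kappa(counts) == pytest.approx(-1.0 / 41.0, abs=1e-12)

    def test_matches_oracle_on_random_panels(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            counts = random_count_matrix(rng, int(rng.integers(2, 40)),
                                         int(rng.integers(2, 9)))
            assert fleiss_kappa(counts) == pytest.approx(
                naive_fleiss_kappa(counts), abs=1e-12)

    def test_matches_statsmodels_on_random_panels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = random_count_matrix(rng, 30, 5)
            if all(max(r) == sum(r) for r in counts):
                continue  # statsmodels is NaN on degenerate perfect panels
            assert fleiss_kappa(counts) == pytest.approx(
                sm_fleiss(np.array(counts)), abs=1e-10)

    def test_two_rater_panel_follows_fleiss_formula(self):
        counts = [[2, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 2]]
        assert fleiss_kappa(counts) == pytest.approx(
            naive_fleiss_kappa(counts), abs=1e-15)

    def test_single_class_panel_is_one(self):
        assert fleiss_kappa([[5, 0, 0], [5, 0, 0]]) == 1.0

    def test_duplicate_rater_keeps_perfect_panel_at_one(self):
        rows = [["TB"] * 3, ["NEITHER"] * 3, ["PDC"] * 3]
        panel = panel_from_rows(rows)
        wider = panel_from_rows([r + [r[0]] for r in rows])
        assert fleiss_kappa(panel) == 1.0 == fleiss_kappa(wider)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa([[1, 0, 0]])

    @settings(max_examples=100, derandomize=True)
    @given(count_matrices())
    def test_bounded_and_permutation_invariant(self, counts):
        k = fleiss_kappa(counts)
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
        permuted = [[row[2], row[0], row[1]] for row in counts]
        assert fleiss_kappa(permuted) == pytest.approx(k, abs=1e-12)
        shuffled = list(reversed(counts))
        assert fleiss_kappa(shuffled) == pytest.approx(k, abs=1e-12)


class TestCohenKappa:
    def test_identical_vectors_give_one(self):
        a = ["TB", "PDC", "NEITHER", "TB"]
        assert cohen_kappa(a, list(a)) == 1.0

    def test_crossed_disagreement_gives_minus_one(self):
        assert cohen_kappa(["TB", "PDC"], ["PDC", "TB"]) == -1.0

    def test_matches_contingency_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        cats = np.array(["TB", "PDC", "NEITHER"], dtype=object)
        for _ in range(40):
            a = cats[rng.choice(3, 1000, p=[0.6, 0.1, 0.3])]
            b = np.where(rng.random(1000) < 0.7, a,
                         cats[rng.integers(0, 3, 1000)])
            assert cohen_kappa(a, b) == pytest.approx(
                naive_cohen_kappa(a, b), abs=1e-12)

    def test_matches_statsmodels_contingency(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(3)
        cats = np.array(["TB", "PDC", "NEITHER"], dtype=object)
        a = cats[rng.integers(0, 3, 500)]
        b = cats[rng.integers(0, 3, 500)]
        table = pd.crosstab(pd.Categorical(a, cats), pd.Categorical(b, cats),
                            dropna=False)
        assert cohen_kappa(a, b) == pytest.approx(
            cohens_kappa(table.to_numpy(), return_results=False), abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["TB"], ["TB", "PDC"])

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        cats = np.array(["TB", "PDC", "NEITHER"], dtype=object)
        a = cats[rng.integers(0, 3, 200)]
        b = cats[rng.integers(0, 3, 200)]
        swap = {"TB": "NEITHER", "NEITHER": "PDC", "PDC": "TB"}
        a2 = np.array([swap[x] for x in a], dtype=object)
        b2 = np.array([swap[x] for x in b], dtype=object)
        assert cohen_kappa(a2, b2) == pytest.approx(cohen_kappa(a, b), abs=1e-12)


class TestPairwiseMatrix:
    def test_identical_raters_all_ones(self):
        rows = [["TB"] * 4, ["PDC"] * 4, ["NEITHER"] * 4]
        mat = pairwise_kappa_matrix(panel_from_rows(rows))
        off = mat.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off == 1.0).all()

    def test_symmetric_and_matches_per_pair_computation(self):
        rng = np.random.default_rng(5)
        cats = np.array(["TB", "PDC", "NEITHER"], dtype=object)
        rows = [list(cats[rng.integers(0, 3, 3)]) for _ in range(80)]
        panel = panel_from_rows(rows)
        mat = pairwise_kappa_matrix(panel)
        assert mat.equals(mat.T)
        for ra, rb in [("R1", "R2"), ("R1", "R3"), ("R2", "R3")]:
            direct = naive_cohen_kappa(panel.ratings[ra], panel.ratings[rb])
            assert mat.loc[ra, rb] == pytest.approx(direct, abs=1e-12)

    def test_raters_without_shared_objects_are_undefined(self):
        df = pd.DataFrame(
            {"R1": ["TB", "PDC", np.nan, np.nan],
             "R2": ["TB", "TB", np.nan, np.nan],
             "R3": [np.nan, np.nan, "PDC", "TB"],
             "R4": [np.nan, np.nan, "PDC", "PDC"]},
            index=pd.Index([1, 2, 3, 4], name="object_id"))
        mat = pairwise_kappa_matrix(RatingPanel(df))
        assert np.isnan(mat.loc["R1", "R3"]) and np.isnan(mat.loc["R2", "R4"])
        assert np.isfinite(mat.loc["R1", "R2"]) and np.isfinite(mat.loc["R3", "R4"])


class TestInterpretKappa:
    @pytest.mark.parametrize("k,band", [
        (0.42, "moderate"), (0.51, "moderate"), (-0.5, "poor"),
        (0.20, "poor"), (0.21, "fair"), (0.40, "fair"), (0.60, "moderate"),
        (0.61, "good"), (0.80, "good"), (0.81, "very good"), (1.0, "very good"),
    ])
    def test_landis_koch_bands(self, k, band):
        assert interpret_kappa(k) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestComputeAgreement:
    def test_groupwise_fleiss_and_bands(self):
        rng = np.random.default_rng(6)
        cats = np.array(["TB", "PDC", "NEITHER"], dtype=object)
        rows = [list(cats[rng.integers(0, 3, 5)]) for _ in range(40)]
        panel = panel_from_rows(rows)
        groups = pd.Series(["g1"] * 20 + ["g2"] * 20, index=panel.ratings.index)
        rep = compute_agreement(panel, groups)
        assert set(rep.fleiss) == {"g1", "g2"}
        for g in ("g1", "g2"):
            sub = panel.subset_objects(groups.index[groups == g])
            assert rep.fleiss[g] == pytest.approx(fleiss_kappa(sub), abs=1e-15)
            assert rep.fleiss_bands[g] == interpret_kappa(rep.fleiss[g])
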