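"""ECC weight elicitation, Kendall's W and harmonic-mean re-ranking."""

import numpy as np
import pytest
from scipy.stats import rankdata

from cbrecc import (
    Case,
    CaseBase,
    ECCWeights,
    ExpertScoreMatrix,
    ecc_score,
    elicit_weights,
    harmonic_fuse,
    kendalls_w,
    rerank_with_ecc,
    retrieve,
)
from cbrecc.fusion import ConcordanceUndefined


def _matrix(arr):
    arr = np.asarray(arr)
    m, n = arr.shape
    return ExpertScoreMatrix([f"r{i}" for i in range(m)], [f"i{j}" for j in range(n)], arr)


def kendalls_w_direct(arr):
    """Independent direct-summation W with tie correction."""
    arr = np.asarray(arr, dtype=float)
    m, n = arr.shape
    ranks = np.array([rankdata(row) for row in arr])
    Rj = ranks.sum(axis=0)
    Rbar = Rj.mean()
    S = sum((Rj[j] - Rbar) ** 2 for j in range(n))
    T = 0.0
    for row in arr:
        for v in set(row):
            t = int((row == v).sum())
            T += t**3 - t
    return 12.0 * S / (m**2 * (n**3 - n) - m * T)


class TestElicitWeights:
    def test_identical_rater_rows_give_proportional_weights(self):
        w = elicit_weights(_matrix([[6, 3, 1]] * 4))
        assert w.weights == pytest.approx({"i0": 0.6, "i1": 0.3, "i2": 0.1})

    def test_item_means_8_2_10_give_04_01_05(self):
        # any matrix whose column means are in ratio 8:2:10
        w = elicit_weights(_matrix([[8, 2, 10], [7, 1, 10], [9, 3, 10], [8, 2, 10]]))
        assert w.weights["i0"] == pytest.approx(0.4)
        assert w.weights["i1"] == pytest.approx(0.1)
        assert w.weights["i2"] == pytest.approx(0.5)

    def test_trimmed_means_match_hand_computation(self):
        scores = [[10, 2], [6, 4], [5, 5], [4, 6], [1, 8]]
        w = elicit_weights(_matrix(scores), trim=True)
        # per item drop one max and one min: (6+5+4)/3 = 5 and (4+5+6)/3 = 5
        assert w.weights == pytest.approx({"i0": 0.5, "i1": 0.5})
        assert w.trimmed

    def test_trim_needs_at_least_four_raters(self):
        with pytest.raises(ValueError, match="4 raters"):
            elicit_weights(_matrix([[5, 5], [4, 6], [6, 4]]), trim=True)

    def test_scale_invariance_of_weights(self):
        base = np.array([[4, 2, 1], [3, 2, 2], [5, 1, 3], [4, 3, 1]])
        w1 = elicit_weights(_matrix(base)).weights
        w2 = elicit_weights(_matrix(2 * base)).weights
        assert w1 == pytest.approx(w2)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            arr = rng.integers(1, 11, size=(5, 4))
            w = elicit_weights(_matrix(arr))
            assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_feature_name_mapping(self):
        w = elicit_weights(_matrix([[8, 2, 10]] * 3),
                           items_as_features=["spec", "name", "quality"])
        assert w.weights == pytest.approx({"spec": 0.4, "name": 0.1, "quality": 0.5})


class TestKendallsW:
    def test_identical_untied_rankings_give_one(self):
        W, chi2, df, p = kendalls_w(_matrix([[1, 5, 3, 8]] * 6))
        assert W == pytest.approx(1.0)
        assert df == 3
        assert p < 0.05

    def test_latin_square_rankings_give_zero(self):
        W, _c, _d, p = kendalls_w(_matrix([[1, 2, 3], [2, 3, 1], [3, 1, 2]]))
        assert W == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_summation_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            arr = rng.integers(1, 11, size=(int(rng.integers(2, 8)), int(rng.integers(2, 8))))
            W, chi2, df, _p = kendalls_w(_matrix(arr))
            m, n = arr.shape
            assert W == pytest.approx(kendalls_w_direct(arr), abs=1e-12)
            assert chi2 == pytest.approx(m * (n - 1) * W)
            assert 0.0 <= W <= 1.0

    def test_invariant_to_rater_order_and_monotone_rescoring(self):
        arr = np.array([[3, 1, 9, 5], [2, 2, 8, 4], [4, 1, 10, 6]])
        W1 = kendalls_w(_matrix(arr))[0]
        W2 = kendalls_w(_matrix(arr[::-1]))[0]
        # squeeze scores monotonically (ranks preserved, ties preserved)
        squeezed = np.ceil(arr / 2).astype(int)
        assert (np.array([rankdata(r) for r in squeezed]) ==
                np.array([rankdata(r) for r in arr])).all()
        W3 = kendalls_w(_matrix(squeezed))[0]
        assert W1 == pytest.approx(W2) == pytest.approx(W3)

    def test_fully_tied_panel_is_undefined(self):
        with pytest.raises(ConcordanceUndefined):
            kendalls_w(_matrix([[4, 4, 4], [7, 7, 7]]))


class TestEccScore:
    def _weights(self):
        return ECCWeights(
            {"doctor_specialty": 0.4, "reveal_real_name": 0.1, "case_quality": 0.5},
            (1.0, 0.0, 2, 1.0),
        )

    def test_all_values_at_domain_maximum_give_one(self, fna_schema, small_base):
        c = small_base.cases[0]
        case = Case("q", {**c.values, "doctor_specialty": 10, "reveal_real_name": 1,
                          "case_quality": 10})
        assert ecc_score(case, self._weights(), fna_schema) == pytest.approx(1.0)

    def test_hand_arithmetic_on_typical_values(self, fna_schema, small_base):
        c = small_base.cases[0]
        case = Case("q", {**c.values, "doctor_specialty": 5, "reveal_real_name": 1,
                          "case_quality": 8})
        expected = 0.4 * (4 / 9) + 0.1 * 1 + 0.5 * (7 / 9)
        assert ecc_score(case, self._weights(), fna_schema) == pytest.approx(expected)

    def test_unit_weight_projects_single_feature(self, fna_schema, small_base):
        c = small_base.cases[0]
        w = ECCWeights({"doctor_specialty": 1.0, "reveal_real_name": 0.0,
                        "case_quality": 0.0}, (1.0, 0.0, 2, 1.0))
        case = Case("q", {**c.values, "doctor_specialty": 7})
        assert ecc_score(case, w, fna_schema) == pytest.approx(6 / 9)

    def test_score_always_in_unit_interval(self, fna_schema, small_base):
        w = self._weights()
        for c in small_base.cases[:20]:
            assert 0.0 <= ecc_score(c, w, fna_schema) <= 1.0


class TestHarmonicFuse:
    def test_equal_inputs_are_fixed_points(self):
        assert harmonic_fuse(0.8, 0.8) == pytest.approx(0.8)

    def test_zero_annihilates(self):
        assert harmonic_fuse(0.9, 0.0) == 0.0
        assert harmonic_fuse(0.0, 0.0) == 0.0

    def test_hand_arithmetic(self):
        assert harmonic_fuse(0.8, 0.4) == pytest.approx(2 * 0.8 * 0.4 / 1.2)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            harmonic_fuse(-0.1, 0.5)

    def test_mean_inequality_chain(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 1, 500)
        p = rng.uniform(0, 1, 500)
        for a, b in zip(s, p):
            h = harmonic_fuse(a, b)
            assert min(a, b) - 1e-12 <= h <= np.sqrt(a * b) + 1e-12 <= (a + b) / 2 + 1e-12
            assert h == pytest.approx(harmonic_fuse(b, a))


class TestRerank:
    def test_uniform_ecc_preserves_similarity_order(self, small_base):
        q = small_base.cases[0]
        ranked = retrieve(q, small_base, 8, small_base.schema)
        uniform = CaseBase(
            small_base.schema,
            [Case(c.id, {**c.values, "doctor_specialty": 6, "reveal_real_name": 1,
                         "case_quality": 6}, c.label) for c in small_base],
        )
        w = ECCWeights({"doctor_specialty": 0.4, "reveal_real_name": 0.1,
                        "case_quality": 0.5}, (1.0, 0.0, 2, 1.0))
        fused = rerank_with_ecc(ranked, uniform, w, small_base.schema)
        assert fused.ids == ranked.ids
        assert [e[5] for e in fused.entries] == [e[4] for e in fused.entries]

    def test_strong_provenance_promotes_lower_similarity_case(self):
        # S (0.86, 0.77) with P (0.50, 0.95): fused order swaps
        assert harmonic_fuse(0.77, 0.95) > harmonic_fuse(0.86, 0.50)

    def test_rerank_is_a_permutation(self, small_base):
        q = small_base.cases[3]
        ranked = retrieve(q, small_base, 10, small_base.schema)
        w = elicit_weights(
            _matrix([[8, 2, 10]] * 4),
            items_as_features=["doctor_specialty", "reveal_real_name", "case_quality"],
        )
        fused = rerank_with_ecc(ranked, small_base, w, small_base.schema)
        assert sorted(fused.ids) == sorted(ranked.ids)
        assert [e[5] for e in fused.entries] == list(range(1, len(fused.entries) + 1))

    def test_fused_sorted_descending_with_similarity_tiebreak(self, small_base):
        q = small_base.cases[3]
        ranked = retrieve(q, small_base, 12, small_base.schema)
        w = ECCWeights({"doctor_specialty": 0.4, "reveal_real_name": 0.1,
                        "case_quality": 0.5}, (1.0, 0.0, 2, 1.0))
        fused = rerank_with_ecc(ranked, small_base, w, small_base.schema)
        sps = [e[3] for e in fused.entries]
        assert sps == sorted(sps, reverse=True)

    def test_unresolvable_id_errors(self, small_base):
        from cbrecc.retrieval import RankedRetrieval
        from cbrecc.casebase import CaseBaseError

        ranked = RankedRetrieval("q", [("nope", 0.5, 1)], 1)
        w = ECCWeights({"doctor_specialty": 1.0, "reveal_real_name": 0.0,
                        "case_quality": 0.0}, (1.0, 0.0, 2, 1.0))
        with pytest.raises(CaseBaseError, match="nope"):
            rerank_with_ecc(ranked, small_base, w, small_base.schema)


class TestScoreMatrixIO:
    def test_csv_round_trip(self, tmp_path):
        m = _matrix([[1, 10, 5], [2, 9, 6]])
        path = tmp_path / "scores.csv"
        m.to_csv(path)
        back = ExpertScoreMatrix.from_csv(path)
        assert back.raters == m.raters and back.items == m.items
        assert (back.scores == m.scores).all()

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError, match="1, 10"):
            _matrix([[0, 5], [3, 4]])
        with pytest.raises(ValueError, match="2 raters"):
            _matrix([[3, 4]])
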