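"""Weighted local-similarity matching, KNN retrieval and K selection."""

import numpy as np
import pytest

from cbrecc import (
    Case,
    CaseBase,
    FeatureSpec,
    GeneratorConfig,
    case_similarity,
    generate_casebase,
    knn_fusion_score,
    local_similarity,
    retrieve,
    select_optimal_k,
)
from cbrecc.retrieval import RankedRetrieval, RetrievalError

from conftest import random_toy_base


def brute_force_retrieve(query, subbase, k, schema):
    sims = [(case_similarity(query, c, schema), c.id) for c in subbase]
    sims.sort(key=lambda t: (-t[0], t[1]))
    return [(cid, s) for s, cid in sims[: min(k, len(subbase))]]


class TestLocalSimilarity:
    def test_identity_is_one_for_every_kind(self):
        num = FeatureSpec("x", "numeric", "internal", (0, 10))
        cat = FeatureSpec("g", "categorical", "internal", ("a", "b", "c"))
        assert local_similarity(4.2, 4.2, num) == 1.0
        assert local_similarity("b", "b", cat) == 1.0

    def test_domain_endpoints_are_maximally_dissimilar(self):
        spec = FeatureSpec("x", "numeric", "internal", (0, 10))
        assert local_similarity(0, 10, spec) == 0.0

    def test_age_gap_hand_arithmetic(self):
        spec = FeatureSpec("age", "numeric", "internal", (10, 95))
        assert local_similarity(29, 19, spec) == pytest.approx(1 - 10 / 85)

    def test_symmetry(self):
        spec = FeatureSpec("x", "numeric", "internal", (1, 5))
        assert local_similarity(2, 4, spec) == local_similarity(4, 2, spec)

    def test_categorical_mismatch_is_zero(self):
        cat = FeatureSpec("g", "categorical", "internal", ("a", "b", "c"))
        assert local_similarity("a", "c", cat) == 0.0


class TestCaseSimilarity:
    def test_weighted_hand_arithmetic(self, toy_schema):
        # local sims (1.0, 0.5, 0.0) with weights (2, 1, 1) -> 0.625
        q = Case("q", {"a": 5.0, "b": 0.0, "c": 0})
        r = Case("r", {"a": 5.0, "b": 5.0, "c": 1})
        assert case_similarity(q, r, toy_schema) == pytest.approx(0.625)

    def test_self_similarity_is_one(self, small_base):
        for c in small_base.cases[:5]:
            assert case_similarity(c, c, small_base.schema) == pytest.approx(1.0)

    def test_maximal_dissimilarity_is_zero(self, toy_schema):
        q = Case("q", {"a": 0.0, "b": 0.0, "c": 0})
        r = Case("r", {"a": 10.0, "b": 10.0, "c": 1})
        assert case_similarity(q, r, toy_schema) == 0.0

    def test_symmetry_and_range(self, small_base):
        rng = np.random.default_rng(2)
        cases = small_base.cases
        for _ in range(20):
            a, b = rng.choice(len(cases), size=2, replace=False)
            s1 = case_similarity(cases[a], cases[b], small_base.schema)
            s2 = case_similarity(cases[b], cases[a], small_base.schema)
            assert s1 == pytest.approx(s2)
            assert 0.0 <= s1 <= 1.0

    def test_ecc_features_do_not_enter_similarity(self, small_base):
        a, b = small_base.cases[0], small_base.cases[1]
        mutated = Case(b.id, {**b.values, "case_quality": 1, "doctor_specialty": 1}, b.label)
        assert case_similarity(a, b, small_base.schema) == pytest.approx(
            case_similarity(a, mutated, small_base.schema)
        )


class TestRetrieve:
    def test_k_saturates_at_base_size(self, small_base):
        q = small_base.cases[0]
        out = retrieve(q, small_base, 10_000, small_base.schema)
        assert len(out.entries) == len(small_base)
        assert [r for _c, _s, r in out.entries] == list(range(1, len(small_base) + 1))

    def test_identical_stored_case_is_rank_one(self, small_base):
        stored = small_base.cases[7]
        q = Case("query", dict(stored.values))
        out = retrieve(q, small_base, 3, small_base.schema)
        assert out.entries[0][0] == stored.id
        assert out.entries[0][1] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_bases(self):
        rng = np.random.default_rng(33)
        for _ in range(15):
            base = random_toy_base(rng, int(rng.integers(5, 40)), 3)
            q = Case("q", {s.name: base.cases[0].values[s.name] for s in base.schema.internal})
            k = int(rng.integers(1, 10))
            ours = retrieve(q, base, k, base.schema)
            ref = brute_force_retrieve(q, base, k, base.schema)
            assert [(c, pytest.approx(s)) for c, s, _r in ours.entries] == ref

    def test_similarity_ties_break_by_ascending_id(self, toy_schema):
        cases = [
            Case("b", {"a": 4.0, "b": 0.0, "c": 0}, 0),
            Case("a", {"a": 4.0, "b": 0.0, "c": 0}, 1),
            Case("c", {"a": 9.0, "b": 9.0, "c": 1}, 0),
        ]
        base = CaseBase(toy_schema, cases)
        q = Case("q", {"a": 4.0, "b": 0.0, "c": 0})
        out = retrieve(q, base, 3, toy_schema)
        assert out.ids[:2] == ["a", "b"]

    def test_empty_subbase_raises_routing_error(self, toy_schema):
        with pytest.raises(RetrievalError, match="routing"):
            retrieve(Case("q", {"a": 1.0, "b": 1.0, "c": 0}), CaseBase(toy_schema, []), 3, toy_schema)


class TestFusionScore:
    def _ranked(self, sims_and_ids):
        entries = [(cid, s, r + 1) for r, (cid, s) in enumerate(sims_and_ids)]
        return RankedRetrieval("q", entries, k_used=len(entries))

    def test_unanimous_labels_give_their_value(self, toy_schema):
        q = Case("q", {"a": 1.0, "b": 1.0, "c": 0})
        ranked = self._ranked([("x", 0.9), ("y", 0.5)])
        assert knn_fusion_score(q, ranked, {"x": 1, "y": 1}, toy_schema) == 1.0

    def test_equal_distance_split_labels_give_half(self, toy_schema):
        q = Case("q", {"a": 1.0, "b": 1.0, "c": 0})
        ranked = self._ranked([("x", 0.7), ("y", 0.7)])
        assert knn_fusion_score(q, ranked, {"x": 0, "y": 1}, toy_schema) == pytest.approx(0.5)

    def test_three_neighbour_hand_arithmetic(self, toy_schema):
        q = Case("q", {"a": 1.0, "b": 1.0, "c": 0})
        ranked = self._ranked([("x", 0.8), ("y", 0.6), ("z", 0.5)])
        sp = knn_fusion_score(q, ranked, {"x": 1, "y": 0, "z": 1}, toy_schema)
        assert sp == pytest.approx((5 + 2) / (5 + 2.5 + 2))

    def test_exact_match_short_circuits_to_its_label(self, toy_schema):
        q = Case("q", {"a": 1.0, "b": 1.0, "c": 0})
        ranked = self._ranked([("x", 1.0), ("y", 0.2)])
        assert knn_fusion_score(q, ranked, {"x": 0, "y": 1}, toy_schema) == 0.0

    def test_monotone_in_neighbour_labels(self, toy_schema):
        rng = np.random.default_rng(5)
        q = Case("q", {"a": 1.0, "b": 1.0, "c": 0})
        for _ in range(20):
            sims = rng.uniform(0.05, 0.95, size=4)
            ranked = self._ranked([(f"n{i}", float(s)) for i, s in enumerate(sims)])
            labels = {f"n{i}": int(rng.integers(0, 2)) for i in range(4)}
            sp0 = knn_fusion_score(q, ranked, labels, toy_schema)
            flip = next((k for k, v in labels.items() if v == 0), None)
            if flip is None:
                continue
            sp1 = knn_fusion_score(q, ranked, {**labels, flip: 1}, toy_schema)
            assert sp1 >= sp0

    def test_closer_neighbour_pulls_score_toward_its_label(self, toy_schema):
        q = Case("q", {"a": 1.0, "b": 1.0, "c": 0})
        labels = {"x": 1, "y": 0}
        near = self._ranked([("x", 0.9), ("y", 0.5)])
        far = self._ranked([("x", 0.6), ("y", 0.5)])
        assert knn_fusion_score(q, near, labels, toy_schema) > \
            knn_fusion_score(q, far, labels, toy_schema)


class TestSelectOptimalK:
    def test_singleton_grid_returns_that_k(self, small_base):
        cv = select_optimal_k(small_base, [3], folds=3, seed=0)
        assert cv.best_k == 3 and len(cv.grid) == 1

    def test_same_seed_reproduces_result(self, small_base):
        a = select_optimal_k(small_base, [1, 2, 3, 5], folds=3, seed=42)
        b = select_optimal_k(small_base, [1, 2, 3, 5], folds=3, seed=42)
        assert a == b

    def test_separable_base_reaches_perfect_accuracy(self, separable_base):
        cv = select_optimal_k(separable_base, [1, 2, 3], folds=3, seed=0)
        best_acc = max(a for _k, a in cv.grid)
        assert best_acc == 1.0

    def test_oversized_k_is_skipped_with_warning(self, small_base):
        with pytest.warns(UserWarning, match="skipped"):
            cv = select_optimal_k(small_base, [1, 1000], folds=3, seed=0)
        assert [k for k, _a in cv.grid] == [1]

    def test_smallest_maximizing_k_wins(self, separable_base):
        cv = select_optimal_k(separable_base, [4, 2, 1, 3], folds=3, seed=1)
        accs = dict(cv.grid)
        best = max(accs.values())
        assert cv.best_k == min(k for k, a in accs.items() if a == best)
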