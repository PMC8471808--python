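"""Phase II: weighted local-similarity KNN retrieval and K selection.

Global similarity between a query and a stored case is the weighted mean
of per-feature local similarities over the internal channel,

    S(I, R) = Σ_i w_i · sim(f_i^I, f_i^R) / Σ_i w_i,

with sim = 1 − |a − b| / width for numeric/ordinal features and an
equality indicator for binary/categorical ones.  Retrieval is an
exhaustive scan of the (usually class-matched) sub-base; at the scale of
clinical case bases (~10^3 cases) no approximate index is warranted.

The fusion score of a neighbourhood,

    Sp = Σ w · d^{-1} · y / Σ w · d^{-1},     d = 1 − S,

is an inverse-distance-weighted mean of the neighbour labels; a
zero-distance (exact) match short-circuits Sp to the mean label of all
exact matches.  ``select_optimal_k`` picks K by stratified cross-validated
classification accuracy of this score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .casebase import Case, CaseBase, CaseBaseError
from .schema import FeatureSchema, FeatureSpec, SchemaError


class RetrievalError(ValueError):
    """Retrieval preconditions violated (e.g. empty candidate sub-base)."""


@dataclass
class RankedRetrieval:
    """Ordered retrieval result: (case_id, similarity, rank) triples.

    Entries are sorted by similarity descending, ties broken by ascending
    case id; ranks run 1..len(entries) without gaps.
    """

    query_id: str
    entries: list[tuple[str, float, int]]
    k_used: int

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def to_json(self, path) -> None:
        doc = {
            "query_id": self.query_id,
            "k_used": self.k_used,
            "entries": [
                {"case_id": cid, "similarity": s, "rank": r} for cid, s, r in self.entries
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_table(self, base: CaseBase) -> pd.DataFrame:
        """Wide table, one column per retrieved case: similarity row first,
        then the feature values — the layout used for case-comparison
        printouts."""
        cols = {}
        feat_names = [f.name for f in base.schema.features if f.channel in ("internal", "ecc")]
        for cid, s, _r in self.entries:
            case = base[cid]
            col = {"similarity": s}
            for name in feat_names:
                col[name] = case.values[name]
            col[base.schema.label.name] = case.label
            cols[cid] = col
        return pd.DataFrame(cols)


@dataclass
class CVResult:
    """Cross-validation grid for K with the smallest maximizing K."""

    grid: list[tuple[int, float]]
    best_k: int
    folds: int
    seed: int

    def to_json(self, path) -> None:
        doc = {
            "grid": [{"k": k, "mean_accuracy": a} for k, a in self.grid],
            "best_k": self.best_k,
            "folds": self.folds,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def local_similarity(a, b, spec: FeatureSpec) -> float:
    """Per-feature similarity in [0, 1].

    Numeric/ordinal: 1 − |a−b| / domain width (1.0 for a zero-width
    domain); binary/categorical: 1.0 iff equal.
    """
    if spec.kind in ("numeric", "ordinal"):
        w = spec.width
        if w == 0:
            return 1.0
        return 1.0 - abs(float(a) - float(b)) / w
    return 1.0 if a == b else 0.0


def case_similarity(query: Case, stored: Case, schema: FeatureSchema) -> float:
    """Weighted mean of local similarities over internal features."""
    specs = [f for f in schema.internal if f.weight > 0]
    if not specs:
        raise SchemaError("no internal features with positive weight")
    num = 0.0
    den = 0.0
    for spec in specs:
        num += spec.weight * local_similarity(query.values[spec.name], stored.values[spec.name], spec)
        den += spec.weight
    return num / den


# -- vectorized similarity (same semantics, array path) ---------------------


def _encode(cases: Sequence[Case], schema: FeatureSchema) -> np.ndarray:
    """Internal features as a float matrix; categorical levels as codes."""
    specs = [f for f in schema.internal if f.weight > 0]
    out = np.empty((len(cases), len(specs)))
    for j, spec in enumerate(specs):
        if spec.kind in ("numeric", "ordinal"):
            out[:, j] = [float(c.values[spec.name]) for c in cases]
        else:
            codes = {lv: float(i) for i, lv in enumerate(spec.domain)}
            out[:, j] = [codes[c.values[spec.name]] for c in cases]
    return out


def _similarity_matrix(Q: np.ndarray, X: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    """Pairwise similarities, rows = queries, cols = stored cases."""
    specs = [f for f in schema.internal if f.weight > 0]
    w = np.array([f.weight for f in specs])
    S = np.zeros((Q.shape[0], X.shape[0]))
    for j, spec in enumerate(specs):
        d = Q[:, j][:, None] - X[:, j][None, :]
        if spec.kind in ("numeric", "ordinal"):
            width = spec.width
            sim = 1.0 - np.abs(d) / width if width else np.ones_like(d)
        else:
            sim = (d == 0).astype(float)
        S += w[j] * sim
    return S / w.sum()


def retrieve(query: Case, subbase: CaseBase, k: int, schema: FeatureSchema) -> RankedRetrieval:
    """Top-min(k, |subbase|) most similar cases by exhaustive scan.

    The sub-base is normally the class-matched sub-base chosen by Phase-I
    triage of the query; an empty one means triage produced no candidates.
    """
    if len(subbase) == 0:
        raise RetrievalError("empty sub-base: Phase-I routing produced no candidates")
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = _similarity_matrix(_encode([query], schema), _encode(subbase.cases, schema), schema)[0]
    order = sorted(range(len(subbase)), key=lambda i: (-sims[i], subbase.cases[i].id))
    top = order[: min(k, len(subbase))]
    entries = [(subbase.cases[i].id, float(sims[i]), r + 1) for r, i in enumerate(top)]
    return RankedRetrieval(query.id, entries, k_used=min(k, len(subbase)))


def knn_fusion_score(
    query: Case,
    neighbours: RankedRetrieval,
    labels: Mapping[str, int],
    schema: FeatureSchema,
    case_weights: Mapping[str, float] | None = None,
) -> float:
    """Inverse-distance-weighted mean label Sp of the retrieved neighbours.

    ``d = 1 − similarity``; any exact match (d = 0) short-circuits Sp to
    the mean label of the exact matches.  Per-case weights default to 1.
    """
    if not neighbours.entries:
        raise RetrievalError("empty neighbourhood")
    missing = [cid for cid, _s, _r in neighbours.entries if cid not in labels]
    if missing:
        raise CaseBaseError(f"label map missing neighbour id(s): {missing[:5]}")
    wmap = case_weights or {}
    exact = [labels[cid] for cid, s, _r in neighbours.entries if 1.0 - s == 0.0]
    if exact:
        return float(np.mean(exact))
    num = 0.0
    den = 0.0
    for cid, s, _r in neighbours.entries:
        d = 1.0 - s
        w = wmap.get(cid, 1.0) / d
        num += w * labels[cid]
        den += w
    return num / den


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per case; each class spread round-robin after a shuffle."""
    assignment = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def select_optimal_k(
    base: CaseBase,
    k_grid: Sequence[int],
    folds: int,
    seed: int,
    schema: FeatureSchema | None = None,
) -> CVResult:
    """Choose K by stratified K-fold cross-validated Sp classification.

    Each held-out case is classified against the training folds: its k
    nearest neighbours (whole training fold, both classes) vote through
    the fusion score Sp, with Sp > 0.5 → malignant and ties → benign.
    Among grid values attaining the maximal mean accuracy the smallest K
    wins.  A grid point exceeding the smallest per-class training count is
    skipped with a warning.  Fully reproducible from ``seed``.
    """
    schema = schema or base.schema
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.array([c.label for c in base])
    if any(l is None for l in y):
        raise CaseBaseError("all cases must be labelled for cross-validation")
    class_counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if min(class_counts.values()) < folds:
        raise CaseBaseError("each class needs at least `folds` members")

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, folds, rng)
    X = _encode(base.cases, schema)

    # per-fold: sorted neighbour labels + similarities, largest first
    fold_sorted: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    min_train_class = np.inf
    for f in range(folds):
        test = fold_of == f
        train = ~test
        for c in class_counts:
            min_train_class = min(min_train_class, int((y[train] == c).sum()))
        S = _similarity_matrix(X[test], X[train], schema)
        train_ids = np.array([base.cases[i].id for i in np.flatnonzero(train)])
        # descending similarity, ties by ascending id (match retrieve())
        order = np.lexsort((train_ids[None, :].repeat(S.shape[0], 0), -S), axis=1)
        S_sorted = np.take_along_axis(S, order, axis=1)
        y_sorted = y[train][order]
        fold_sorted.append((S_sorted, y_sorted, np.flatnonzero(test)))

    grid: list[tuple[int, float]] = []
    for k in k_grid:
        if k > min_train_class:
            warnings.warn(f"k={k} exceeds the smallest training-fold class count; skipped")
            continue
        correct = 0
        for S_sorted, y_sorted, test_idx in fold_sorted:
            s_k = S_sorted[:, :k]
            y_k = y_sorted[:, :k]
            d = 1.0 - s_k
            with np.errstate(divide="ignore"):
                inv = 1.0 / d
            exact = d == 0.0
            has_exact = exact.any(axis=1)
            sp = np.empty(len(s_k))
            if has_exact.any():
                sp[has_exact] = np.array(
                    [y_k[i][exact[i]].mean() for i in np.flatnonzero(has_exact)]
                )
            rest = ~has_exact
            sp[rest] = (inv[rest] * y_k[rest]).sum(axis=1) / inv[rest].sum(axis=1)
            pred = (sp > 0.5).astype(int)
            correct += int((pred == y[test_idx]).sum())
        grid.append((int(k), correct / len(base)))

    if not grid:
        raise ValueError("no usable k in the grid")
    best_acc = max(a for _k, a in grid)
    best_k = min(k for k, a in grid if a == best_acc)
    return CVResult(grid, best_k, folds, seed)
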