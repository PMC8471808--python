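"""Phase III: ECC weight elicitation, concordance testing, and
harmonic-mean re-ranking of retrieved cases.

External case characteristics (ECC) — the recording doctor's specialty
score, their willingness to reveal their real name, and a peer
case-quality score — describe a case's provenance and appraisal rather
than its clinical content.  Weights for these attributes are elicited
from a panel of expert raters: each item's weight is its mean score
divided by the sum of all items' mean scores, optionally after trimming
one maximum and one minimum score per item.  Panel agreement is checked
with Kendall's coefficient of concordance W (mid-ranks, standard tie
correction, chi-square p-value).

A retrieved case's ECC score P_t = Σ w_i·x̃_i uses domain-normalized
values x̃ ∈ [0, 1], making P_t commensurate with the content similarity
S_t; the two are fused by the binary harmonic mean

    SP_t = 2·S_t·P_t / (S_t + P_t),

whose pull toward the smaller operand penalizes cases that are similar
but poorly sourced (or vice versa).  Re-ranking by SP_t can promote a
lower-similarity case with strong provenance above a higher-similarity
one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .casebase import Case, CaseBase, CaseBaseError
from .retrieval import RankedRetrieval
from .schema import FeatureSchema, SchemaError


class ConcordanceUndefined(ValueError):
    """Kendall's W is undefined (every rater ties every item)."""


@dataclass
class ExpertScoreMatrix:
    """Complete m×n matrix of integer scores in [1, 10], raters × items."""

    raters: list[str]
    items: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        m, n = self.scores.shape
        if m != len(self.raters) or n != len(self.items):
            raise ValueError("score matrix shape does not match rater/item lists")
        if m < 2 or n < 2:
            raise ValueError("need at least 2 raters and 2 items")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix must be complete")
        if (self.scores < 1).any() or (self.scores > 10).any():
            raise ValueError("scores must lie in [1, 10]")

    @classmethod
    def from_csv(cls, path) -> "ExpertScoreMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.scores, index=self.raters, columns=self.items).to_csv(path)


@dataclass
class ECCWeights:
    """Normalized ECC feature weights with concordance diagnostics."""

    weights: dict[str, float]
    concordance: tuple[float, float, int, float]  # (W, chi_square, df, p_value)
    trimmed: bool = False

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {total}")

    def to_json(self, path) -> None:
        W, x2, df, p = self.concordance
        doc = {
            "weights": dict(sorted(self.weights.items())),
            "concordance": {"W": W, "chi_square": x2, "df": df, "p_value": p},
            "trimmed": self.trimmed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ECCWeights":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        c = doc["concordance"]
        return cls(doc["weights"], (c["W"], c["chi_square"], c["df"], c["p_value"]), doc["trimmed"])


@dataclass
class FusedRetrieval:
    """Re-ranked retrieval: (case_id, S_t, P_t, SP_t, rank_without_ecc,
    rank_with_ecc), sorted by SP_t descending (ties: higher S_t, then
    ascending id)."""

    query_id: str
    entries: list[tuple[str, float, float, float, int, int]]

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    def to_json(self, path) -> None:
        doc = {
            "query_id": self.query_id,
            "entries": [
                {
                    "case_id": cid,
                    "similarity": s,
                    "ecc_score": p,
                    "fused": sp,
                    "rank_without_ecc": r0,
                    "rank_with_ecc": r1,
                }
                for cid, s, p, sp, r0, r1 in self.entries
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_csv(self, path) -> None:
        """Two-block comparison table: similarity-only ordering next to the
        ECC-fused ordering."""
        without = sorted(self.entries, key=lambda e: e[4])
        with_ecc = sorted(self.entries, key=lambda e: e[5])
        df = pd.DataFrame(
            {
                "index_without_ecc": [e[0] for e in without],
                "sorting_value_without_ecc": [e[1] for e in without],
                "index_with_ecc": [e[0] for e in with_ecc],
                "sorting_value_with_ecc": [e[3] for e in with_ecc],
            }
        )
        df.to_csv(path, index=False)


def elicit_weights(
    scores: ExpertScoreMatrix,
    trim: bool = False,
    items_as_features: Sequence[str] | None = None,
) -> ECCWeights:
    """Weights from item means: w_i = mean_i / Σ_j mean_j.

    With ``trim=True`` (needs ≥ 4 raters) one maximal and one minimal
    score are removed per item before averaging.  Concordance is always
    computed on the untrimmed matrix.
    """
    X = scores.scores.astype(float)
    m, _n = X.shape
    if trim:
        if m < 4:
            raise ValueError("trimmed elicitation needs at least 4 raters")
        Xs = np.sort(X, axis=0)
        means = Xs[1:-1].mean(axis=0)
    else:
        means = X.mean(axis=0)
    w = means / means.sum()
    names = list(items_as_features) if items_as_features is not None else scores.items
    if len(names) != len(w):
        raise ValueError("feature-name list length must match item count")
    return ECCWeights(dict(zip(names, w.tolist())), kendalls_w(scores), trimmed=trim)


def kendalls_w(scores: ExpertScoreMatrix) -> tuple[float, float, int, float]:
    """Kendall's coefficient of concordance with tie correction.

    Items are ranked within each rater (mid-ranks).  With R_j the rank
    totals, S = Σ_j (R_j − m(n+1)/2)² and T_r = Σ_groups (t³ − t) the
    per-rater tie correction,

        W = 12·S / (m²(n³ − n) − m·Σ_r T_r),

    chi_square = m(n−1)·W on df = n−1, p from the upper tail.
    """
    X = scores.scores.astype(float)
    m, n = X.shape
    ranks = np.vstack([rankdata(row) for row in X])
    T = 0.0
    for row in X:
        _levels, counts = np.unique(row, return_counts=True)
        T += float((counts**3 - counts).sum())
    R = ranks.sum(axis=0)
    S = float(((R - m * (n + 1) / 2.0) ** 2).sum())
    denom = m**2 * (n**3 - n) - m * T
    if denom == 0:
        raise ConcordanceUndefined("every rater ties every item; W is undefined")
    W = 12.0 * S / denom
    chi_square = m * (n - 1) * W
    df = n - 1
    p = float(chi2.sf(chi_square, df))
    return (W, chi_square, df, p)


def ecc_score(case: Case, weights: ECCWeights, schema: FeatureSchema) -> float:
    """Weighted ECC score P_t = Σ w_i·x̃_i with domain-normalized values.

    Ordinal/numeric ECC values map to (x − lo)/(hi − lo) — a 1–10 score
    becomes (x − 1)/9 — and binary values enter as-is, so P_t ∈ [0, 1].
    """
    ecc_specs = {f.name: f for f in schema.ecc}
    if set(weights.weights) != set(ecc_specs):
        raise SchemaError(
            f"weights cover {sorted(weights.weights)} but schema declares "
            f"ECC features {sorted(ecc_specs)}"
        )
    total = 0.0
    for name, w in weights.weights.items():
        if name not in case.values:
            raise CaseBaseError(f"case {case.id!r} is missing ECC feature {name!r}")
        spec = ecc_specs[name]
        x = case.values[name]
        if spec.kind in ("numeric", "ordinal"):
            lo, hi = spec.domain
            xn = (float(x) - lo) / (hi - lo)
        elif spec.kind == "binary":
            xn = float(x == spec.domain[1])
        else:
            raise SchemaError(f"categorical ECC feature {name!r} has no numeric scale")
        total += w * xn
    return total


def harmonic_fuse(s: float, p: float) -> float:
    """Binary harmonic mean SP_t = 2sp/(s+p); 0 when s + p = 0.

    Always min(s,p) ≤ SP_t ≤ √(sp) ≤ (s+p)/2, with equality iff s = p —
    the fused score leans toward the weaker of content similarity and
    provenance quality.
    """
    if s < 0 or p < 0:
        raise ValueError("harmonic fusion needs non-negative inputs")
    if s + p == 0:
        return 0.0
    return 2.0 * s * p / (s + p)


def rerank_with_ecc(
    retrieval: RankedRetrieval,
    base: CaseBase,
    weights: ECCWeights,
    schema: FeatureSchema,
) -> FusedRetrieval:
    """Fuse each retrieved case's similarity with its ECC score and re-sort.

    Both the similarity-only and the fused rank are retained so the effect
    of the ECC can be read off as a before/after comparison.
    """
    scored = []
    for cid, s, r0 in retrieval.entries:
        try:
            case = base[cid]
        except KeyError:
            raise CaseBaseError(f"retrieved id {cid!r} not present in the case base")
        p = ecc_score(case, weights, schema)
        scored.append((cid, s, p, harmonic_fuse(s, p), r0))
    scored.sort(key=lambda e: (-e[3], -e[1], e[0]))
    entries = [(cid, s, p, sp, r0, i + 1) for i, (cid, s, p, sp, r0) in enumerate(scored)]
    return FusedRetrieval(retrieval.query_id, entries)
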