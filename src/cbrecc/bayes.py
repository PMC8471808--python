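"""Phase I: naive Bayes triage of cases into benign/malignant.

The classifier assumes class-conditional independence of the internal
features.  Each feature contributes either a Gaussian class-conditional
density (numeric/ordinal, the default) or a Laplace-smoothed categorical
table (binary/categorical, or any feature after discretization).  The
posterior is computed in log space,

    log P(y | x)  ∝  log P(y) + Σ_i log P(x_i | y),

then normalized.  Ties in ``classify`` break to class 0 (benign).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .casebase import Case, CaseBase, CaseBaseError
from .schema import FeatureSchema, SchemaError

CLASSES = (0, 1)


@dataclass
class NBModel:
    """Fitted priors and per-feature class-conditional distributions.

    ``conditionals[name]`` is either
    ``{"mode": "gaussian", "params": {c: (mean, var)}}`` or
    ``{"mode": "categorical", "levels": [...], "tables": {c: {level: p}},
    "fallback": {c: p_unseen}}`` where the fallback is the smoothed
    zero-count cell used for levels never seen in training.
    """

    class_priors: dict[int, float]
    conditionals: dict[str, dict]
    feature_list: list[str]

    def to_json(self, path) -> None:
        doc = {
            "class_priors": {str(c): p for c, p in self.class_priors.items()},
            "feature_list": self.feature_list,
            "conditionals": {},
        }
        for name, cond in self.conditionals.items():
            if cond["mode"] == "gaussian":
                doc["conditionals"][name] = {
                    "mode": "gaussian",
                    "params": {str(c): list(v) for c, v in cond["params"].items()},
                }
            else:
                doc["conditionals"][name] = {
                    "mode": "categorical",
                    "levels": [str(lv) for lv in cond["levels"]],
                    "tables": {
                        str(c): {str(lv): p for lv, p in t.items()}
                        for c, t in cond["tables"].items()
                    },
                    "fallback": {str(c): p for c, p in cond["fallback"].items()},
                }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def fit_nb(
    base: CaseBase,
    alpha: float = 1.0,
    mode: Mapping[str, str] | None = None,
    features: Sequence[str] | None = None,
) -> NBModel:
    """Fit the naive Bayes model on a fully labelled case base.

    Parameters
    ----------
    alpha
        Laplace smoothing count for categorical conditionals.
    mode
        Optional per-feature override, ``{name: "gaussian" | "categorical"}``.
        By default numeric/ordinal features are Gaussian and
        binary/categorical features are categorical.
    features
        Features to use; defaults to every internal-channel feature.

    Gaussian variances are computed with the maximum-likelihood estimator
    and floored at ``1e-9 * width**2`` of the declared domain so that a
    constant feature yields a finite, sharply peaked density.
    """
    if len(base) == 0:
        raise CaseBaseError("cannot fit on an empty case base")
    labels = [c.label for c in base]
    if any(l is None for l in labels):
        raise CaseBaseError("all cases must be labelled")
    if len(set(labels)) < 2:
        raise CaseBaseError("both classes must be present")

    names = list(features) if features is not None else [f.name for f in base.schema.internal]
    n = len(base)
    by_class = {c: [case for case in base if case.label == c] for c in CLASSES}
    priors = {c: len(by_class[c]) / n for c in CLASSES}

    conditionals: dict[str, dict] = {}
    for name in names:
        spec = base.schema[name]
        m = (mode or {}).get(name) or (
            "gaussian" if spec.kind in ("numeric", "ordinal") else "categorical"
        )
        if m == "gaussian":
            if spec.kind not in ("numeric", "ordinal"):
                raise SchemaError(f"feature {name!r} is {spec.kind}; gaussian mode needs numeric")
            floor = 1e-9 * spec.width**2
            params = {}
            for c in CLASSES:
                xs = np.array([float(case.values[name]) for case in by_class[c]])
                params[c] = (float(xs.mean()), max(float(xs.var(ddof=0)), floor))
            conditionals[name] = {"mode": "gaussian", "params": params}
        elif m == "categorical":
            levels = list(spec.domain) if spec.kind in ("binary", "categorical") else sorted(
                {case.values[name] for case in base}
            )
            L = len(levels)
            tables, fallback = {}, {}
            for c in CLASSES:
                nc = len(by_class[c])
                counts = {lv: 0 for lv in levels}
                for case in by_class[c]:
                    v = case.values[name]
                    counts[v] = counts.get(v, 0) + 1
                tables[c] = {lv: (counts[lv] + alpha) / (nc + alpha * L) for lv in levels}
                fallback[c] = alpha / (nc + alpha * L)
            conditionals[name] = {
                "mode": "categorical",
                "levels": levels,
                "tables": tables,
                "fallback": fallback,
            }
        else:
            raise ValueError(f"unknown conditional mode {m!r}")
    return NBModel(priors, conditionals, names)


def _log_likelihood(model: NBModel, case: Case, c: int) -> float:
    ll = math.log(model.class_priors[c])
    for name in model.feature_list:
        if name not in case.values:
            raise CaseBaseError(f"case {case.id!r} is missing model feature {name!r}")
        v = case.values[name]
        cond = model.conditionals[name]
        if cond["mode"] == "gaussian":
            mean, var = cond["params"][c]
            x = float(v)
            ll += -0.5 * math.log(2 * math.pi * var) - (x - mean) ** 2 / (2 * var)
        else:
            p = cond["tables"][c].get(v, cond["fallback"][c])
            ll += math.log(p)
    return ll


def posterior(model: NBModel, case: Case) -> dict[int, float]:
    """Posterior class probabilities, normalized to sum to 1."""
    lls = np.array([_log_likelihood(model, case, c) for c in CLASSES])
    log_post = lls - logsumexp(lls)
    return {c: float(np.exp(lp)) for c, lp in zip(CLASSES, log_post)}


def classify(model: NBModel, case: Case) -> int:
    """Argmax of the posterior; an exact tie goes to class 0 (benign)."""
    post = posterior(model, case)
    return 1 if post[1] > post[0] else 0
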