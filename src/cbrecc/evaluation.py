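"""Confusion-matrix metrics, ROC/AUC and holdout evaluation drivers.

The positive class is 1 (malignant) throughout: TP = malignant predicted
malignant, FN = malignant predicted benign, FP = benign predicted
malignant, TN = benign predicted benign.  A ratio with a zero denominator
is reported as 0 and flagged.  The ROC sweeps a descending threshold over
the distinct scores (ties grouped); AUC is the trapezoid area, which
equals the Mann–Whitney concordant-pair statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .bayes import NBModel, classify, fit_nb, posterior
from .casebase import Case, CaseBase, CaseBaseError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Classification metrics plus ROC for one evaluated split."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    counts: ConfusionCounts
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            "roc": [[fpr, tpr] for fpr, tpr in self.roc],
            "auc": self.auc,
            "undefined": self.undefined,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        c = d["counts"]
        return cls(
            d["accuracy"], d["precision"], d["recall"], d["f_measure"],
            ConfusionCounts(c["tp"], c["tn"], c["fp"], c["fn"]),
            [tuple(p) for p in d["roc"]], d["auc"], list(d["undefined"]),
        )

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def confusion(predictions: Mapping[str, int], truth: Mapping[str, int]) -> ConfusionCounts:
    """Tally the confusion counts over a shared id set."""
    if set(predictions) != set(truth):
        raise CaseBaseError("prediction and truth id sets differ")
    tp = tn = fp = fn = 0
    for cid, yhat in predictions.items():
        y = truth[cid]
        if y == 1 and yhat == 1:
            tp += 1
        elif y == 0 and yhat == 0:
            tn += 1
        elif y == 0 and yhat == 1:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Accuracy, precision, recall and F-measure from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated cases")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f_measure")
        f = 0.0
    return EvalReport(accuracy, precision, recall, f, counts, undefined=undefined)


def roc_curve(
    scores: Mapping[str, float], truth: Mapping[str, int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (fpr, tpr) from (0,0) to (1,1) and the trapezoid AUC."""
    if set(scores) != set(truth):
        raise CaseBaseError("score and truth id sets differ")
    y = np.array([truth[i] for i in scores])
    s = np.array([scores[i] for i in scores], dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present in the truth")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # group tied scores
            j += 1
        tp += int((y[i:j] == 1).sum())
        fp += int((y[i:j] == 0).sum())
        points.append((fp / n0, tp / n1))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def stratified_split(
    labels: Mapping[str, int], test_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Stratified (train_ids, test_ids) split.

    Per stratum, floor(n_s · fraction) cases go to the test set; if the
    resulting test size falls short of floor(n · fraction), the deficit is
    drawn from the larger stratum.  Reproducible from ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(labels))
    y = np.array([labels[i] for i in ids])
    test: list[str] = []
    take = {}
    for c in np.unique(y):
        take[c] = int(np.floor((y == c).sum() * test_fraction))
    deficit = int(np.floor(len(ids) * test_fraction)) - sum(take.values())
    if deficit > 0:
        larger = max(np.unique(y), key=lambda c: (y == c).sum())
        take[larger] += deficit
    for c in np.unique(y):
        pool = ids[y == c].copy()
        rng.shuffle(pool)
        test.extend(pool[: take[c]].tolist())
    test_set = set(test)
    train = [i for i in ids.tolist() if i not in test_set]
    if not train or not test:
        raise ValueError("split emptied one side")
    for c in np.unique(y):
        if take[c] == (y == c).sum() or take[c] == 0:
            raise ValueError("split emptied a class in one side")
    return train, sorted(test)


def holdout_experiment(
    base: CaseBase,
    model_spec: Mapping | None = None,
    test_fraction: float = 1.0 / 3.0,
    seed: int = 0,
) -> EvalReport:
    """Stratified holdout of the naive Bayes triage classifier.

    Fits on the training portion, reports metrics and the ROC (scored by
    the malignant posterior) on the held-out portion.
    """
    spec = dict(model_spec or {})
    labels = base.labels()
    if len(labels) != len(base):
        raise CaseBaseError("holdout evaluation needs a fully labelled base")
    train_ids, test_ids = stratified_split(labels, test_fraction, seed)
    by_id = {c.id: c for c in base}
    train = CaseBase(base.schema, [by_id[i] for i in base.ids if i in set(train_ids)])
    model = fit_nb(train, alpha=spec.get("alpha", 1.0), mode=spec.get("mode"))
    preds = {}
    scores = {}
    truth = {}
    for i in test_ids:
        case = by_id[i]
        preds[i] = classify(model, case)
        scores[i] = posterior(model, case)[1]
        truth[i] = labels[i]
    report = metrics(confusion(preds, truth))
    report.roc, report.auc = roc_curve(scores, truth)
    return report


def plot_roc(reports: Mapping[str, EvalReport], path) -> None:
    """Write a ROC comparison figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        xs = [p[0] for p in rep.roc]
        ys = [p[1] for p in rep.roc]
        ax.plot(xs, ys, label=f"{name} (AUC {rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
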