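"""End-to-end orchestration of the three-phase retrieval pipeline.

Phase I triages a query with the naive Bayes model; Phase II retrieves
the K most similar cases from the class-matched sub-base; Phase III fuses
content similarity with the ECC score by the binary harmonic mean and
re-ranks.  Every run writes its intermediate artifacts and a manifest
(config hash + seed) so that identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import bayes, evaluation, fusion, preprocessing, retrieval
from .casebase import Case, CaseBase, load_casebase, partition_by_class
from .schema import FeatureSchema

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration mirroring the CLI flags.

    ``retrieval_k`` and ``cv`` are mutually exclusive (exactly one);
    when fusion is enabled exactly one of ``ecc_weights_path`` /
    ``ecc_scores_path`` must be given.
    """

    schema_path: str
    casebase_path: str
    seed: int
    outdir: str
    normalize: Mapping | None = None  # {"features": [...], "scale":, "shift":}
    nb_alpha: float = 1.0
    partition_source: str = "true"  # "true" labels or "nb" predictions
    retrieval_k: int | None = None
    cv: Mapping | None = None  # {"k_grid": [...], "folds": int}
    ecc_weights_path: str | None = None
    ecc_scores_path: str | None = None
    ecc_trim: bool = False
    fuse_ecc: bool = True

    def __post_init__(self) -> None:
        if (self.retrieval_k is None) == (self.cv is None):
            raise ValueError("specify exactly one of retrieval_k / cv")
        if self.partition_source not in ("true", "nb"):
            raise ValueError("partition_source must be 'true' or 'nb'")
        if self.fuse_ecc:
            if (self.ecc_weights_path is None) == (self.ecc_scores_path is None):
                raise ValueError("specify exactly one ECC weight source when fusion is enabled")

    def to_dict(self) -> dict:
        return {
            "schema_path": str(self.schema_path),
            "casebase_path": str(self.casebase_path),
            "seed": self.seed,
            "outdir": str(self.outdir),
            "normalize": dict(self.normalize) if self.normalize else None,
            "nb_alpha": self.nb_alpha,
            "partition_source": self.partition_source,
            "retrieval_k": self.retrieval_k,
            "cv": dict(self.cv) if self.cv else None,
            "ecc_weights_path": str(self.ecc_weights_path) if self.ecc_weights_path else None,
            "ecc_scores_path": str(self.ecc_scores_path) if self.ecc_scores_path else None,
            "ecc_trim": self.ecc_trim,
            "fuse_ecc": self.fuse_ecc,
        }

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def config_hash(self) -> str:
        """Content-addressed run fingerprint.

        Input files enter by the SHA-256 of their bytes and the output
        directory is excluded, so relocating a workspace does not change
        the hash; only the data and settings do.
        """

        def digest(path: str | None) -> str | None:
            if path is None:
                return None
            return hashlib.sha256(Path(path).read_bytes()).hexdigest()

        doc = self.to_dict()
        doc.pop("outdir")
        for key in ("schema_path", "casebase_path", "ecc_weights_path", "ecc_scores_path"):
            doc[key.replace("_path", "_sha256")] = digest(doc.pop(key))
        canon = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()


def _write_json(path: Path, doc) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_inputs(config: PipelineConfig) -> tuple[FeatureSchema, CaseBase]:
    schema = FeatureSchema.from_json(config.schema_path)
    base = load_casebase(config.casebase_path, schema)
    return schema, base


def _ecc_weights(config: PipelineConfig, schema: FeatureSchema) -> fusion.ECCWeights:
    if config.ecc_weights_path:
        return fusion.ECCWeights.from_json(config.ecc_weights_path)
    scores = fusion.ExpertScoreMatrix.from_csv(config.ecc_scores_path)
    ecc_names = [f.name for f in schema.ecc]
    return fusion.elicit_weights(scores, trim=config.ecc_trim, items_as_features=ecc_names)


def _choose_k(config: PipelineConfig, base: CaseBase, schema: FeatureSchema, outdir: Path) -> int:
    if config.retrieval_k is not None:
        return config.retrieval_k
    cv = retrieval.select_optimal_k(
        base,
        k_grid=list(config.cv.get("k_grid", range(1, 26))),
        folds=int(config.cv.get("folds", 10)),
        seed=config.seed,
        schema=schema,
    )
    cv.to_json(outdir / "cv.json")
    return cv.best_k


def run_pipeline(config: PipelineConfig, query: Case) -> fusion.FusedRetrieval | retrieval.RankedRetrieval:
    """Triage, retrieve and (optionally) ECC-fuse for a single query case.

    Returns the fused retrieval (or the plain ranked retrieval when Phase
    III is disabled); all intermediates land in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        schema, base = _load_inputs(config)
    except Exception as exc:
        raise PipelineError(f"load: {exc}") from exc

    if config.normalize:
        try:
            params = preprocessing.fit_normalizer(
                base,
                config.normalize["features"],
                scale=config.normalize.get("scale", 1.0),
                shift=config.normalize.get("shift", 0.0),
            )
            base = preprocessing.apply_normalizer(base, params)
            qbase = preprocessing.apply_normalizer(CaseBase(schema, [query]), params)
            query = qbase.cases[0]
            schema = base.schema
            params.to_json(outdir / "normalization.json")
        except Exception as exc:
            raise PipelineError(f"preprocess: {exc}") from exc

    try:
        model = bayes.fit_nb(base, alpha=config.nb_alpha)
        post = bayes.posterior(model, query)
        triage = bayes.classify(model, query)
        model.to_json(outdir / "nb_model.json")
        _write_json(outdir / "posterior.json", {"query_id": query.id,
                                                "posterior": {str(c): p for c, p in post.items()},
                                                "triage_class": triage})
    except Exception as exc:
        raise PipelineError(f"phase I (triage): {exc}") from exc

    try:
        if config.partition_source == "true":
            labels = base.labels()
        else:
            labels = {c.id: bayes.classify(model, c) for c in base}
        benign, malignant = partition_by_class(base, labels)
        subbase = malignant if triage == 1 else benign
        k = _choose_k(config, base, schema, outdir)
        ranked = retrieval.retrieve(query, subbase, k, schema)
        ranked.to_json(outdir / "retrieval.json")
        ranked.to_table(subbase).to_csv(outdir / "retrieval.csv")
    except retrieval.RetrievalError as exc:
        raise PipelineError(f"phase II (retrieval): no candidate cases — {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"phase II (retrieval): {exc}") from exc

    result: fusion.FusedRetrieval | retrieval.RankedRetrieval = ranked
    if config.fuse_ecc:
        try:
            weights = _ecc_weights(config, schema)
            weights.to_json(outdir / "ecc_weights.json")
            fused = fusion.rerank_with_ecc(ranked, base, weights, schema)
            fused.to_json(outdir / "fused.json")
            fused.to_csv(outdir / "fused.csv")
            result = fused
        except Exception as exc:
            raise PipelineError(f"phase III (fusion): {exc}") from exc

    _write_json(
        outdir / "manifest.json",
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_cases": len(base),
            "query_id": query.id,
            "triage_class": triage,
            "k_used": ranked.k_used,
            "fused": config.fuse_ecc,
        },
    )
    return result


def run_evaluation(config: PipelineConfig) -> dict:
    """Holdout + cross-validation study of Phases I and II.

    Produces the Phase-I naive Bayes holdout report, a plain-KNN holdout
    report at the selected K, the CV grid over K, and the combined
    triage→retrieval report at the best K.  Artifacts are written to the
    output directory; the dict maps report names to objects.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema, base = _load_inputs(config)
    labels = base.labels()
    train_ids, test_ids = evaluation.stratified_split(labels, 1.0 / 3.0, config.seed)
    by_id = {c.id: c for c in base}
    train = CaseBase(schema, [by_id[i] for i in base.ids if i in set(train_ids)])

    # Phase I: naive Bayes holdout
    model = bayes.fit_nb(train, alpha=config.nb_alpha)
    nb_preds = {i: bayes.classify(model, by_id[i]) for i in test_ids}
    nb_scores = {i: bayes.posterior(model, by_id[i])[1] for i in test_ids}
    truth = {i: labels[i] for i in test_ids}
    nb_report = evaluation.metrics(evaluation.confusion(nb_preds, truth))
    nb_report.roc, nb_report.auc = evaluation.roc_curve(nb_scores, truth)
    nb_report.to_json(outdir / "phase1_nb.json")

    # Phase II: K selection by stratified CV on the full labelled base
    if config.cv is not None:
        cv = retrieval.select_optimal_k(
            base,
            k_grid=list(config.cv.get("k_grid", range(1, 26))),
            folds=int(config.cv.get("folds", 10)),
            seed=config.seed,
            schema=schema,
        )
    else:
        cv = retrieval.CVResult([(config.retrieval_k, float("nan"))], config.retrieval_k, 0, config.seed)
    cv.to_json(outdir / "cv.json")
    k = cv.best_k

    # plain KNN holdout at K (retrieval over the whole training base)
    knn_preds = {}
    knn_scores = {}
    for i in test_ids:
        ranked = retrieval.retrieve(by_id[i], train, k, schema)
        sp = retrieval.knn_fusion_score(by_id[i], ranked, labels, schema)
        knn_scores[i] = sp
        knn_preds[i] = int(sp > 0.5)
    knn_report = evaluation.metrics(evaluation.confusion(knn_preds, truth))
    knn_report.roc, knn_report.auc = evaluation.roc_curve(knn_scores, truth)
    knn_report.to_json(outdir / "phase1_knn.json")

    # combined: NB triage -> class-matched sub-base -> Sp at best K
    if config.partition_source == "true":
        part_labels = {i: labels[i] for i in train.ids}
    else:
        part_labels = {c.id: bayes.classify(model, c) for c in train}
    benign, malignant = partition_by_class(train, part_labels)
    comb_preds = {}
    comb_scores = {}
    for i in test_ids:
        triage = bayes.classify(model, by_id[i])
        subbase = malignant if triage == 1 else benign
        ranked = retrieval.retrieve(by_id[i], subbase, k, schema)
        sp = retrieval.knn_fusion_score(by_id[i], ranked, labels, schema)
        comb_scores[i] = sp
        comb_preds[i] = int(sp > 0.5)
    comb_report = evaluation.metrics(evaluation.confusion(comb_preds, truth))
    comb_report.roc, comb_report.auc = evaluation.roc_curve(comb_scores, truth)
    comb_report.to_json(outdir / "combined.json")

    _write_json(
        outdir / "manifest.json",
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_cases": len(base),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "best_k": k,
        },
    )
    return {"phase1_nb": nb_report, "phase1_knn": knn_report, "cv": cv, "combined": comb_report}
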