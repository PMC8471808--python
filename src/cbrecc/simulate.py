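"""Synthetic case bases and expert score panels.

The real case base behind this line of work (a hospital FNA archive of
roughly 1,214 breast-tumour cases, 950 benign and 264 malignant) is not
public, so a generator emulates its schema, value domains and class
imbalance.  Internal features are drawn per class from truncated normals
(continuous) or their rounded counterparts (ordinal/binary), with the
benign and malignant means separated by ``class_separation`` per-class
standard deviations — a single knob controlling how learnable the labels
are.  ECC features are drawn independently of the internal features: a
case's provenance quality says nothing about its pathology.

Expert score panels mix a shared per-item effect with per-rater noise in
proportion ``concordance : 1 − concordance``, so concordance 1 yields
identical rankings across raters (Kendall's W = 1) and concordance 0
yields pure noise (W near 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .casebase import Case, CaseBase
from .fusion import ExpertScoreMatrix
from .schema import FeatureSchema

#: fraction of the domain width used as the per-class feature SD
_REL_SD = 0.12
#: cap on the normalized benign/malignant mean gap, keeps both means in range
_MAX_GAP = 0.9

DEFAULT_MALIGNANT_FRACTION = 264 / 1214


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the case-base generator.

    ``class_separation`` is the benign/malignant mean gap in units of the
    per-class SD (a per-feature standardized effect size); 0 makes labels
    unlearnable, values ≥ 6 make the classes essentially separable.
    ``ecc_profile`` maps each ECC feature to distribution parameters:
    ``{"mean": .., "sd": ..}`` for scored features or ``{"p": ..}`` for
    binary ones.  ``exact_counts`` assigns labels by fixed counts
    (round(n·fraction) malignant) instead of Bernoulli draws.
    """

    n_cases: int
    malignant_fraction: float = DEFAULT_MALIGNANT_FRACTION
    class_separation: float = 3.0
    ecc_profile: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.malignant_fraction < 1:
            raise ValueError("malignant_fraction must lie in (0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")

    def to_json(self, path) -> None:
        doc = {
            "n_cases": self.n_cases,
            "malignant_fraction": self.malignant_fraction,
            "class_separation": self.class_separation,
            "ecc_profile": {k: dict(v) for k, v in sorted(self.ecc_profile.items())},
            "seed": self.seed,
            "exact_counts": self.exact_counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


_DEFAULT_ECC = {"mean": 7.0, "sd": 2.0, "p": 0.8}


def _class_means(separation: float) -> tuple[float, float]:
    gap = min(separation * _REL_SD, _MAX_GAP)
    return 0.5 - gap / 2.0, 0.5 + gap / 2.0


def generate_casebase(config: GeneratorConfig, schema: FeatureSchema) -> CaseBase:
    """Draw a schema-conforming case base; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    if config.exact_counts:
        n1 = round(n * config.malignant_fraction)
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[:n1]] = 1
    else:
        y = (rng.random(n) < config.malignant_fraction).astype(int)

    mu0, mu1 = _class_means(config.class_separation)
    columns: dict[str, np.ndarray] = {}
    for spec in schema.internal:
        if spec.kind in ("numeric", "ordinal"):
            lo, hi = spec.domain
            width = hi - lo
            mu = np.where(y == 1, mu1, mu0)
            z = np.clip(rng.normal(mu, _REL_SD), 0.0, 1.0)
            x = lo + width * z
            if spec.kind == "ordinal":
                x = np.clip(np.rint(x), lo, hi).astype(int)
            columns[spec.name] = x
        elif spec.kind == "binary":
            p = np.where(y == 1, mu1, mu0)
            draws = rng.random(n) < p
            levels = np.array(spec.domain, dtype=object)
            columns[spec.name] = levels[draws.astype(int)]
        else:  # categorical: class-1 mass tilted toward later levels
            levels = list(spec.domain)
            L = len(levels)
            gap = min(config.class_separation * _REL_SD, _MAX_GAP)
            tilt = 1.0 + gap * np.arange(L) / max(L - 1, 1)
            p1 = tilt / tilt.sum()
            p0 = p1[::-1]
            idx = np.where(
                y == 1,
                rng.choice(L, size=n, p=p1),
                rng.choice(L, size=n, p=p0),
            )
            columns[spec.name] = np.array(levels, dtype=object)[idx]

    for spec in schema.ecc:
        prof = {**_DEFAULT_ECC, **dict(config.ecc_profile.get(spec.name, {}))}
        if spec.kind == "binary":
            draws = rng.random(n) < prof["p"]
            levels = np.array(spec.domain, dtype=object)
            columns[spec.name] = levels[draws.astype(int)]
        else:
            lo, hi = spec.domain
            x = np.clip(rng.normal(prof["mean"], prof["sd"], size=n), lo, hi)
            if spec.kind == "ordinal":
                x = np.clip(np.rint(x), lo, hi).astype(int)
            columns[spec.name] = x

    pad = len(str(n))
    cases = []
    for i in range(n):
        values = {}
        for name, col in columns.items():
            v = col[i]
            if isinstance(v, np.generic):
                v = v.item()
            values[name] = v
        cases.append(Case(f"C{i + 1:0{pad}d}", values, int(y[i])))
    return CaseBase(schema, cases, provenance=f"synthetic (seed={config.seed})")


def generate_expert_scores(
    m: int, n: int, concordance: float, seed: int
) -> ExpertScoreMatrix:
    """Draw an m-rater × n-item integer score panel with tunable agreement.

    Scores are ``round(concordance·effect_j + (1 − concordance)·u_rj)``
    clipped to [1, 10], with distinct item effects evenly spread over
    [1, 10] and rater noise uniform on [1, 10].
    """
    if m < 2 or n < 2:
        raise ValueError("need m >= 2 raters and n >= 2 items")
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    effects = np.linspace(1.0, 10.0, n)
    noise = rng.uniform(1.0, 10.0, size=(m, n))
    raw = concordance * effects[None, :] + (1.0 - concordance) * noise
    scores = np.clip(np.rint(raw), 1, 10).astype(int)
    return ExpertScoreMatrix(
        [f"rater{r + 1:02d}" for r in range(m)],
        [f"item{j + 1:02d}" for j in range(n)],
        scores,
    )
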