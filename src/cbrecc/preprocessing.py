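"""Case-table preprocessing: min-max normalization, binarization and
correlation-based feature subset selection.

Normalization is affine min-max: ``x -> scale*(x - min)/(max - min) + shift``.
With the defaults (scale 1, shift 0) training values land in [0, 1]; with
scale 2 and shift -1 they land in [-1, 1].  Parameters are fitted on a
training base and can be serialized for reuse at query time, where values
outside the training range are clipped to the range end.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .casebase import Case, CaseBase, CaseBaseError
from .schema import FeatureSchema, FeatureSpec, SchemaError

log = logging.getLogger(__name__)


@dataclass
class NormalizationParams:
    """Fitted per-feature min/max plus the affine scale/shift."""

    ranges: dict[str, tuple[float, float]]
    scale: float = 1.0
    shift: float = 0.0
    constant: set[str] = field(default_factory=set)

    def to_json(self, path) -> None:
        doc = {
            "ranges": {k: list(v) for k, v in sorted(self.ranges.items())},
            "scale": self.scale,
            "shift": self.shift,
            "constant": sorted(self.constant),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            ranges={k: (v[0], v[1]) for k, v in doc["ranges"].items()},
            scale=doc["scale"],
            shift=doc["shift"],
            constant=set(doc["constant"]),
        )


def fit_normalizer(
    base: CaseBase,
    features: Sequence[str],
    scale: float = 1.0,
    shift: float = 0.0,
) -> NormalizationParams:
    """Record the observed min/max of the named numeric/ordinal features.

    Constant features (min == max) are flagged; :func:`apply_normalizer`
    maps them to the mid-range value ``shift + scale/2``.
    """
    ranges: dict[str, tuple[float, float]] = {}
    constant: set[str] = set()
    for name in features:
        spec = base.schema[name]
        if spec.kind not in ("numeric", "ordinal"):
            raise SchemaError(f"feature {name!r} is {spec.kind}, not numeric/ordinal")
        xs = [float(c.values[name]) for c in base]
        if not xs:
            raise CaseBaseError("cannot fit a normalizer on an empty case base")
        lo, hi = min(xs), max(xs)
        ranges[name] = (lo, hi)
        if lo == hi:
            constant.add(name)
    return NormalizationParams(ranges, scale, shift, constant)


def apply_normalizer(base: CaseBase, params: NormalizationParams) -> CaseBase:
    """Apply a fitted min-max transform, returning a new case base.

    The affected features become ``numeric`` with domain
    ``[shift, shift + scale]`` (or reversed when scale < 0).  Out-of-range
    values are clipped to the training range end and logged.
    """
    lo_out = min(params.shift, params.shift + params.scale)
    hi_out = max(params.shift, params.shift + params.scale)
    if lo_out == hi_out:  # scale 0 would collapse the domain
        raise SchemaError("normalizer scale must be nonzero")

    replacements = {}
    for name in params.ranges:
        old = base.schema[name]
        replacements[name] = FeatureSpec(
            name, "numeric", old.channel, (lo_out, hi_out), old.weight, old.units
        )
    schema = base.schema.replace(**replacements)

    clipped = 0
    cases = []
    for c in base:
        values = dict(c.values)
        for name, (lo, hi) in params.ranges.items():
            x = float(values[name])
            if x < lo or x > hi:
                clipped += 1
                x = min(max(x, lo), hi)
            if lo == hi:
                values[name] = params.shift + params.scale / 2.0
            else:
                values[name] = params.scale * (x - lo) / (hi - lo) + params.shift
        cases.append(Case(c.id, values, c.label))
    if clipped:
        log.warning("clipped %d value(s) outside the training range", clipped)
    return CaseBase(schema, cases, provenance=base.provenance + " [normalized]")


def binarize(base: CaseBase, feature: str, rule) -> CaseBase:
    """Replace a feature by one or more {0,1}-valued features.

    ``rule`` is one of:

    * ``("threshold", t)`` — numeric/ordinal; value ``>= t`` maps to 1;
    * ``("levels", {level: 0 or 1})`` — explicit level map, total over the
      declared domain;
    * ``("onehot", None)`` — categorical expansion into one binary column
      per level, named ``{feature}={level}``, exactly one of which is 1.
    """
    spec = base.schema[feature]
    kind_rule, arg = rule

    if kind_rule == "threshold":
        if spec.kind not in ("numeric", "ordinal"):
            raise SchemaError(f"threshold rule needs a numeric/ordinal feature, got {spec.kind}")
        new_spec = FeatureSpec(feature, "binary", spec.channel, (0, 1), spec.weight)
        schema = base.schema.replace(**{feature: new_spec})
        cases = [
            Case(c.id, {**c.values, feature: int(float(c.values[feature]) >= arg)}, c.label)
            for c in base
        ]
        return CaseBase(schema, cases, base.provenance)

    if kind_rule == "levels":
        levels = spec.domain if spec.kind in ("binary", "categorical") else None
        if levels is None:
            raise SchemaError("level rule needs a binary/categorical feature")
        missing = [lv for lv in levels if lv not in arg]
        if missing:
            raise SchemaError(f"level rule not total: missing {missing}")
        if not set(arg.values()) <= {0, 1}:
            raise SchemaError("level rule must map to {0, 1}")
        new_spec = FeatureSpec(feature, "binary", spec.channel, (0, 1), spec.weight)
        schema = base.schema.replace(**{feature: new_spec})
        cases = [
            Case(c.id, {**c.values, feature: arg[c.values[feature]]}, c.label) for c in base
        ]
        return CaseBase(schema, cases, base.provenance)

    if kind_rule == "onehot":
        if spec.kind not in ("binary", "categorical"):
            raise SchemaError("one-hot expansion needs a binary/categorical feature")
        new_specs = tuple(
            FeatureSpec(f"{feature}={lv}", "binary", spec.channel, (0, 1), spec.weight)
            for lv in spec.domain
        )
        features = []
        for f in base.schema.features:
            if f.name == feature:
                features.extend(new_specs)
            else:
                features.append(f)
        schema = FeatureSchema(tuple(features))
        cases = []
        for c in base:
            values = {k: v for k, v in c.values.items() if k != feature}
            for lv in spec.domain:
                values[f"{feature}={lv}"] = int(c.values[feature] == lv)
            cases.append(Case(c.id, values, c.label))
        return CaseBase(schema, cases, base.provenance)

    raise SchemaError(f"unknown binarization rule {kind_rule!r}")


def select_low_correlation_subset(
    base: CaseBase, candidates: Sequence[str], rho_max: float = 0.9
) -> list[str]:
    """Greedy low-correlation feature filter.

    Candidates are visited in the schema's declared order; one is kept iff
    its absolute Pearson correlation with every already-kept feature is
    strictly below ``rho_max``.  A zero-variance feature's correlation
    cannot be computed and is treated as 0 with a warning.  The result
    depends only on the declared feature order, never on case order.
    """
    if not 0 <= rho_max <= 1:
        raise ValueError("rho_max must lie in [0, 1]")
    if len(base) < 2:
        raise CaseBaseError("need at least 2 cases to estimate correlations")
    ordered = [f.name for f in base.schema.features if f.name in set(candidates)]
    cols = {name: np.array([float(c.values[name]) for c in base]) for name in ordered}

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            warnings.warn("zero-variance feature: correlation treated as 0", stacklevel=2)
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    kept: list[str] = []
    for name in ordered:
        if all(abs(corr(cols[name], cols[k])) < rho_max for k in kept):
            kept.append(name)
    return kept
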