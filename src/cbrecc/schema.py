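"""Typed feature schemas for diagnostic case bases.

A :class:`FeatureSchema` declares, for every column of a case table, its
name, kind (``numeric``/``ordinal``/``binary``/``categorical``), value
domain, channel and retrieval weight.  Channels separate the clinical
content of a case (``internal``, used for similarity matching) from its
provenance and appraisal (``ecc`` — external case characteristics such as
the specialty of the recording doctor, their willingness to reveal their
real name, and a peer case-quality score), the diagnosis (``label``,
binary with 1 = malignant) and the row identifier (``id``).

Two ready-made schemas are bundled: :func:`breast_fna_schema`, covering a
fine-needle-aspirate breast-tumour case base (age, tumour consistency,
clump thickness, FNA material type, swab count plus the three ECC
attributes), and :func:`retrieval_demo_schema`, a variant that adds the
gender, clump-mobility ("set") and cell-description attributes seen in
some exported case tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

KINDS = ("numeric", "ordinal", "binary", "categorical")
CHANNELS = ("internal", "ecc", "label", "id")


class SchemaError(ValueError):
    """A schema declaration or a value's conformance to it is invalid."""


@dataclass(frozen=True)
class FeatureSpec:
    """One column of a case table.

    Parameters
    ----------
    name
        Column name; must be unique within a schema.
    kind
        ``numeric`` (continuous), ``ordinal`` (integer-graded scale),
        ``binary`` (two levels, canonically 0/1) or ``categorical``.
    channel
        ``internal`` features drive similarity; ``ecc`` features drive
        re-ranking; exactly one ``label`` and at most one ``id`` column.
    domain
        ``(low, high)`` closed range for numeric/ordinal kinds, a tuple of
        admissible levels for binary/categorical kinds, or ``None`` for the
        free-form ``id`` column.
    weight
        Non-negative retrieval weight; consulted only for ``internal``
        features.
    units
        Optional free-text unit annotation (e.g. ``"years"``, ``"cm"``).
    """

    name: str
    kind: str
    channel: str = "internal"
    domain: tuple | None = None
    weight: float = 1.0
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for feature {self.name!r}")
        if self.channel not in CHANNELS:
            raise SchemaError(f"unknown channel {self.channel!r} for feature {self.name!r}")
        if self.channel == "id":
            return
        if self.domain is None:
            raise SchemaError(f"feature {self.name!r} needs a domain")
        if self.kind in ("numeric", "ordinal"):
            lo, hi = self.domain
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
                raise SchemaError(
                    f"feature {self.name!r}: numeric/ordinal domain needs lower < upper, got {self.domain}"
                )
        else:
            if len(self.domain) < 2:
                raise SchemaError(f"feature {self.name!r}: needs at least two levels")
            if self.kind == "binary" and len(self.domain) != 2:
                raise SchemaError(f"feature {self.name!r}: binary features have exactly two levels")
        if not (math.isfinite(self.weight) and self.weight >= 0):
            raise SchemaError(f"feature {self.name!r}: weight must be finite and >= 0")

    # -- value handling ----------------------------------------------------

    @property
    def width(self) -> float:
        """Width of a numeric/ordinal domain."""
        if self.kind not in ("numeric", "ordinal"):
            raise SchemaError(f"feature {self.name!r} has no numeric width")
        lo, hi = self.domain  # type: ignore[misc]
        return float(hi) - float(lo)

    def contains(self, value: Any) -> bool:
        if self.channel == "id":
            return True
        if self.kind in ("numeric", "ordinal"):
            lo, hi = self.domain  # type: ignore[misc]
            try:
                return lo <= float(value) <= hi
            except (TypeError, ValueError):
                return False
        return value in self.domain  # type: ignore[operator]

    def parse(self, text: Any):
        """Parse a raw (usually string) cell into this feature's value type."""
        if self.channel == "id":
            return str(text)
        if self.kind == "numeric":
            return float(text)
        if self.kind == "ordinal":
            x = float(text)
            return int(x) if float(x).is_integer() else x
        # binary / categorical: match against declared levels
        for level in self.domain:  # type: ignore[union-attr]
            if text == level or str(text) == str(level):
                return level
            try:
                if float(text) == float(level):
                    return level
            except (TypeError, ValueError):
                pass
        raise SchemaError(f"value {text!r} is not a level of feature {self.name!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` shared by a case base."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        labels = [f for f in self.features if f.channel == "label"]
        if len(labels) != 1:
            raise SchemaError("schema needs exactly one label feature")
        lab = labels[0]
        if lab.kind != "binary" or set(lab.domain) != {0, 1}:  # type: ignore[arg-type]
            raise SchemaError("label feature must be binary with levels {0, 1}")
        if len([f for f in self.features if f.channel == "id"]) > 1:
            raise SchemaError("at most one id feature")
        internal = self.internal
        if internal and not any(f.weight > 0 for f in internal):
            raise SchemaError("internal weights must not all be zero")

    # -- lookups -----------------------------------------------------------

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def internal(self) -> list[FeatureSpec]:
        return [f for f in self.features if f.channel == "internal"]

    @property
    def ecc(self) -> list[FeatureSpec]:
        return [f for f in self.features if f.channel == "ecc"]

    @property
    def label(self) -> FeatureSpec:
        return next(f for f in self.features if f.channel == "label")

    @property
    def id_spec(self) -> FeatureSpec | None:
        return next((f for f in self.features if f.channel == "id"), None)

    @property
    def value_names(self) -> list[str]:
        """Names of the features carried in ``Case.values`` (not label/id)."""
        return [f.name for f in self.features if f.channel in ("internal", "ecc")]

    def replace(self, **by_name: FeatureSpec) -> "FeatureSchema":
        """Return a schema with the named specs replaced."""
        return FeatureSchema(tuple(by_name.get(f.name, f) for f in self.features))

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for f in self.features:
            rec: dict[str, Any] = {"name": f.name, "kind": f.kind, "channel": f.channel}
            if f.domain is not None:
                rec["domain"] = list(f.domain)
            rec["weight"] = f.weight
            if f.units:
                rec["units"] = f.units
            out.append(rec)
        return {"features": out}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        specs = []
        for rec in d["features"]:
            domain = rec.get("domain")
            if domain is not None:
                domain = tuple(domain)
            specs.append(
                FeatureSpec(
                    name=rec["name"],
                    kind=rec["kind"],
                    channel=rec.get("channel", "internal"),
                    domain=domain,
                    weight=float(rec.get("weight", 1.0)),
                    units=rec.get("units"),
                )
            )
        return cls(tuple(specs))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def breast_fna_schema() -> FeatureSchema:
    """Default schema of a breast fine-needle-aspirate case base.

    Internal features cover patient age (10–95 years), tumour consistency
    graded soft→hard (1–5), clump thickness (0–22 cm), FNA material type
    (1–5) and number of swabs (1–10).  ECC features are the doctor's
    specialty score (1–10), willingness to reveal their real name ({0,1})
    and the peer case-quality score (1–10).  The label is 1 = malignant,
    0 = benign.
    """
    return FeatureSchema(
        (
            FeatureSpec("index", "categorical", "id"),
            FeatureSpec("age", "numeric", "internal", (10, 95), 1.0, "years"),
            FeatureSpec("consistency", "ordinal", "internal", (1, 5), 1.0),
            FeatureSpec("clump_thickness", "numeric", "internal", (0, 22), 1.0, "cm"),
            FeatureSpec("fna", "ordinal", "internal", (1, 5), 1.0),
            FeatureSpec("swabs", "ordinal", "internal", (1, 10), 1.0),
            FeatureSpec("class", "binary", "label", (0, 1)),
            FeatureSpec("doctor_specialty", "ordinal", "ecc", (1, 10)),
            FeatureSpec("reveal_real_name", "binary", "ecc", (0, 1)),
            FeatureSpec("case_quality", "ordinal", "ecc", (1, 10)),
        )
    )


def retrieval_demo_schema() -> FeatureSchema:
    """Schema variant with gender, clump mobility ("set") and cell grade.

    Some exported case tables carry these three extra internal attributes;
    the variant is bundled so that both table layouts are expressible.
    """
    return FeatureSchema(
        (
            FeatureSpec("index", "categorical", "id"),
            FeatureSpec("gender", "binary", "internal", (0, 1)),
            FeatureSpec("age", "numeric", "internal", (10, 95), 1.0, "years"),
            FeatureSpec("consistency", "ordinal", "internal", (1, 5), 1.0),
            FeatureSpec("clump_thickness", "numeric", "internal", (0, 22), 1.0, "cm"),
            FeatureSpec("fna", "ordinal", "internal", (1, 5), 1.0),
            FeatureSpec("set", "binary", "internal", (0, 1)),
            FeatureSpec("swabs", "ordinal", "internal", (1, 10), 1.0),
            FeatureSpec("cells", "ordinal", "internal", (1, 10), 1.0),
            FeatureSpec("class", "binary", "label", (0, 1)),
        )
    )
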