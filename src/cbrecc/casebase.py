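"""Cases, case bases and their delimited-file round trip.

The on-disk format is a UTF-8, comma-separated file with a header; the
first column is the case id, the remaining columns follow the schema's
declared order.  Floats are rendered with ``repr`` (shortest string that
round-trips), so ``load(write(base))`` reproduces the base exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .schema import FeatureSchema, SchemaError

log = logging.getLogger(__name__)


class CaseBaseError(ValueError):
    """A case or case-base level validation failure."""


@dataclass(frozen=True)
class Case:
    """A single patient case: an id, a feature-value map and an optional label.

    ``values`` carries every internal and ECC feature; the label (1 =
    malignant, 0 = benign) is kept separately so unlabelled queries use the
    same type.
    """

    id: str
    values: Mapping[str, object]
    label: int | None = None

    def validate(self, schema: FeatureSchema, strict: bool = True) -> None:
        for spec in schema.features:
            if spec.channel in ("label", "id"):
                continue
            if spec.name not in self.values:
                raise CaseBaseError(f"case {self.id!r}: missing feature {spec.name!r}")
            v = self.values[spec.name]
            if strict and not spec.contains(v):
                raise CaseBaseError(
                    f"case {self.id!r}: value {v!r} outside domain of feature {spec.name!r}"
                )
        if self.label is not None and self.label not in (0, 1):
            raise CaseBaseError(f"case {self.id!r}: label must be 0 or 1, got {self.label!r}")


@dataclass
class CaseBase:
    """An ordered, schema-validated collection of cases."""

    schema: FeatureSchema
    cases: list[Case] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cases]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise CaseBaseError(f"duplicate case id {dup!r}")
        for c in self.cases:
            c.validate(self.schema)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def __getitem__(self, case_id: str) -> Case:
        for c in self.cases:
            if c.id == case_id:
                return c
        raise KeyError(case_id)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.cases]

    def labels(self) -> dict[str, int]:
        """Map id -> label for the labelled cases."""
        return {c.id: c.label for c in self.cases if c.label is not None}

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame in on-disk column order (id first)."""
        id_name = self.schema.id_spec.name if self.schema.id_spec else "id"
        rows = []
        for c in self.cases:
            row: dict[str, object] = {id_name: c.id}
            for spec in self.schema.features:
                if spec.channel == "id":
                    continue
                if spec.channel == "label":
                    row[spec.name] = c.label
                else:
                    row[spec.name] = c.values[spec.name]
            rows.append(row)
        cols = [id_name] + [f.name for f in self.schema.features if f.channel != "id"]
        return pd.DataFrame(rows, columns=cols)


def _render(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_casebase(base: CaseBase, path) -> None:
    """Write a case base as CSV: header in schema order, one row per case."""
    id_name = base.schema.id_spec.name if base.schema.id_spec else "id"
    cols = [id_name] + [f.name for f in base.schema.features if f.channel != "id"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        for c in base.cases:
            cells = [c.id]
            for spec in base.schema.features:
                if spec.channel == "id":
                    continue
                cells.append(_render(c.label if spec.channel == "label" else c.values[spec.name]))
            fh.write(",".join(cells) + "\n")


def load_casebase(path, schema: FeatureSchema, strict: bool = True) -> CaseBase:
    """Load and validate a delimited case base.

    Header names must match the schema's names (order-insensitive).  In
    strict mode an out-of-domain value raises a :class:`CaseBaseError`
    naming the row and feature; otherwise offending rows are dropped with a
    logged count.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_name = schema.id_spec.name if schema.id_spec else "id"
    expected = {id_name} | {f.name for f in schema.features if f.channel != "id"}
    got = set(df.columns)
    missing = expected - got
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")
    extra = got - expected
    if extra:
        raise SchemaError(f"unexpected column(s): {sorted(extra)}")

    label_name = schema.label.name
    cases: list[Case] = []
    dropped = 0
    for i, row in df.iterrows():
        cid = str(row[id_name])
        try:
            values: dict[str, object] = {}
            for spec in schema.features:
                if spec.channel in ("id", "label"):
                    continue
                v = spec.parse(row[spec.name])
                if not spec.contains(v):
                    raise CaseBaseError(
                        f"row {i} (id {cid!r}): value {row[spec.name]!r} outside "
                        f"domain of feature {spec.name!r}"
                    )
                values[spec.name] = v
            raw_label = row[label_name]
            label = None if raw_label == "" else int(schema.label.parse(raw_label))
            cases.append(Case(cid, values, label))
        except (SchemaError, CaseBaseError, ValueError) as exc:
            if strict:
                raise CaseBaseError(str(exc)) from exc
            dropped += 1
    if dropped:
        log.warning("dropped %d invalid row(s) while loading %s", dropped, path)
    return CaseBase(schema, cases, provenance=f"loaded from {path}")


def partition_by_class(
    base: CaseBase, labels: Mapping[str, int]
) -> tuple[CaseBase, CaseBase]:
    """Split a case base into (benign, malignant) sub-bases.

    The label source is the supplied map — the stored diagnoses or a
    classifier's predictions, at the caller's choice — so triage-driven and
    ground-truth partitions use the same code path.
    """
    missing = [c.id for c in base if c.id not in labels]
    if missing:
        raise CaseBaseError(f"id(s) missing from label map: {missing[:5]}")
    benign = [c for c in base if labels[c.id] == 0]
    malignant = [c for c in base if labels[c.id] == 1]
    return (
        CaseBase(base.schema, benign, provenance=base.provenance + " [benign]"),
        CaseBase(base.schema, malignant, provenance=base.provenance + " [malignant]"),
    )
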