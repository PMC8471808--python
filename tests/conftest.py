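import numpy as np
import pytest

from cbrecc import (
    Case,
    CaseBase,
    FeatureSchema,
    FeatureSpec,
    GeneratorConfig,
    breast_fna_schema,
    generate_casebase,
)


@pytest.fixture
def fna_schema():
    return breast_fna_schema()


@pytest.fixture
def toy_schema():
    """Minimal 3-internal-feature schema used by hand-arithmetic tests."""
    return FeatureSchema(
        (
            FeatureSpec("id", "categorical", "id"),
            FeatureSpec("a", "numeric", "internal", (0, 10), 2.0),
            FeatureSpec("b", "numeric", "internal", (0, 10), 1.0),
            FeatureSpec("c", "binary", "internal", (0, 1), 1.0),
            FeatureSpec("class", "binary", "label", (0, 1)),
        )
    )


@pytest.fixture
def small_base(fna_schema):
    """Deterministic 60-case moderately separable synthetic base."""
    cfg = GeneratorConfig(n_cases=60, malignant_fraction=0.3, class_separation=3.0,
                          seed=11, exact_counts=True)
    return generate_casebase(cfg, fna_schema)


@pytest.fixture
def separable_base(fna_schema):
    """Strongly separated classes: every reasonable classifier is perfect."""
    cfg = GeneratorConfig(n_cases=120, malignant_fraction=0.3, class_separation=8.0,
                          seed=5, exact_counts=True)
    return generate_casebase(cfg, fna_schema)


def random_toy_base(rng: np.random.Generator, n_cases: int, n_features: int) -> CaseBase:
    """Small random mixed-kind case base for oracle-equivalence tests."""
    specs = [FeatureSpec("id", "categorical", "id")]
    kinds = ["numeric", "ordinal", "binary", "categorical"]
    for j in range(n_features):
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "numeric":
            specs.append(FeatureSpec(f"f{j}", "numeric", "internal", (0.0, 10.0),
                                     float(rng.uniform(0.5, 3.0))))
        elif kind == "ordinal":
            specs.append(FeatureSpec(f"f{j}", "ordinal", "internal", (1, 5),
                                     float(rng.uniform(0.5, 3.0))))
        elif kind == "binary":
            specs.append(FeatureSpec(f"f{j}", "binary", "internal", (0, 1),
                                     float(rng.uniform(0.5, 3.0))))
        else:
            specs.append(FeatureSpec(f"f{j}", "categorical", "internal",
                                     ("x", "y", "z"), float(rng.uniform(0.5, 3.0))))
    specs.append(FeatureSpec("class", "binary", "label", (0, 1)))
    schema = FeatureSchema(tuple(specs))

    def draw(spec):
        if spec.kind == "numeric":
            # coarse grid so that similarity ties actually occur
            return float(rng.integers(0, 11))
        if spec.kind == "ordinal":
            return int(rng.integers(1, 6))
        return spec.domain[int(rng.integers(len(spec.domain)))]

    labels = rng.integers(0, 2, size=n_cases)
    if n_cases >= 2:  # ensure both classes occur
        labels[0], labels[1] = 0, 1
    cases = [
        Case(f"c{i:03d}", {s.name: draw(s) for s in schema.internal}, int(labels[i]))
        for i in range(n_cases)
    ]
    return CaseBase(schema, cases)
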