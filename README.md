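# cbrecc — case-based diagnostic retrieval with ECC re-ranking

`cbrecc` implements a three-phase case-based reasoning (CBR) pipeline for
clinical decision support, built around breast fine-needle-aspirate (FNA)
case bases:

1. **Phase I — triage.** A naive Bayes classifier
   `P(y|x) ∝ P(y)·Π_i P(x_i|y)` assigns a new case to the benign (0) or
   malignant (1) sub-base, using Gaussian class-conditionals for
   continuous features and Laplace-smoothed tables for categorical ones.
2. **Phase II — retrieval.** Within the class-matched sub-base, the K
   nearest historical cases are found by weighted local-similarity
   matching, `S(I,R) = Σ_i w_i·sim(f_i^I, f_i^R) / Σ_i w_i`, with
   `sim = 1 − |a−b|/width` for graded features and an equality indicator
   for categorical ones. K is selected by stratified cross-validation of
   the inverse-distance-weighted neighbourhood label score
   `Sp = Σ w·d⁻¹·y / Σ w·d⁻¹` (`d = 1 − S`).
3. **Phase III — ECC fusion.** External case characteristics (ECC) — the
   recording doctor's specialty score, willingness to reveal their real
   name, and a peer case-quality score — are combined into a provenance
   score `P_t = Σ w_i·x̃_i` (domain-normalized values, weights elicited
   from an expert panel and checked with Kendall's W), then fused with
   content similarity by the binary harmonic mean
   `SP_t = 2·S_t·P_t/(S_t + P_t)` and the retrieval is re-ranked.
   The harmonic mean leans toward the smaller operand, so a case must be
   both similar *and* well sourced to rank highly.

The intended users are medical-informatics researchers studying how
provenance-aware re-ranking changes which historical cases a decision
support system surfaces. Real hospital case bases with ECC annotations
are not publicly available, so the package ships a synthetic generator
that emulates a realistic archive (schema, value domains, 950:264 class
imbalance) with a controllable class-separation knob.

## Worked example

```python
from cbrecc import *

schema = breast_fna_schema()
base = generate_casebase(GeneratorConfig(n_cases=300, malignant_fraction=264/1214,
                                         seed=42, exact_counts=True), schema)

model = fit_nb(base)
query = Case("new-patient", {
    "age": 29, "consistency": 5, "clump_thickness": 6.0, "fna": 1, "swabs": 5,
    "doctor_specialty": 7, "reveal_real_name": 1, "case_quality": 7,
})
triage = classify(model, query)                      # -> 0 (benign)

benign, malignant = partition_by_class(base, base.labels())
ranked = retrieve(query, benign if triage == 0 else malignant, 5, schema)

panel = generate_expert_scores(m=10, n=3, concordance=0.85, seed=42)
weights = elicit_weights(panel, items_as_features=[f.name for f in schema.ecc])
fused = rerank_with_ecc(ranked, base, weights, schema)
```

The run prints (via the entries of `ranked` and `fused`):

```
posterior: {0: 1.0, 1: 0.0}  triage: 0
rank 1: C174  S_t=0.8437
rank 2: C021  S_t=0.8331
...
weights: {'doctor_specialty': 0.101, 'reveal_real_name': 0.327,
          'case_quality': 0.571}  W=1.000 p=4.5e-05
rank 1 (was 5): C123  S_t=0.8230  P_t=0.9663  SP_t=0.8889
rank 2 (was 3): C006  S_t=0.8330  P_t=0.8168  SP_t=0.8248
rank 3 (was 1): C174  S_t=0.8437  P_t=0.7646  SP_t=0.8022
```

Reading: the query is triaged benign with near-certain posterior, so only
benign cases are retrieved. Case C174 is the closest match by content
(S_t = 0.844), but C123 — slightly less similar at S_t = 0.823 — carries
much stronger provenance (P_t = 0.966 vs 0.765), so after harmonic fusion
it is promoted to rank 1. The elicited panel weights put about 57% of the
provenance score on the peer case-quality rating, and the panel's
Kendall's W of 1.0 (p ≈ 5e-5) says the ten raters ranked the three ECC
attributes identically.

The same steps are available from a shell:

```sh
cbrecc simulate --n 300 --seed 42 --exact-counts --out base.csv --schema-out schema.json
cbrecc select-k --casebase base.csv --seed 0 --out cv.json
cbrecc retrieve --casebase base.csv --query query.csv --k 5 --out retrieval.json
cbrecc weights  --scores panel.csv --out weights.json
cbrecc fuse --retrieval retrieval.json --casebase base.csv \
            --weights weights.json --out fused.json
cbrecc evaluate --casebase base.csv --seed 0 --outdir eval/
```

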