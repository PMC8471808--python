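# Methods

## The model

`cbrecc` treats diagnostic decision support as retrieval, not just
classification: given a new patient case, the deliverable is a short,
ranked list of comparable historical cases, ordered so that the cases a
clinician would actually trust come first. Three stages contribute:

**Triage.** A naive Bayes classifier over the internal (clinical)
features routes the query to the benign or malignant sub-base. Priors
are class frequencies; continuous and graded features get Gaussian
class-conditionals (maximum-likelihood mean and variance), categorical
ones get Laplace-smoothed frequency tables over the *declared* level
set, so a level unseen in training still receives its smoothed
zero-count probability. The posterior is evaluated in log space and
normalized with log-sum-exp; exact posterior ties classify as benign.
Restricting retrieval to the triaged sub-base assumes the triage is
right; since the stored cases carry confirmed diagnoses, the stored-base
partition uses true labels by default, and the naive-Bayes-predicted
partition is available behind a flag for ablation.

**Retrieval.** Similarity is a weighted mean of per-feature local
similarities over the internal channel only — ECC features and the label
never enter content similarity. Local similarity for numeric/ordinal
features normalizes by the declared domain width, so feature scales are
comparable without preprocessing; binary/categorical features contribute
an equality indicator. Per-feature retrieval weights default to 1
(uniform): no weighting scheme is self-evidently better a priori, and
the schema makes them overridable (they can also be elicited from an
expert panel with the Phase-III machinery). Retrieval is an exhaustive
scan; at case-base scales of ~10³ an approximate index would only add
failure modes.

**Neighbourhood score and K selection.** The fusion score
`Sp = Σ w·d⁻¹·y / Σ w·d⁻¹` with `d = 1 − S` is a convex combination of
neighbour labels. A zero-distance neighbour would divide by zero; rather
than an epsilon, an exact match short-circuits `Sp` to the mean label of
all exact matches (a single exact match simply contributes its label).
K is chosen by stratified K-fold cross-validation (default 10 folds,
grid 1–25): each held-out case is classified against the training folds
by `Sp > 0.5 → malignant` (a tie at exactly 0.5 goes to benign, matching
the triage tie-break), the grid accuracy is the pooled accuracy over all
held-out cases, and among maximizers the smallest K wins — small
neighbourhoods are the regime of interest for case *presentation*, where
a clinician reads only a handful of cases.

**ECC fusion.** The external case characteristics are scored as
`P_t = Σ w_i·x̃_i` with each value normalized to [0, 1] by its declared
domain (a 1–10 score maps to `(x−1)/9`, binary flags enter as-is). The
normalization matters: fusing requires `P_t` to live on the same [0, 1]
scale as the similarity `S_t`, and anchoring at the declared domain ends
makes the map exact rather than approximate (`x/10` would never reach 0).
The binary harmonic mean `SP_t = 2·S_t·P_t/(S_t+P_t)` satisfies
`min ≤ SP_t ≤ √(S_t·P_t) ≤ (S_t+P_t)/2` with equality iff the operands
are equal, and annihilates when either operand is 0 — a deliberate
penalty structure: high similarity cannot compensate for worthless
provenance, nor vice versa. Fused ties are broken by higher similarity
(content dominates), then ascending case id.

**Weight elicitation and concordance.** ECC weights come from an expert
panel: each item's weight is its mean score divided by the sum of all
item means, so weights are invariant to rescaling all scores by a
constant. An optional trimmed variant removes one maximum and one
minimum score per item before averaging (requiring ≥ 4 raters); panel
agreement is always assessed on the untrimmed matrix with Kendall's W
using mid-ranks and the standard tie correction
`W = 12S / (m²(n³−n) − mΣT)`, with the chi-square approximation
`χ² = m(n−1)W` on `n−1` degrees of freedom for the p-value. A panel in
which every rater ties every item has an undefined W and is reported as
such rather than silently returning a number.

## Evaluation conventions

The positive class is malignant (1) throughout: FN means a malignant
case predicted benign. Precision, recall and F are reported as 0 with an
explicit `undefined` flag when their denominator is 0. The ROC sweeps a
descending threshold over distinct scores with tied scores grouped; the
trapezoid AUC then equals the Mann–Whitney concordant-pair statistic
exactly, which the test suite checks pair by pair. Holdout splits are
stratified: each stratum contributes `floor(n_s·fraction)` test cases,
and any shortfall relative to `floor(n·fraction)` is drawn from the
larger stratum (1,214 cases at one third → 404 test cases, 88
malignant). All splits, folds and generators take explicit seeds.

## The synthetic generator

Real FNA archives with ECC annotations are not publicly available, so
all quantitative results in this repository are computed on synthetic
case bases. The generator emulates the target archive's shape — the
bundled schema (age 10–95 y, tumour consistency 1–5, clump thickness
0–22 cm, FNA type 1–5, swabs 1–10, plus the three ECC attributes) and a
950:264 benign:malignant imbalance, with an exact-count mode for fixtures
needing that split precisely.

Internal features are drawn per class from normals in domain-normalized
coordinates: SD 0.12 of the domain width, class means separated by
`class_separation` SDs (capped at 0.9 of the width), clipped into the
domain and rounded for ordinal features. `class_separation` is therefore
a per-feature standardized effect size; the default of 3.0 represents
strong single-feature signal of the kind FNA morphology features carry.
Note that with five conditionally independent informative features a
per-feature gap of 3 SD makes the *joint* classification problem
essentially separable — so perfect holdout accuracy on synthetic data
validates the pipeline's mechanics, not any claim about real-data
accuracy. What the generator deliberately does not model: correlated
features, label noise, missingness, and any dependence of ECC values on
the clinical content (ECC features are drawn independently of the label
— provenance says nothing about pathology; scored ECC attributes are
discretized N(7, 2), the real-name flag is Bernoulli(0.8)).

Expert panels mix a shared item effect (distinct values spread over
1–10) with per-rater uniform noise in proportion
`concordance : 1 − concordance`, rounded and clipped to 1–10. At
concordance 1 all raters produce identical rankings (W = 1 exactly,
including the tie-corrected case); at 0 the panel is pure noise and W
concentrates near 0 as the panel grows.

## Numerical and design choices

- Naive Bayes variances are floored at `1e-9·width²` so constant
  features yield finite, sharply peaked densities instead of errors.
- Similarity ties in retrieval break by ascending case id —
  deterministic and schema-independent.
- Normalization (`x → scale·(x−min)/(max−min) + shift`) clips
  query-time values outside the training range to the range end rather
  than erroring: a new patient may legitimately be older than anyone in
  the archive. Constant features map to the mid-range `shift + scale/2`.
- The low-correlation feature filter is a greedy forward pass in
  declared schema order keeping a candidate iff |Pearson ρ| with every
  kept feature is below the threshold (default 0.9); results depend on
  feature order only, never on row order. Zero-variance features have no
  defined correlation and pass with a warning.
- Run manifests fingerprint a configuration by hashing the *contents*
  of its input files plus all settings (output location excluded), so
  relocating a workspace does not change the hash but touching the data
  does.

## Problem sizes

The bundled study runs at the emulated archive's scale: 1,214 cases
(950/264) for holdout and cross-validation, a 10-rater × 3-item
elicitation panel, and 50 query replays for the re-ranking summary.
Oracle-equivalence checks in the test suite run on hundreds of randomly
drawn small instances (bases ≤ 200 cases, panels ≤ 12×12), which is
ample to exercise every tie and degenerate branch.

## Known limitations

- The generator's truncation-by-clipping places small point masses at
  domain boundaries; at the default SD this is negligible but visible at
  extreme separations.
- With a ground-truth sub-base partition, the combined
  triage-then-retrieve classifier's decision coincides with the triage
  decision (every neighbour shares the triaged class); the NB-predicted
  partition lets neighbours overrule the triage and is the setting where
  the combined stage can differ.
- The chi-square p-value for Kendall's W is a large-sample
  approximation; for very small panels (n ≤ 3 items) exact tables would
  be preferable.
- Categorical ECC features have no canonical [0, 1] scale and are
  rejected in the ECC score rather than guessed at.
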