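# Methods

This note documents the models, conventions and numerical choices behind
`ctrss`, and what the synthetic-cohort experiments do and do not demonstrate.

## Data model

All code data are reduced to **presence semantics** at ingestion: a
(patient, code, system) triple is kept once regardless of how often or when
it was documented. This matches the prediction target — eligibility is a
property of the patient, not of an encounter — and makes the feature matrix
binary. Codes are normalised to a canonical form (trimmed, upper-cased,
hyphens and dots preserved); diagnosis and procedure attributes are
namespaced `dx:` / `proc:` so the two catalogues cannot collide after
truncation. Gender is encoded as a single binary column (female = 0,
male = 1); age enters in years, untransformed, since ranking-based
evaluation is invariant to monotone rescaling for the tree ensembles, the
SVM pipeline standardises internally, and the logistic families estimate
their own slope.

Patients present in demographics but without any code record are retained
with all-zero code columns (such patients exist in real extracts). Patients
with codes but no demographics are rejected, because age and gender are
mandatory model inputs; how a production system should impute missing
demographics is left open here.

## Hierarchy aggregation

Category-level aggregation is purely syntactic: the first three characters
of an ICD-like code (letter + two digits) or the first four of an OPS-like
code (chapter digit, hyphen, two digits). No catalogue file is needed, and
the operation is idempotent.

Block-level aggregation needs real catalogue content — blocks are labelled
*ranges* of categories — so it is driven by an explicit block-map file.
The official German catalogues are licensed resources and are not
redistributed; the repository ships a small demonstration map
(`demo_block_map()`), and the synthetic generator emits a map covering its
whole code universe. Range containment is decided on parsed keys
(letter, number) / (chapter, number) rather than string comparison, which
breaks on mixed-width numerics.

A category not covered by any range **falls back to itself** with a warning
(strict mode turns this into an error). Silently dropping unmapped codes
would break the monotone-coarsening invariant (attribute counts
non-increasing, per-attribute prevalence and valued-cell fraction
non-decreasing from raw → category → block), which the test suite enforces
on random cohorts.

## Attribute selection

Univariate selection on the 2 × 2 attribute × eligibility table. The
χ² test of independence is used without continuity correction (1 df); when
any expected cell count is below 5 — Cochran's rule, strictly `< 5` — the
two-sided Fisher exact test is used instead. Degenerate tables (constant
attribute or single-class labels) are defined to return p = 1 with a
degeneracy flag rather than erroring, so a ranking over thousands of sparse
columns is total. Ties in either ranking break lexicographically by
attribute name, making rankings reproducible. Age and gender bypass
selection and are always included.

Selection statistics are computed **on the training partition only** by
default. Computing them on all patients would leak label information from
the holdout set into the model inputs; a `selection_scope: all`
configuration switch exists for comparison with pipelines that do rank on
the full dataset. In learning curves the ranking is recomputed on each
reduced training subset for the same reason (also switchable).

## Model families

| family | implementation | notable defaults |
|---|---|---|
| `cart_tree` | `sklearn.tree.DecisionTreeClassifier` | `min_samples_split=20`, `min_samples_leaf=7` (classical CART stopping à la rpart's minsplit/minbucket) |
| `random_forest` | `sklearn.ensemble.RandomForestClassifier` | 500 trees, √p candidate attributes per split, bootstrap resampling; `max_features=p` recovers pure bagging |
| `logistic` | `sklearn.linear_model.LogisticRegression` | unpenalised, lbfgs |
| `logistic_stepwise` | backward elimination over `statsmodels.Logit` fits | drop the term whose removal most lowers AIC, until none does |
| `svm` | `StandardScaler` + `sklearn.svm.SVC` | RBF kernel, C = 1, `gamma='scale'`, Platt sigmoid for probabilities |

The stepwise variant is written here because no installed library provides
R-style backward-AIC selection for logistic models; fits use lbfgs with
warnings suppressed, since quasi-separation is routine on sparse binary
columns and only the score ranking matters. Constant columns are dropped
before elimination (inestimable next to the intercept). Note that sklearn's
cost-complexity pruning is not identical to rpart's `cp` rule; the stopping
parameters above are the package's CART reading, not a bug-for-bug port.

Every family is wrapped behind one `train`/`score` interface: a
`TrainedModel` freezes its attribute schema and refuses mismatched columns,
scores are clipped into [0, 1] as a contract, and identical
(spec, seed, matrix) triples give identical scores. Class imbalance (down
to a few percent eligible) is handled by score ranking only — no
resampling or reweighting.

## Evaluation

* **Holdout split**: 1/3 test, stratified by label by default. With
  inclusion prevalences of a few percent an unstratified split can lose all
  eligible patients from one side; a flag restores unstratified splitting.
* **ROC-AUC**: trapezoidal area under the empirical ROC. Tied scores
  collapse to one curve vertex, so the trapezoid awards half credit — the
  statistic is exactly the concordant-pair (Mann–Whitney) count with ½ for
  ties, and the suite asserts equality against a brute-force pair-counting
  oracle to 1e-12.
* **Bootstrap CI**: percentile method, 1,000 resamples of (score, label)
  pairs, 2.5/97.5 quantiles (linear interpolation, the standard quantile
  definition). Resamples that lose a class are redrawn so the resample count
  stays exact. Inside the bootstrap the AUC is computed by a vectorised
  rank formula; its equality with the trapezoidal route is unit-tested.
* **Training-set reduction**: each step removes `round(0.3·n)` patients
  uniformly at random (unstratified), stopping when the remainder would
  fall below a configurable floor (default 10) or either class would drop
  below 2 patients — the trainability minimum every family requires. The
  test set stays fixed across the whole curve, so differences reflect
  training size only.
* **Grid**: families × aggregation levels × selection methods × k ×
  ladder sizes. Per-cell seeds derive from the master seed by hashing the
  cell coordinates (blake2s, 31-bit), so any cell reproduces in isolation;
  cell failures are recorded in the result row, never silently dropped.
  The per-level reduction ladder is shared across families so that family
  comparisons at a given size use identical training subsets.

## Synthetic cohorts

The generator emulates the structure of routine-code extracts:

* a mono-hierarchical universe per system (default 12 diagnosis and 8
  procedure blocks, 5 categories each, 5–6 full codes per category);
* background codes drawn per patient from independent Bernoulli columns
  with lognormal prevalences (σ = 0.7) whose median is the **sparsity
  dial** (default 0.4%, i.e. the matrix is ~0.5% valued before
  aggregation);
* ages uniform on 16–90 years, genders Bernoulli(0.5), both signal-free
  unless the rule uses age;
* a **planted rule** — by default *any code from 2 randomly chosen
  diagnosis blocks, and age ≥ 18* — whose code exposures are scattered as
  1 + Poisson(1) draws over the ~60 rare child codes of the signal blocks.
  The exposure probability is solved from the target inclusion prevalence
  (default 10%), and emitted labels equal the rule up to a symmetric flip
  probability (default 2%).

Because the rule is deterministic in the generated data, its evaluation is
a Bayes-optimal score and `bayes_auc` an explicit ceiling; under label
noise the ceiling has a closed form from the realized rule/label table,
which the tests verify exactly. Planting at the family level reproduces the
regime where hierarchy aggregation genuinely helps: at block level the
signal is 2 binary columns and models saturate the ceiling from ~80
training patients, while on raw codes the learning curve rises over the
whole training range — this is why the learning-curve trend checks run on
unaggregated codes and the ceiling-recovery check at block level.

What the generator does **not** emulate: correlated comorbidity structure,
coding-practice and billing effects, temporal admission structure, and
free-text or laboratory attributes. Passing tests therefore demonstrate
correctness of the machinery and recoverability of family-structured
signal, not expected performance on any real hospital's data.

## Problem sizes in the shipped experiments

Tests and the acceptance script run at 200–1,500 synthetic patients with
the evaluation constants above; checks that target determinism or curve
shape rather than interval quality use reduced bootstrap counts (50–200).
These sizes are the package's chosen demonstration scale — large enough
for the planted signal to be comfortably above selection noise, small
enough to iterate on quickly.

## Known limitations

* Category extraction trusts code syntax; malformed codes error rather
  than being coerced, and no validity check against official catalogues is
  performed.
* Stepwise logistic refits O(p²) models; it is the slowest family and is
  intended for the small post-selection attribute sets (≤ 42 columns), not
  for unreduced matrices.
* Bootstrap CIs are percentile CIs of the test-set AUC; they do not account
  for training-set variability.
* The screening path assumes the deployment extract uses the same code
  systems and block map as training; terminology drift is not detected
  beyond schema mismatches.
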