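# Methods

This note records the models implemented in `roughprog`, the conventions
chosen where the underlying theory leaves room, and what the synthetic
generators do and do not emulate.

## Decision tables and preference orders

A decision table holds objects described by condition attributes plus
exactly one decision attribute. Attributes are either *plain* (compared
only for equality) or *criteria*, whose declared domain order is a
preference order: gain criteria list values worst-to-best, cost criteria
best-to-worst. Internally every comparison is gain-oriented — a cost
criterion's rank is its reversed domain index — so the dominance
machinery never branches on orientation; the schema keeps the declared
orientation for reporting. The decision domain is always ordered
(worst-to-best), which is what makes upward/downward class unions well
defined. Domains are declared in the schema, never inferred from data: a
preference order cannot be recovered safely from observed values.

Object identifiers default to 1-based row numbers when no id column is
given. Tables are complete by contract — empty cells are either rejected
at load time or replaced by a per-attribute fill value.

## Approximations

CRSA partitions the universe by exact value-tuple equality (tables are
expected to be discretized first; there is deliberately no numeric
tolerance). Granules are reported in first-occurrence order so results
are reproducible.

DRSA defines x D_P y as: x outranks y on every criterion of P and equals
y on every plain attribute of P. A basis containing only plain attributes
therefore reduces dominance to indiscernibility. The upper approximation
of an upward union is implemented as the union of members' positive
cones; the equivalent characterization — objects whose negative cone
meets the union — is asserted against it in tests rather than assumed.

The strict quality of approximation is the fraction of objects outside
every downward-union boundary (equal to the upward-boundary version; the
equality is again tested, not assumed). Under variable consistency no
canonical quality formula exists, so this package defines it as: boundary
= upper approximation minus the VC lower approximation, pooled over both
directions of every union. This reduces to the strict definition at
l = 1 and is the documented, configurable convention behind
`drsa_quality(table, P, level)`.

In the seven-patient worked example the printed membership ratio 2/3 is
attributed to all four union members; for the two members whose positive
cone lies entirely inside the union the definition gives ratio 1, so the
package's tests assert the 2/3 value only for the two boundary-adjacent
members, where it follows from the definition.

## Discretization

Clinical severity scores rise monotonically with risk, which supplies the
preference order the dominance model needs. A scheme maps each raw
numeric attribute to ordered categories through explicit intervals; each
bin declares the closure of both endpoints, because clinical tables mix
conventions (the coma-score and hospital-day bins are right-closed, the
blood-gas bins left-closed). U-shaped risk — e.g. both bradycardia and
tachycardia scoring 5 while the normal band scores 0 — is expressed as
disjoint intervals sharing one output score; the output score scale is
monotone in risk even when the raw scale is not. Only four verified
fragments ship as defaults (coma score, blood-gas ratio, hospital day,
the 40–109 bpm pulse bands); full severity-score tables are user
configuration, to avoid inventing clinical content. Raw values of 0 for
heart rate, blood pressure or respiration can encode cardiac arrest in
source data; the shipped pulse fragment deliberately leaves 0 uncovered
so that user configuration must decide its score.

## Rule induction

Both inducers use sequential covering: grow one rule, remove the target
objects it covers, repeat until the target region is covered, then prune.
The target region of a class (MODLEM) is its classical lower
approximation; of a union (VC-DomLEM), its VC lower approximation at
level l. A rule closes when its consistency
μ = |[Φ(r)] ∩ target| / |[Φ(r)]| reaches the threshold (m or l); only
closing rules are emitted, so every emitted rule satisfies μ ≥ threshold.

Condition growth:

* **Candidates** are drawn from the values of currently uncovered target
  objects inside the matched set — the standard way to keep the search
  finite and anchored on objects still needing cover. A candidate is
  admissible when it strictly shrinks the matched set while keeping at
  least one uncovered target object. This admissibility rule (rather
  than requiring each step to improve the selection measure) guarantees
  termination, and at an attainable threshold guarantees every
  lower-approximation object ends up covered: when no admissible
  candidate remains the matched set has collapsed onto a single profile
  (CRSA) or a single positive cone (DRSA at l = 1), where μ = 1.
* **MODLEM** scores candidates by the Shannon entropy of the decision
  distribution over the would-be matched set (lower is better), ties by
  larger positive cover, then fixed attribute/domain order. On ordered
  attributes candidates are at-least / at-most cutpoints — the ordinal
  analogue of MODLEM's numeric cutpoints — so one attribute may
  contribute both ends of an interval; plain attributes contribute
  equality tests. Membership (∈ value-set) conditions are supported in
  the representation and matcher.
* **VC-DomLEM** scores candidates by μ of the extended rule, ties by
  coverage |[Φ(r ∪ ec)] ∩ target|, then fixed order. Criteria conditions
  are direction-locked: at-least for upward unions, at-most for downward;
  plain attributes use equality. Same-direction conditions on one
  criterion merge into the tighter bound, so no finalized rule carries a
  condition implied by another.
* An unattainable threshold (possible on inconsistent data when μ is
  measured against the VC lower approximation) discards the partial rule
  with a warning and removes the attempted objects from the uncovered
  pool, so induction always terminates.

Pruning drops per-rule conditions whose deletion leaves the matched set
unchanged (most recently added first), then removes any rule whose
covered positive objects are a subset of a same-consequent rule's with μ
no worse. Determinism: identical inputs and configuration always give
identical rule sets — every tie is broken by schema order, then domain
order, and candidate enumeration order is fixed.

Rules from boundary regions (range consequents) are represented,
matched and voted on, but never induced: induction runs from lower
approximations only, matching the study configuration this package
targets.

## Classification and threshold

A rule fires when every antecedent condition holds; union- and
range-consequent rules vote their full RHS support for every class in
the consequent (the consequent asserts membership in the union without
apportioning it further). Scores are votes normalized by the total LHS
support of fired rules. The decision compares the positive-class score
with τ: strictly above is positive, strictly below negative, exactly τ —
or no fired rules — is *undefined*. Undefined objects count as uncovered
in coverage, whichever of the two causes (tie or no fire) produced them.

For ROC analysis, undefined objects either receive an imputed score of
0.5 (default) or are excluded; the choice is configuration, both are
implemented, and reports state which was active, since published
evaluations rarely state the handling.

## Evaluation

AUC is the normalized Mann–Whitney statistic with ties counted half,
identical to trapezoidal integration of the empirical ROC with tied
scores collapsed; it is verified against an O(n²) concordance oracle and
scikit-learn. The operating point scans the unique score values and
returns the threshold minimizing the Euclidean distance from
(FPR, TPR) to (0, 1), smaller threshold on ties; sensitivity and
specificity are reported there, per fold, then averaged. Cohen's κ is
computed from the 2×2 confusion at that threshold; degenerate marginals
(chance agreement 1) yield κ = 0 with a warning.

Cross-validation uses seeded, class-stratified folds — stratification
keeps each fold near the cohort prevalence, which matters at ≈47%
positive rate — and reports per-fold values with means and standard
deviations. The grid search repeats this across consistency levels,
yielding the level × (AUC, coverage) table used to choose an operating
consistency level.

## Synthetic data

The seven-patient fixture is exact and is the anchor of the worked-example
tests.

The SUPPORT-like generator emulates the *structure* of a seriously-ill
cohort: 13 numeric attributes drawn inside the ranges observed in the
SUPPORT study, diagnosis-group and cancer-status categoricals at the
published proportions, and a binary six-month outcome at a configurable
prevalence (default 0.47). Each patient has a latent frailty; severity
levels per attribute are drawn with frailty-shifted probabilities and raw
values uniformly within the drawn level's interval, so discretization
recovers the level. The outcome is a deterministic threshold on the
weighted severity sum (plus group offsets: coma and multi-organ failure
with malignancy high, congestive heart failure and chronic obstructive
pulmonary disease low) cut at the (1 − prevalence) quantile; a
deterministic profile-hash jitter splits ties at the cut so the realized
prevalence is sharp while the outcome remains an exact function of the
discretized profile — hence γ = 1 at zero injected inconsistency.
Inconsistency is injected by overwriting sampled recipients' condition
profiles with a donor's profile and the opposite decision, creating
boundary regions of controlled size. The generator does **not** reproduce
the real cohort's joint distribution, correlations, or published
means/SDs, and its three-level severity bins for attributes beyond the
four verified fragments are synthetic stand-ins; tests passing on this
data demonstrate correctness of the machinery and qualitative behavior
(coverage falling as the consistency level tightens on inconsistent
data), not clinical performance on the real dataset.

Planted-rule tables draw objects uniformly over an all-criteria condition
space and label them positive exactly when one of the planted monotone
rules fires; the positive region is upward-closed by construction, so the
table is monotone-consistent and VC-DomLEM at l = 1 must recover the
planted covers exactly — which is tested.

## Problem sizes and numerics

Default test and evaluation sizes are chosen to exercise the machinery
well inside interactive runtimes: oracle-equivalence sweeps use hundreds
of random tables of at most 12 objects (where brute force is exact),
generator-based evaluations use cohorts of 200–1000 patients with 5-fold
cross-validation. Set-algebraic results are exact (no floating
tolerance); ratio comparisons in tests use absolute tolerances of 1e-12.
Entropy uses base-2 logarithms; μ and entropy comparisons during growth
are exact floating comparisons, with all residual ties broken by fixed
enumeration order.

## Known limitations

* Missing values are handled only at load time (reject or fill); the
  approximation theory itself assumes complete tables.
* Only the μ rule-consistency measure is implemented for VC-DomLEM, and
  only class entropy for MODLEM condition selection.
* No reduct computation, attribute-core analysis, or boundary-rule
  induction.
* Probability estimates are raw support frequencies; no calibration.
* The decision domain must be totally ordered; partial preference over
  three or more outcome classes is not supported.
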