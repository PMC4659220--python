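# roughprog

Rough-set prognostic classification for tabular clinical data: classical
(CRSA) and dominance-based (DRSA / VC-DRSA) rough set approximations,
MODLEM and VC-DomLEM decision-rule induction, a rule-voting classifier
with an explicit decision threshold, clinical-score discretization, and a
cross-validated evaluation suite.

## The problem

Prognostic questions such as *"will this seriously ill patient survive the
next six months?"* drive consequential decisions — hospice referral among
them — and the clinicians, patients and families making those decisions
need models whose reasoning they can inspect. Rough set theory offers
exactly that: instead of a fitted coefficient vector, it produces a set of
**if–then decision rules** read directly off a decision table of patients,
each rule annotated with the patients that support it.

Given a decision table *S* = (*U*, *A*, *V*, *f*) — objects *U*, condition
attributes *C* plus one decision attribute *d*, value sets *V*, and an
information function *f* — the toolkit provides:

* **CRSA**: the indiscernibility relation *R*(*B*) groups objects with
  identical values on *B* ⊆ *C* into granules; a decision class *Y* is
  approximated from below, R̲\_B(Y) = {x : [x]\_B ⊆ Y}, and from above,
  R̄\_B(Y) = {x : [x]\_B ∩ Y ≠ ∅}; their difference is the boundary of
  undecidable objects, and γ\_B(F) = Σ\_t |R̲\_B(Y\_t)| / |U| is the quality
  of approximation.
* **DRSA**: condition attributes with preference-ordered domains
  (*criteria*) induce a dominance relation — x dominates y when x is at
  least as good on every criterion and equal on every plain attribute.
  Upward unions Y\_t^≥ ("at least class t") are approximated from the
  positive dominance cones D\_P^+(x), downward unions from the negative
  cones.
* **VC-DRSA**: the variable-consistency relaxation admits x into the
  lower approximation of Y\_t^≥ when at least a fraction *l* ∈ (0,1] of
  D\_P^+(x) lies in the union, tolerating controlled inconsistency and
  avoiding the over-specific rules the strict model produces on noisy
  clinical data.
* **Rule induction**: sequential covering of each class (MODLEM, condition
  choice by class entropy) or each class union (VC-DomLEM, condition
  choice by the rule consistency μ = |[Φ(r)] ∩ Y̲\_t| / |[Φ(r)]|, ties by
  coverage), emitting only rules with μ at or above the configured
  consistency level, then pruning redundant conditions and rules.
* **Classification**: every fired rule votes its right-hand-side support;
  votes are normalized by the summed left-hand-side support of all fired
  rules, giving a frequency estimate of class probability, thresholded at
  τ (a score exactly at τ, or no fired rules, leaves the object
  *undefined*).
* **Evaluation**: stratified k-fold cross-validation reporting AUC,
  Cohen's κ, sensitivity/specificity at the ROC point nearest (0,1),
  coverage and rules-fired statistics, plus a consistency-level grid
  search.

## Worked example

The package ships a seven-patient coronary-disease table (`x1`…`x7`; five
gain criteria, plain attribute *Gender*, binary outcome):

```python
import roughprog as rp

table = rp.table1_fixture()
C = table.condition_names

rp.indiscernibility_partition(table, C)
# granules: [['x1'], ['x2'], ['x3', 'x4', 'x7'], ['x5', 'x6']]

appr = rp.approximate(table, C, "Yes")
# lower: ['x5', 'x6']  upper: ['x3', 'x4', 'x5', 'x6', 'x7']  boundary: ['x3', 'x4', 'x7']
rp.quality_of_classification(table, C)      # 0.5714285714285714  (= 4/7)

up = rp.upward_union(table, "Yes")
rp.vc_lower_approximation(table, C, up, 0.6)
# VC lower (l=0.6): ['x4', 'x5', 'x6', 'x7']

rules = rp.vcdomlem_induce(table, rp.InductionConfig(0.6, "mu"))
print(rp.render_rules(rules, table.decision))
# If SystBP >= H then Coronary disease >= Yes  [LHS=2, RHS=2, mu=1.000]
# If Age >= M then Coronary disease >= Yes  [LHS=6, RHS=4, mu=0.667]
# If HDL <= L and SystBP <= M then Coronary disease <= No  [LHS=2, RHS=2, mu=1.000]

patient = {"Gender": "F", "Age": "H", "SystBP": "M",
           "HDL": "H", "Diabetic": "No", "Smoker": "No"}
cs = rp.score(rules, patient, table.schema)
rp.classify(cs, 0.5, "Yes", "No")
# score[Yes]=0.667  ->  label 'Yes'
```

The three patients `x3`, `x4`, `x7` share one condition profile but split
2:1 on the outcome — the boundary region. The strict dominance model
certifies only `x5`, `x6` as surely diseased; relaxing the consistency
level to *l* = 0.6 admits `x4` and `x7` (two thirds of their dominating
cone has the disease), and the induced rule `Age >= M` then covers them
with μ = 2/3. The new patient fires that rule and is classified positive
at τ = 0.5 with an estimated probability of 4/6 ≈ 0.667.

## Synthetic cohorts and the command line

`roughprog.synthetic_data` generates SUPPORT-like cohorts — 13 numeric
physiology/demographic attributes inside the ranges observed in the
SUPPORT study, a diagnosis group, cancer status, and a binary six-month
death outcome at ≈47% prevalence — with controllable label inconsistency,
plus planted-rule tables for recovery testing. A thin CLI wraps the
library:

```sh
roughprog simulate --n 500 --seed 7 --prefix cohort
roughprog induce   --method vcdomlem --level 0.6 \
                   --table cohort_disc.csv --schema cohort_schema.yaml --out rules.jsonl
roughprog classify --rules rules.jsonl --table cohort_disc.csv \
                   --schema cohort_schema.yaml --tau 0.5
roughprog evaluate --method vcdomlem --table cohort_disc.csv \
                   --schema cohort_schema.yaml --cv 5 --seed 1 --grid 0.1,0.2,0.4,0.6,0.8,1.0
```

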