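"""Rule-voting classification of unseen objects.

Every rule whose antecedent matches the object "fires" and votes its RHS
support for its consequent class(es); votes are normalized by the summed
LHS support of all fired rules, giving a frequency-based estimate of class
membership probability.  A binary decision compares the positive-class
score with a threshold tau: strictly above is positive, strictly below
negative, and a score exactly at tau — or no fired rules at all — leaves
the object undefined (uncovered).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .decision_table import AttributeSpec, DecisionTable
from .errors import MissingCellError, ThresholdError
from .rule_induction import DecisionRule

log = logging.getLogger(__name__)


class _Undefined:
    """Sentinel label for objects the rule set cannot classify."""

    def __repr__(self):
        return "UNDEFINED"

    def __bool__(self):
        return False


UNDEFINED = _Undefined()


@dataclass
class ClassScore:
    """Normalized vote tally of one object over the decision classes."""

    object: str
    fired_rules: tuple
    votes: dict            # class -> summed RHS support
    total_lhs: int         # summed LHS support over fired rules
    score: dict            # class -> votes / total_lhs (0-filled)
    covered: bool          # at least one rule fired
    label: object = UNDEFINED
    tau: float | None = None


def matches(rule: DecisionRule, values: Mapping,
            schema: Sequence[AttributeSpec], *,
            missing: str = "warn") -> bool:
    """True iff every elementary condition holds for the object's values.

    A missing antecedent attribute makes the rule non-firing with a logged
    warning (set ``missing="error"`` to raise instead).
    """
    spec_of = {a.name: a for a in schema}
    for cond in rule.antecedent:
        if cond.attribute not in values:
            if missing == "error":
                raise MissingCellError(
                    f"object lacks a value for {cond.attribute!r}"
                )
            log.warning("rule references %r, absent from object; rule does not fire",
                        cond.attribute)
            return False
        if not cond.holds(values[cond.attribute], spec_of[cond.attribute]):
            return False
    return True


def score(ruleset: Sequence[DecisionRule], values: Mapping,
          schema: Sequence[AttributeSpec], object_id: str = "?") -> ClassScore:
    """Vote tally for one object: RHS-support votes over LHS normalization.

    Union- and range-consequent rules credit every class in their
    consequent with the full RHS weight.
    """
    decision = next(a for a in schema if a.role == "decision")
    fired = tuple(r for r in ruleset if matches(r, values, schema))
    votes = {c: 0 for c in decision.domain}
    total_lhs = 0
    for r in fired:
        total_lhs += r.lhs_support
        for c in r.consequent.classes(decision):
            votes[c] += r.rhs_support
    if total_lhs > 0:
        scores = {c: votes[c] / total_lhs for c in decision.domain}
    else:
        scores = {c: 0.0 for c in decision.domain}
    return ClassScore(
        object=object_id, fired_rules=fired, votes=votes,
        total_lhs=total_lhs, score=scores, covered=bool(fired),
    )


def classify(class_score: ClassScore, tau: float, positive_class,
             negative_class=None) -> object:
    """Threshold the positive-class score.

    Positive iff score > tau; negative iff score < tau; a score equal to
    tau, or an object with no fired rules, is UNDEFINED.  Returns the
    label and records it (with tau) on the ClassScore.
    """
    if not 0 <= tau <= 1:
        raise ThresholdError(f"tau must be in [0,1], got {tau}")
    class_score.tau = tau
    if not class_score.covered:
        class_score.label = UNDEFINED
        return UNDEFINED
    s = class_score.score[positive_class]
    if s > tau:
        class_score.label = positive_class
    elif s < tau:
        class_score.label = negative_class if negative_class is not None else "NOT-" + str(positive_class)
    else:
        class_score.label = UNDEFINED
    return class_score.label


def score_table(ruleset: Sequence[DecisionRule], table: DecisionTable,
                positive_class, tau: float | None = None) -> list:
    """Score every object of a table; classify when tau is given."""
    schema = table.schema
    decision = table.decision
    neg = [v for v in decision.domain if v != positive_class]
    negative = neg[0] if len(neg) == 1 else None
    out = []
    for o in table.objects:
        values = {k: v for k, v in table.row(o).items() if k != decision.name}
        cs = score(ruleset, values, schema, object_id=o)
        if tau is not None:
            classify(cs, tau, positive_class, negative)
        out.append(cs)
    return out
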