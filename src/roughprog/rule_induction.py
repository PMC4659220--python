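"""Sequential-covering induction of minimal decision-rule sets.

Two inducers share one skeleton.  MODLEM grows rules for each decision
class from its classical lower approximation, choosing at every step the
elementary condition that minimizes the class entropy of the covered set.
VC-DomLEM grows rules for each upward/downward union of classes from its
variable-consistency lower approximation, choosing the condition that
maximizes the rule consistency mu, with ties broken by coverage.  In both,
a rule closes once its consistency reaches the configured threshold, its
covered target objects are removed, and the loop repeats until the target
region is covered; redundant conditions and redundant rules are pruned.

Elementary conditions are equality tests on plain attributes and, on
criteria, outranking tests (at-least / at-most on the preference order).
Two same-direction conditions on one criterion merge into the tighter one,
and an at-least/at-most pair forms an interval, so finalized rules never
carry a condition implied by another.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .crsa import approximate
from .decision_table import AttributeSpec, ClassUnion, DecisionTable, class_unions, decision_classes
from .drsa import vc_lower_approximation
from .errors import ConsistencyLevelError, SchemaError, UndefinedRuleConsistencyError

RELATIONS = ("=", "in", ">=", "<=")


@dataclass(frozen=True)
class ElementaryCondition:
    """One clause of a rule antecedent: (attribute, relation, value).

    ``>=`` / ``<=`` compare positions on a criterion's preference order;
    ``in`` tests membership in a value set (MODLEM output only).
    """

    attribute: str
    relation: str
    value: object

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise SchemaError(f"unknown relation {self.relation!r}")
        if self.relation == "in":
            object.__setattr__(self, "value", frozenset(self.value))

    def holds(self, value, spec: AttributeSpec) -> bool:
        if self.relation == "=":
            return value == self.value
        if self.relation == "in":
            return value in self.value
        if self.relation == ">=":
            return spec.rank(value) >= spec.rank(self.value)
        return spec.rank(value) <= spec.rank(self.value)

    def render(self) -> str:
        if self.relation == "in":
            vals = ", ".join(str(v) for v in sorted(self.value, key=str))
            return f"{self.attribute} in {{{vals}}}"
        sym = {"=": "=", ">=": ">=", "<=": "<="}[self.relation]
        return f"{self.attribute} {sym} {self.value}"


@dataclass(frozen=True)
class Consequent:
    """Rule conclusion: a single class, a union, or a contiguous range.

    relation ``=`` names one decision class, ``>=`` / ``<=`` an upward or
    downward union, ``range`` a contiguous block (boundary-rule
    representation; supported for matching and voting, never induced).
    """

    relation: str
    value: object  # decision value, or (lo, hi) pair for "range"

    def classes(self, decision: AttributeSpec) -> tuple:
        dom = decision.domain
        if self.relation == "=":
            return (self.value,)
        if self.relation == ">=":
            return tuple(dom[dom.index(self.value):])
        if self.relation == "<=":
            return tuple(dom[: dom.index(self.value) + 1])
        lo, hi = self.value
        return tuple(dom[dom.index(lo): dom.index(hi) + 1])

    def render(self, decision: AttributeSpec) -> str:
        if self.relation == "range":
            lo, hi = self.value
            return f"{decision.name} in ({lo} .. {hi})"
        return f"{decision.name} {self.relation} {self.value}"


@dataclass(frozen=True)
class DecisionRule:
    """Finalized rule with its training supports.

    ``lhs_support`` counts training objects matched by the antecedent,
    ``rhs_support`` those also in the consequent class(es); ``mu`` is
    their ratio.
    """

    antecedent: tuple
    consequent: Consequent
    lhs_support: int
    rhs_support: int
    mu: float
    provenance: str = ""

    def render(self, decision: AttributeSpec) -> str:
        lhs = " and ".join(c.render() for c in self.antecedent) or "(anything)"
        return f"If {lhs} then {self.consequent.render(decision)}"


# -- matching ------------------------------------------------------------

def condition_holds(cond: ElementaryCondition, values, schema_lookup) -> bool:
    return cond.holds(values[cond.attribute], schema_lookup(cond.attribute))


def match_objects(table: DecisionTable,
                  antecedent: Iterable[ElementaryCondition]) -> frozenset:
    """Training objects satisfying every elementary condition."""
    matched = set(table.objects)
    for cond in antecedent:
        spec = table.spec(cond.attribute)
        matched = {o for o in matched if cond.holds(table.value(o, cond.attribute), spec)}
    return frozenset(matched)


def rule_mu(antecedent: Sequence[ElementaryCondition], table: DecisionTable,
            target: frozenset) -> float:
    """Rule consistency: fraction of antecedent-matching objects in the
    target region (the approximation the rule is grown for)."""
    if not antecedent:
        raise UndefinedRuleConsistencyError("antecedent is empty")
    phi = match_objects(table, antecedent)
    if not phi:
        raise UndefinedRuleConsistencyError("antecedent matches no object")
    return len(phi & target) / len(phi)


def _finalize(table: DecisionTable, antecedent, consequent: Consequent,
              provenance: str) -> DecisionRule:
    phi = match_objects(table, antecedent)
    members = set()
    classes = decision_classes(table)
    for c in consequent.classes(table.decision):
        members |= classes[c]
    rhs = len(phi & members)
    return DecisionRule(
        antecedent=tuple(antecedent), consequent=consequent,
        lhs_support=len(phi), rhs_support=rhs,
        mu=rhs / len(phi) if phi else 0.0, provenance=provenance,
    )


# -- config --------------------------------------------------------------

@dataclass(frozen=True)
class InductionConfig:
    """Induction settings: consistency threshold (m for MODLEM, l for
    VC-DomLEM), the condition-selection measure, and loop guards."""

    consistency_threshold: float = 1.0
    condition_measure: str = "entropy"  # "entropy" (MODLEM) or "mu" (VC-DomLEM)
    max_iterations: int = 10_000
    tie_break: str = "coverage"

    def __post_init__(self):
        if not 0 < self.consistency_threshold <= 1:
            raise ConsistencyLevelError(
                f"consistency threshold must be in (0,1], got {self.consistency_threshold}"
            )
        if self.condition_measure not in ("entropy", "mu"):
            raise SchemaError(f"unknown condition measure {self.condition_measure!r}")


# -- growth machinery ----------------------------------------------------

def _entropy(table: DecisionTable, phi) -> float:
    counts: dict = {}
    dname = table.decision.name
    for o in phi:
        v = table.value(o, dname)
        counts[v] = counts.get(v, 0) + 1
    n = len(phi)
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def _candidate_conditions(table, phi, uncovered, directions):
    """Candidate elementary conditions drawn from the values of currently
    uncovered target objects inside the matched set.

    ``directions`` maps each condition attribute to the admissible
    relations: ``("=",)`` for plain attributes, ``(">=", "<=")`` for
    MODLEM criteria, a single locked direction for VC-DomLEM.
    """
    seeds = phi & uncovered
    cands = []
    for spec in table.condition_attributes:
        present = {table.value(o, spec.name) for o in seeds}
        if spec.domain is None:
            raise SchemaError(
                f"attribute {spec.name!r} has no declared domain: "
                "discretize the table before rule induction"
            )
        for v in spec.domain:
            if v not in present:
                continue
            for rel in directions[spec.name]:
                cands.append(ElementaryCondition(spec.name, rel, v))
    return cands


def _add_condition(antecedent: list, cond: ElementaryCondition,
                   spec: AttributeSpec) -> list:
    """Append a condition, merging with any same-attribute condition so
    that no clause implies another (tighter bound wins)."""
    out = []
    merged = cond
    for c in antecedent:
        if c.attribute != cond.attribute or c.relation != cond.relation:
            out.append(c)
            continue
        if cond.relation == "=":
            merged = cond  # replace (same attribute equality)
        elif cond.relation == ">=":
            keep = c if spec.rank(c.value) >= spec.rank(cond.value) else cond
            merged = keep
        elif cond.relation == "<=":
            keep = c if spec.rank(c.value) <= spec.rank(cond.value) else cond
            merged = keep
        else:
            out.append(c)
            continue
    out.append(merged)
    return out


def _minimize_conditions(table, antecedent):
    """Drop conditions whose deletion leaves the matched set unchanged."""
    conds = list(antecedent)
    phi = match_objects(table, conds)
    changed = True
    while changed and len(conds) > 1:
        changed = False
        # try dropping most recently added conditions first
        for i in reversed(range(len(conds))):
            trial = conds[:i] + conds[i + 1:]
            if match_objects(table, trial) == phi:
                conds = trial
                changed = True
                break
    return conds


def _grow_rule(table, target, uncovered, directions, config):
    """Grow one rule by greedy condition addition.

    Candidates must shrink the matched set while keeping at least one
    uncovered target object; growth stops when the rule consistency
    reaches the threshold or no admissible candidate remains (then the
    partial rule is returned only if it meets the threshold).
    """
    antecedent: list = []
    phi = frozenset(table.objects)
    for _ in range(config.max_iterations):
        if antecedent and len(phi & target) / len(phi) >= config.consistency_threshold:
            return antecedent, phi
        best = None
        best_key = None
        for cond in _candidate_conditions(table, phi, uncovered, directions):
            spec = table.spec(cond.attribute)
            new_phi = frozenset(
                o for o in phi if cond.holds(table.value(o, cond.attribute), spec)
            )
            if new_phi == phi or not (new_phi & uncovered):
                continue
            pos = len(new_phi & target)
            if config.condition_measure == "entropy":
                key = (-_entropy(table, new_phi), pos)
            else:
                key = (pos / len(new_phi), pos)
            if best_key is None or key > best_key:
                best, best_key = (cond, new_phi), key
        if best is None:
            break
        cond, phi = best
        antecedent = _add_condition(antecedent, cond, table.spec(cond.attribute))
    if antecedent and len(phi & target) / len(phi) >= config.consistency_threshold:
        return antecedent, phi
    return None, phi


def _cover_target(table, target, consequent, directions, config, provenance):
    """Sequential covering of one target region (class or union)."""
    rules = []
    uncovered = set(target)
    guard = 0
    while uncovered:
        guard += 1
        if guard > config.max_iterations:
            warnings.warn(f"{provenance}: iteration guard reached, "
                          f"{len(uncovered)} target objects left uncovered")
            break
        antecedent, phi = _grow_rule(table, target, frozenset(uncovered),
                                     directions, config)
        if antecedent is None:
            warnings.warn(
                f"{provenance}: consistency threshold "
                f"{config.consistency_threshold} unattainable for "
                f"{len(phi & uncovered) or len(uncovered)} objects; rule discarded"
            )
            dropped = phi & uncovered
            if dropped:
                uncovered -= dropped
            else:
                break
            continue
        antecedent = _minimize_conditions(table, antecedent)
        phi = match_objects(table, antecedent)
        rules.append(_finalize(table, antecedent, consequent, provenance))
        newly = phi & uncovered
        if not newly:
            break
        uncovered -= newly
    return rules


# -- the two inducers ----------------------------------------------------

def modlem_induce(table: DecisionTable, config: InductionConfig | None = None):
    """MODLEM: entropy-guided rules from classical lower approximations.

    For each decision class, rules are grown from the class's lower
    approximation under the full condition-attribute set.  Conditions are
    equality tests on plain attributes and at-least / at-most cutpoints on
    ordered attributes (so one attribute may contribute both ends of an
    interval).  Each emitted rule has consistency >= m against its
    approximation.
    """
    config = config or InductionConfig(condition_measure="entropy")
    if config.condition_measure != "entropy":
        raise SchemaError("MODLEM uses the entropy condition measure")
    C = table.condition_names
    directions = {
        a.name: (">=", "<=") if a.is_ordered else ("=",)
        for a in table.condition_attributes
    }
    rules = []
    for value in table.decision.domain:
        target = approximate(table, C, value).lower
        if not target:
            continue
        rules += _cover_target(
            table, target, Consequent("=", value), directions, config,
            provenance=f"modlem:lower({value})",
        )
    return prune(rules, table)


def vcdomlem_induce(table: DecisionTable, config: InductionConfig | None = None):
    """VC-DomLEM: mu-guided rules from VC lower approximations of unions.

    For every non-trivial upward union, rules carry at-least conditions on
    criteria (and equality on plain attributes) and conclude membership in
    the union; downward unions mirror with at-most conditions.  Growth
    maximizes the rule consistency mu against the variable-consistency
    lower approximation at level l, ties broken by coverage; only rules
    with mu >= l are emitted.
    """
    config = config or InductionConfig(condition_measure="mu")
    if config.condition_measure != "mu":
        raise SchemaError("VC-DomLEM uses the mu condition measure")
    level = config.consistency_threshold
    C = table.condition_names
    dom = table.decision.domain
    rules = []
    for union in class_unions(table):
        trivial_up = union.direction == ">=" and union.cut_index == 0
        trivial_down = union.direction == "<=" and union.cut_index == len(dom) - 1
        if trivial_up or trivial_down:
            continue
        target = vc_lower_approximation(table, C, union, level)
        if not target:
            continue
        locked = ">=" if union.direction == ">=" else "<="
        directions = {
            a.name: (locked,) if a.is_criterion else ("=",)
            for a in table.condition_attributes
        }
        rules += _cover_target(
            table, target, Consequent(union.direction, union.cut_value),
            directions, config,
            provenance=f"vcdomlem:vclower({union.direction}{union.cut_value},l={level})",
        )
    return prune(rules, table)


# -- pruning -------------------------------------------------------------

def prune(ruleset: Sequence[DecisionRule], table: DecisionTable):
    """Minimality pass over a finished rule set.

    Per rule, conditions whose deletion leaves the matched set (hence mu
    and cover) unchanged are dropped.  Then any rule whose covered
    positive objects are a subset of a same-consequent rule's with mu no
    worse is removed.
    """
    minimized = []
    for r in ruleset:
        conds = tuple(_minimize_conditions(table, r.antecedent))
        if conds != r.antecedent:
            r = _finalize(table, conds, r.consequent, r.provenance)
        minimized.append(r)

    classes = decision_classes(table)
    covers = []
    for r in minimized:
        members = set()
        for c in r.consequent.classes(table.decision):
            members |= classes[c]
        covers.append(match_objects(table, r.antecedent) & members)

    keep = [True] * len(minimized)
    for i, ri in enumerate(minimized):
        for j, rj in enumerate(minimized):
            if i == j or not keep[j]:
                continue
            same = ri.consequent == rj.consequent
            if same and covers[i] <= covers[j] and rj.mu >= ri.mu:
                if covers[i] == covers[j] and ri.mu == rj.mu and i < j:
                    continue  # identical pair: keep the first
                keep[i] = False
                break
    return [r for r, k in zip(minimized, keep) if k]


# -- serialization -------------------------------------------------------

def rule_to_dict(rule: DecisionRule) -> dict:
    return {
        "antecedent": [
            {"attribute": c.attribute, "relation": c.relation,
             "value": sorted(c.value, key=str) if c.relation == "in" else c.value}
            for c in rule.antecedent
        ],
        "consequent": {"relation": rule.consequent.relation,
                       "value": list(rule.consequent.value)
                       if rule.consequent.relation == "range"
                       else rule.consequent.value},
        "lhs_support": rule.lhs_support,
        "rhs_support": rule.rhs_support,
        "mu": rule.mu,
        "provenance": rule.provenance,
    }


def rule_from_dict(d: dict) -> DecisionRule:
    cons = d["consequent"]
    value = tuple(cons["value"]) if cons["relation"] == "range" else cons["value"]
    return DecisionRule(
        antecedent=tuple(
            ElementaryCondition(c["attribute"], c["relation"],
                                frozenset(c["value"]) if c["relation"] == "in"
                                else c["value"])
            for c in d["antecedent"]
        ),
        consequent=Consequent(cons["relation"], value),
        lhs_support=int(d["lhs_support"]),
        rhs_support=int(d["rhs_support"]),
        mu=float(d["mu"]),
        provenance=d.get("provenance", ""),
    )


def save_rules(rules: Sequence[DecisionRule], path) -> None:
    with open(path, "w") as fh:
        for r in rules:
            fh.write(json.dumps(rule_to_dict(r)) + "\n")


def load_rules(path) -> list:
    rules = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            rules.append(rule_from_dict(json.loads(line)))
    return rules


def render_rules(rules: Sequence[DecisionRule], decision: AttributeSpec) -> str:
    lines = []
    for r in rules:
        lines.append(f"{r.render(decision)}  "
                     f"[LHS={r.lhs_support}, RHS={r.rhs_support}, mu={r.mu:.3f}]")
    return "\n".join(lines)
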