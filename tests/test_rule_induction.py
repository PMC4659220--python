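"""MODLEM / VC-DomLEM induction: worked example, invariants, and an
exhaustive small-rule-space oracle on random tables."""

import itertools

import numpy as np
import pytest

from roughprog.crsa import approximate
from roughprog.decision_table import (
    AttributeSpec,
    DecisionTable,
    class_unions,
    decision_classes,
    upward_union,
)
from roughprog.drsa import vc_lower_approximation
from roughprog.errors import UndefinedRuleConsistencyError
from roughprog.rule_induction import (
    Consequent,
    DecisionRule,
    ElementaryCondition,
    InductionConfig,
    load_rules,
    match_objects,
    modlem_induce,
    prune,
    rule_mu,
    save_rules,
    vcdomlem_induce,
)

from conftest import random_table

EC = ElementaryCondition


def positive_cover(table, rule):
    classes = decision_classes(table)
    members = set()
    for c in rule.consequent.classes(table.decision):
        members |= classes[c]
    return match_objects(table, rule.antecedent) & members


class TestRuleMu:
    def test_exact_rule_has_mu_one(self, table1):
        ante = (EC("Age", "=", "H"), EC("Smoker", "=", "Yes"))
        target = decision_classes(table1)["Yes"]
        assert match_objects(table1, ante) == {"x5", "x6"}
        assert rule_mu(ante, table1, target) == 1.0

    def test_partial_rule_mu_two_thirds(self, table1):
        ante = (EC("Age", "=", "H"),)
        target = decision_classes(table1)["Yes"]
        assert match_objects(table1, ante) == {"x1", "x5", "x6"}
        assert rule_mu(ante, table1, target) == pytest.approx(2 / 3)

    def test_rule_matching_only_target_members(self, table1):
        ante = (EC("Diabetic", "=", "Yes"),)
        target = decision_classes(table1)["Yes"]
        assert rule_mu(ante, table1, target) == 1.0

    def test_empty_match_raises(self, table1):
        ante = (EC("Age", "=", "L"), EC("Age", "=", "H"))
        with pytest.raises(UndefinedRuleConsistencyError):
            rule_mu(ante, table1, decision_classes(table1)["Yes"])

    def test_criterion_conditions_use_domain_order(self, table1):
        ante = (EC("Age", ">=", "M"),)
        phi = match_objects(table1, ante)
        assert phi == {"x1", "x3", "x4", "x5", "x6", "x7"}  # Age L excluded


class TestModlem:
    def test_worked_example_contains_paper_rule_cover(self, table1):
        rules = modlem_induce(table1, InductionConfig(1.0, "entropy"))
        yes_rules = [r for r in rules if r.consequent.classes(table1.decision) == ("Yes",)]
        covers = [match_objects(table1, r.antecedent) for r in yes_rules]
        assert frozenset({"x5", "x6"}) in covers

    def test_perfect_single_attribute_gives_one_rule_per_class(self):
        schema = [AttributeSpec("marker", "attribute", ("neg", "pos")),
                  AttributeSpec("noise", "attribute", ("a", "b")),
                  AttributeSpec("d", "decision", ("No", "Yes"))]
        vals = {}
        for i in range(8):
            m = "pos" if i % 2 else "neg"
            vals[str(i + 1)] = {"marker": m, "noise": "ab"[i % 3 % 2],
                                "d": "Yes" if m == "pos" else "No"}
        t = DecisionTable(list(vals), schema, vals)
        rules = modlem_induce(t, InductionConfig(1.0, "entropy"))
        assert len(rules) == 2
        assert all(len(r.antecedent) == 1 for r in rules)
        assert {r.antecedent[0].value for r in rules} == {"neg", "pos"}

    @pytest.mark.parametrize("seed", range(12))
    def test_mu_one_rules_cover_lower_approximations(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_obj=8, n_classes=2)
        rules = modlem_induce(t, InductionConfig(1.0, "entropy"))
        for r in rules:
            assert r.mu == 1.0
        for v in t.decision.domain:
            lower = approximate(t, t.condition_names, v).lower
            covered = set()
            for r in rules:
                if v in r.consequent.classes(t.decision):
                    covered |= match_objects(t, r.antecedent)
            assert lower <= covered

    @pytest.mark.parametrize("seed", range(6))
    def test_against_exhaustive_small_rule_oracle(self, seed):
        # every induced rule must be reproducible by some rule of <= 2
        # conditions from the exhaustive space with the same cover, or be
        # a longer rule that still satisfies mu = 1
        rng = np.random.default_rng(100 + seed)
        t = random_table(rng, n_obj=8, n_attr=3, n_classes=2)
        rules = modlem_induce(t, InductionConfig(1.0, "entropy"))

        # exhaustive single/double condition rule space
        singles = []
        for spec in t.condition_attributes:
            rels = (">=", "<=") if spec.is_ordered else ("=",)
            for rel in rels:
                for v in spec.domain:
                    singles.append(EC(spec.name, rel, v))
        space_covers = set()
        for conds in itertools.chain(
                ((c,) for c in singles),
                itertools.combinations(singles, 2)):
            phi = match_objects(t, conds)
            if phi:
                space_covers.add(phi)

        for r in rules:
            assert r.mu == 1.0
            phi = match_objects(t, r.antecedent)
            if len(r.antecedent) <= 2:
                assert phi in space_covers

    def test_every_rule_meets_threshold(self):
        rng = np.random.default_rng(77)
        for m in (0.6, 0.8, 1.0):
            t = random_table(rng, n_obj=10, n_classes=2)
            rules = modlem_induce(t, InductionConfig(m, "entropy"))
            for r in rules:
                lower = None
                for v in t.decision.domain:
                    if v in r.consequent.classes(t.decision):
                        lower = approximate(t, t.condition_names, v).lower
                assert rule_mu(r.antecedent, t, lower) >= m - 1e-12

    def test_deterministic(self, table1):
        a = modlem_induce(table1, InductionConfig(1.0, "entropy"))
        b = modlem_induce(table1, InductionConfig(1.0, "entropy"))
        assert a == b


class TestVcDomlem:
    def test_strict_level_covers_strict_lower(self, table1):
        rules = vcdomlem_induce(table1, InductionConfig(1.0, "mu"))
        up = [r for r in rules if r.consequent.relation == ">="]
        covered = set()
        for r in up:
            assert r.mu == 1.0
            covered |= match_objects(table1, r.antecedent)
        assert covered == {"x5", "x6"}

    def test_relaxed_level_covers_vc_lower(self, table1):
        rules = vcdomlem_induce(table1, InductionConfig(0.6, "mu"))
        up = [r for r in rules if r.consequent.relation == ">="]
        covered = set()
        for r in up:
            assert r.mu >= 0.6 - 1e-12
            covered |= match_objects(table1, r.antecedent)
        assert {"x4", "x5", "x6", "x7"} <= covered

    def test_one_class_table_yields_no_rules(self):
        schema = [AttributeSpec("a", "gain_criterion", (0, 1)),
                  AttributeSpec("d", "decision", ("No", "Yes"))]
        vals = {str(i): {"a": i % 2, "d": "No"} for i in range(1, 5)}
        t = DecisionTable(list(vals), schema, vals)
        rules = vcdomlem_induce(t, InductionConfig(1.0, "mu"))
        assert [r for r in rules if r.consequent.relation == ">="] == []

    def test_condition_directions_respect_union(self, table1):
        rules = vcdomlem_induce(table1, InductionConfig(0.6, "mu"))
        for r in rules:
            for c in r.antecedent:
                spec = table1.spec(c.attribute)
                if spec.is_criterion:
                    assert c.relation == (">=" if r.consequent.relation == ">="
                                          else "<=")
                else:
                    assert c.relation == "="

    @pytest.mark.parametrize("seed", range(8))
    def test_emitted_mu_meets_level_on_random_tables(self, seed):
        rng = np.random.default_rng(300 + seed)
        t = random_table(rng, n_obj=10, n_classes=2, criteria_only=True)
        for level in (0.6, 1.0):
            rules = vcdomlem_induce(t, InductionConfig(level, "mu"))
            for r in rules:
                assert r.mu >= level - 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_strict_rules_cover_strict_lower_random(self, seed):
        rng = np.random.default_rng(400 + seed)
        t = random_table(rng, n_obj=10, n_classes=2, criteria_only=True)
        rules = vcdomlem_induce(t, InductionConfig(1.0, "mu"))
        for union in class_unions(t):
            trivial = (union.direction == ">=" and union.cut_index == 0) or \
                (union.direction == "<=" and
                 union.cut_index == len(t.decision.domain) - 1)
            if trivial:
                continue
            lower = vc_lower_approximation(t, t.condition_names, union, 1.0)
            covered = set()
            for r in rules:
                if (r.consequent.relation, r.consequent.value) == \
                        (union.direction, union.cut_value):
                    covered |= match_objects(t, r.antecedent)
            assert lower <= covered

    def test_deterministic(self, table1):
        a = vcdomlem_induce(table1, InductionConfig(0.6, "mu"))
        b = vcdomlem_induce(table1, InductionConfig(0.6, "mu"))
        assert a == b


class TestPrune:
    def test_duplicate_rule_collapses(self, table1):
        ante = (EC("Age", "=", "H"), EC("Smoker", "=", "Yes"))
        r = DecisionRule(ante, Consequent("=", "Yes"), 2, 2, 1.0)
        out = prune([r, r], table1)
        assert out == [r]

    def test_redundant_condition_removed(self, table1):
        ante = (EC("Age", "=", "H"), EC("Smoker", "=", "Yes"),
                EC("Gender", "=", "M"))
        r = DecisionRule(ante, Consequent("=", "Yes"), 2, 2, 1.0)
        out = prune([r], table1)
        assert len(out) == 1
        attrs = {c.attribute for c in out[0].antecedent}
        assert "Gender" not in attrs
        assert match_objects(table1, out[0].antecedent) == {"x5", "x6"}

    def test_subsumed_rule_removed(self, table1):
        broad = DecisionRule((EC("Diabetic", "=", "Yes"),),
                             Consequent("=", "Yes"), 2, 2, 1.0)
        narrow = DecisionRule((EC("Age", "=", "H"), EC("Smoker", "=", "Yes"),
                               EC("Diabetic", "=", "Yes")),
                              Consequent("=", "Yes"), 2, 2, 1.0)
        out = prune([broad, narrow], table1)
        assert len(out) == 1

    def test_minimal_set_is_fixpoint(self, table1):
        rules = modlem_induce(table1, InductionConfig(1.0, "entropy"))
        assert prune(rules, table1) == rules


class TestSerialization:
    def test_jsonl_roundtrip(self, tmp_path, table1):
        rules = vcdomlem_induce(table1, InductionConfig(0.6, "mu"))
        p = tmp_path / "rules.jsonl"
        save_rules(rules, p)
        again = load_rules(p)
        assert again == rules

    def test_render_matches_if_then_style(self, table1):
        rules = modlem_induce(table1, InductionConfig(1.0, "entropy"))
        text = rules[0].render(table1.decision)
        assert text.startswith("If ") and " then Coronary disease" in text
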