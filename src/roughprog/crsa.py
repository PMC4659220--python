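"""Classical rough set approximations over indiscernibility partitions.

Objects identical on every attribute of a subset B are indiscernible; the
induced equivalence classes are the information granules from which a
concept (decision class) is approximated from below (granules fully inside
the concept) and from above (granules touching it).  The gap between the
two is the boundary region of objects whose membership the attributes in B
cannot settle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .decision_table import DecisionTable, decision_classes
from .errors import SchemaError, UnknownDecisionValueError


@dataclass(frozen=True)
class ApproximationResult:
    """Lower/upper/boundary sets for one concept, plus the basis used."""

    concept: object
    basis: tuple
    lower: frozenset
    upper: frozenset
    boundary: frozenset
    gamma: float | None = None


def _check_basis(table: DecisionTable, attributes: Sequence[str]) -> tuple:
    attrs = tuple(attributes)
    if not attrs:
        raise SchemaError("attribute subset must be nonempty")
    dname = table.decision.name
    for a in attrs:
        table.spec(a)
        if a == dname:
            raise SchemaError("decision attribute cannot enter the basis")
    return attrs


def indiscernibility_partition(table: DecisionTable,
                               attributes: Sequence[str]) -> list:
    """Equivalence classes of the indiscernibility relation R(B).

    Classes are reported in first-occurrence order of their members;
    equality is exact categorical equality (tables are expected to be
    discretized first).
    """
    attrs = _check_basis(table, attributes)
    groups: dict = {}
    for o in table.objects:
        key = tuple(table.value(o, a) for a in attrs)
        groups.setdefault(key, set()).add(o)
    return [frozenset(s) for s in groups.values()]


def approximate(table: DecisionTable, attributes: Sequence[str],
                decision_value) -> ApproximationResult:
    """Lower and upper approximation of one decision class."""
    attrs = _check_basis(table, attributes)
    if decision_value not in table.decision.domain:
        raise UnknownDecisionValueError(
            f"{decision_value!r} is not a decision value"
        )
    concept = decision_classes(table)[decision_value]
    lower, upper = set(), set()
    for granule in indiscernibility_partition(table, attrs):
        if granule <= concept:
            lower |= granule
        if granule & concept:
            upper |= granule
    lower, upper = frozenset(lower), frozenset(upper)
    return ApproximationResult(
        concept=decision_value, basis=attrs,
        lower=lower, upper=upper, boundary=upper - lower,
    )


def quality_of_classification(table: DecisionTable,
                              attributes: Sequence[str]) -> float:
    """Fraction of objects in some lower approximation (gamma_B of F)."""
    attrs = _check_basis(table, attributes)
    total = sum(
        len(approximate(table, attrs, v).lower) for v in table.decision.domain
    )
    return total / len(table)
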