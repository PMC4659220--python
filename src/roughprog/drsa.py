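"""Dominance-based rough set approximations of class unions.

Where the classical approach granulates by equality, the dominance-based
approach orders objects: x dominates y when x is at least as good on every
criterion of the basis P and equal on every plain attribute of P.  The
positive cone of x holds the objects dominating x, the negative cone those
x dominates.  Upward unions of decision classes ("at least class t") are
approximated from cones; the variable-consistency relaxation admits an
object into a lower approximation when at least a fraction l of its cone
agrees with the union, tolerating a controlled amount of inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .crsa import ApproximationResult, _check_basis
from .decision_table import ClassUnion, DecisionTable, class_unions
from .errors import ConsistencyLevelError, UnknownObjectError


@dataclass(frozen=True)
class DominanceCones:
    object: str
    basis: tuple
    positive: frozenset  # objects dominating x (including x)
    negative: frozenset  # objects dominated by x (including x)


def dominates(table: DecisionTable, attributes: Sequence[str],
              xi: str, xj: str) -> bool:
    """True iff xi outranks xj on every criterion of the basis and matches
    it exactly on every plain attribute of the basis.

    A basis of plain attributes only reduces dominance to indiscernibility.
    """
    attrs = _check_basis(table, attributes)
    for o in (xi, xj):
        if o not in table:
            raise UnknownObjectError(f"unknown object {o!r}")
    for a in attrs:
        spec = table.spec(a)
        vi, vj = table.value(xi, a), table.value(xj, a)
        if spec.is_criterion:
            if spec.rank(vi) < spec.rank(vj):
                return False
        elif vi != vj:
            return False
    return True


def dominance_cones(table: DecisionTable, attributes: Sequence[str],
                    x: str) -> DominanceCones:
    attrs = _check_basis(table, attributes)
    if x not in table:
        raise UnknownObjectError(f"unknown object {x!r}")
    pos = frozenset(y for y in table.objects if dominates(table, attrs, y, x))
    neg = frozenset(y for y in table.objects if dominates(table, attrs, x, y))
    return DominanceCones(object=x, basis=attrs, positive=pos, negative=neg)


def _cone(table, attrs, x, direction):
    """Positive cone for upward unions, negative cone for downward."""
    c = dominance_cones(table, attrs, x)
    return c.positive if direction == ">=" else c.negative


def drsa_approximate(table: DecisionTable, attributes: Sequence[str],
                     union: ClassUnion) -> ApproximationResult:
    """Strict lower/upper approximation of an upward or downward union.

    Lower: objects whose whole (positive resp. negative) cone lies in the
    union.  Upper: union of the members' cones — equivalently the objects
    whose opposite cone meets the union.
    """
    attrs = _check_basis(table, attributes)
    members = union.members
    if not members <= set(table.objects):
        raise UnknownObjectError("union members not drawn from this table")
    lower, upper = set(), set()
    for x in table.objects:
        cone = _cone(table, attrs, x, union.direction)
        if cone <= members:
            lower.add(x)
    for x in members:
        # union of members' positive cones (upward) / negative cones (downward)
        upper |= _cone(table, attrs, x, union.direction)
    lower, upper = frozenset(lower), frozenset(upper)
    return ApproximationResult(
        concept=union, basis=attrs,
        lower=lower, upper=upper, boundary=upper - lower,
    )


def vc_lower_approximation(table: DecisionTable, attributes: Sequence[str],
                           union: ClassUnion, level: float) -> frozenset:
    """Variable-consistency lower approximation at object consistency l.

    A union member x is admitted when at least a fraction l of its cone
    (positive for upward unions, negative for downward) belongs to the
    union.  l = 1 recovers the strict lower approximation.
    """
    if not 0 < level <= 1:
        raise ConsistencyLevelError(f"consistency level must be in (0,1], got {level}")
    attrs = _check_basis(table, attributes)
    out = set()
    for x in union.members:
        cone = _cone(table, attrs, x, union.direction)
        if len(cone & union.members) / len(cone) >= level:
            out.add(x)
    return frozenset(out)


def consistency_ratio(table: DecisionTable, attributes: Sequence[str],
                      union: ClassUnion, x: str) -> float:
    """Fraction of x's cone lying in the union (the VC admission statistic)."""
    attrs = _check_basis(table, attributes)
    cone = _cone(table, attrs, x, union.direction)
    return len(cone & union.members) / len(cone)


def drsa_quality(table: DecisionTable, attributes: Sequence[str],
                 level: float | None = None) -> float:
    """Quality of approximation of the ordered classification.

    Strict case: fraction of objects outside every downward-union boundary
    (equal to the upward-boundary version).  With a consistency level l,
    boundaries are taken as upper approximation minus the VC lower
    approximation and pooled over both directions.
    """
    attrs = _check_basis(table, attributes)
    inconsistent: set = set()
    for union in class_unions(table):
        approx = drsa_approximate(table, attrs, union)
        if level is None:
            if union.direction == "<=":
                inconsistent |= approx.boundary
        else:
            lower = vc_lower_approximation(table, attrs, union, level)
            inconsistent |= approx.upper - lower
    return (len(table) - len(inconsistent)) / len(table)
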