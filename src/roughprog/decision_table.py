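"""Decision tables with mixed plain attributes and preference-ordered criteria.

An information system is a table of objects (rows) described by condition
attributes plus one decision attribute.  Attributes split into *plain*
attributes, compared only for equality, and *criteria*, whose value domains
carry a preference order (gain: higher is better; cost: lower is better).
The decision attribute's domain is always preference-ordered, which lets the
dominance-based machinery form upward and downward unions of decision
classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    DomainViolationError,
    DuplicateObjectError,
    MissingCellError,
    NoObjectsError,
    SchemaError,
    UnknownColumnError,
    UnknownObjectError,
    UnorderedDomainError,
)

ROLES = ("attribute", "gain_criterion", "cost_criterion", "decision")


@dataclass(frozen=True)
class AttributeSpec:
    """Schema entry for one attribute.

    Parameters
    ----------
    name
        Column name in the data file.
    role
        ``attribute`` (plain, equality-only), ``gain_criterion`` /
        ``cost_criterion`` (preference-ordered), or ``decision``.
    domain
        Admissible values, listed worst-to-best for gain criteria and the
        decision, best-to-worst for cost criteria.  ``None`` marks an
        unconstrained numeric column (allowed only for plain attributes,
        e.g. raw physiology before discretization).
    missing_policy
        ``reject`` (default) raises on empty cells; ``fill_value``
        substitutes ``fill_value``.
    """

    name: str
    role: str
    domain: tuple | None = None
    missing_policy: str = "reject"
    fill_value: object = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for attribute {self.name!r}")
        if self.missing_policy not in ("reject", "fill_value"):
            raise SchemaError(f"unknown missing policy {self.missing_policy!r}")
        if self.domain is not None:
            dom = tuple(self.domain)
            if len(set(dom)) != len(dom):
                raise SchemaError(f"domain of {self.name!r} has duplicate values")
            object.__setattr__(self, "domain", dom)
        elif self.role != "attribute":
            raise SchemaError(
                f"{self.name!r}: only plain attributes may omit a domain"
            )

    @property
    def is_criterion(self) -> bool:
        return self.role in ("gain_criterion", "cost_criterion")

    @property
    def is_ordered(self) -> bool:
        return self.role in ("gain_criterion", "cost_criterion", "decision")

    def rank(self, value) -> int:
        """Preference rank of ``value``: larger rank = more preferred.

        Cost criteria are normalized here by reversing the declared order,
        so every downstream comparison is gain-oriented; the schema keeps
        the original orientation for reporting.
        """
        if not self.is_ordered:
            raise UnorderedDomainError(f"{self.name!r} carries no preference order")
        try:
            i = self.domain.index(value)
        except ValueError:
            raise DomainViolationError(
                f"value {value!r} not in domain of {self.name!r}"
            ) from None
        return len(self.domain) - 1 - i if self.role == "cost_criterion" else i

    def validate_value(self, value) -> None:
        if self.domain is not None and value not in self.domain:
            raise DomainViolationError(
                f"value {value!r} outside domain of attribute {self.name!r}"
            )


@dataclass(frozen=True)
class ClassUnion:
    """Upward (``>=``) or downward (``<=``) union of decision classes.

    ``cut_index`` indexes the ordered decision domain (0-based); an upward
    union collects every object whose decision class is at least as
    preferred as the cut, a downward union those at most as preferred.
    """

    direction: str  # '>=' or '<='
    cut_index: int
    cut_value: object
    members: frozenset

    def __post_init__(self):
        if self.direction not in (">=", "<="):
            raise ValueError(f"direction must be '>=' or '<=', got {self.direction!r}")


class DecisionTable:
    """Validated objects x attributes table with exactly one decision column."""

    def __init__(self, objects: Sequence[str], schema: Sequence[AttributeSpec],
                 values: Mapping[str, Mapping[str, object]]):
        objects = tuple(str(o) for o in objects)
        if len(objects) == 0:
            raise NoObjectsError("decision table has no objects")
        if len(set(objects)) != len(objects):
            seen, dup = set(), None
            for o in objects:
                if o in seen:
                    dup = o
                    break
                seen.add(o)
            raise DuplicateObjectError(f"duplicate object id {dup!r}")
        schema = tuple(schema)
        decisions = [a for a in schema if a.role == "decision"]
        if len(decisions) != 1:
            raise SchemaError(
                f"schema must declare exactly one decision attribute, got {len(decisions)}"
            )
        names = [a.name for a in schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names in schema")
        self._objects = objects
        self._schema = schema
        self._spec = {a.name: a for a in schema}
        self._values = {
            o: {a.name: values[o][a.name] for a in schema} for o in objects
        }
        for o in objects:
            for a in schema:
                a.validate_value(self._values[o][a.name])

    # -- basic accessors -------------------------------------------------
    @property
    def objects(self) -> tuple:
        return self._objects

    @property
    def schema(self) -> tuple:
        return self._schema

    @property
    def decision(self) -> AttributeSpec:
        return next(a for a in self._schema if a.role == "decision")

    @property
    def condition_attributes(self) -> tuple:
        return tuple(a for a in self._schema if a.role != "decision")

    @property
    def condition_names(self) -> tuple:
        return tuple(a.name for a in self.condition_attributes)

    def spec(self, name: str) -> AttributeSpec:
        try:
            return self._spec[name]
        except KeyError:
            raise UnknownColumnError(f"unknown attribute {name!r}") from None

    def value(self, obj: str, attr: str):
        try:
            row = self._values[obj]
        except KeyError:
            raise UnknownObjectError(f"unknown object {obj!r}") from None
        return row[self.spec(attr).name]

    def row(self, obj: str) -> dict:
        try:
            return dict(self._values[obj])
        except KeyError:
            raise UnknownObjectError(f"unknown object {obj!r}") from None

    def __len__(self) -> int:
        return len(self._objects)

    def __contains__(self, obj) -> bool:
        return obj in self._values

    # -- conversions -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self._values[o] for o in self._objects],
            index=list(self._objects),
            columns=[a.name for a in self._schema],
        )

    def to_csv(self, path, id_column: str = "id") -> None:
        frame = self.to_frame()
        frame.index.name = id_column
        frame.to_csv(path)

    def replace_values(self, objects=None, schema=None, values=None) -> "DecisionTable":
        return DecisionTable(
            objects if objects is not None else self._objects,
            schema if schema is not None else self._schema,
            values if values is not None else self._values,
        )


# -- schema I/O ----------------------------------------------------------

def schema_to_dicts(schema: Iterable[AttributeSpec]) -> list:
    out = []
    for a in schema:
        entry = {"name": a.name, "role": a.role,
                 "domain": None if a.domain is None else list(a.domain)}
        if a.missing_policy != "reject":
            entry["missing_policy"] = a.missing_policy
            entry["fill_value"] = a.fill_value
        out.append(entry)
    return out


def schema_from_dicts(entries: Iterable[Mapping]) -> list:
    return [
        AttributeSpec(
            name=e["name"],
            role=e["role"],
            domain=None if e.get("domain") is None else tuple(e["domain"]),
            missing_policy=e.get("missing_policy", "reject"),
            fill_value=e.get("fill_value"),
        )
        for e in entries
    ]


def load_schema(path) -> list:
    """Read a schema config (YAML or JSON list of attribute entries)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return schema_from_dicts(data)


def save_schema(schema: Iterable[AttributeSpec], path) -> None:
    entries = schema_to_dicts(schema)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(entries, indent=1))
    else:
        Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


# -- table I/O -----------------------------------------------------------

def _coerce(spec: AttributeSpec, raw: str):
    """Match a CSV string cell against the declared domain.

    Domains may hold non-string values (e.g. integer scores); cells are
    matched first verbatim, then through the domain values' own repr.
    """
    if spec.domain is None:
        try:
            return float(raw)
        except (TypeError, ValueError):
            return raw
    if raw in spec.domain:
        return raw
    for v in spec.domain:
        if str(v) == raw:
            return v
    return raw  # left as-is; validate_value reports the violation


def load_table(path, schema: Sequence[AttributeSpec], id_column: str | None = None,
               delimiter: str = ",") -> DecisionTable:
    """Load a delimited text file into a validated ``DecisionTable``.

    The header row must name every schema attribute.  Row order becomes
    object order; object ids come from ``id_column`` when given, else
    1-based row numbers (``"1"``, ``"2"``, ...).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    for spec in schema:
        if spec.name not in frame.columns:
            raise UnknownColumnError(f"column {spec.name!r} not found in {path}")
    if id_column is not None and id_column not in frame.columns:
        raise UnknownColumnError(f"id column {id_column!r} not found in {path}")
    if len(frame) == 0:
        raise NoObjectsError(f"no objects: {path} has a header but no data rows")

    if id_column is not None:
        objects = [str(v) for v in frame[id_column]]
    else:
        objects = [str(i + 1) for i in range(len(frame))]

    values = {}
    for pos, obj in enumerate(objects):
        row = {}
        for spec in schema:
            raw = frame.iloc[pos][spec.name]
            if raw == "" or raw is None:
                if spec.missing_policy == "fill_value":
                    row[spec.name] = spec.fill_value
                    continue
                raise MissingCellError(
                    f"missing value at row {pos + 1}, column {spec.name!r}"
                )
            val = _coerce(spec, raw)
            if spec.domain is not None and val not in spec.domain:
                raise DomainViolationError(
                    f"row {pos + 1}, column {spec.name!r}: value {raw!r} "
                    f"outside domain {list(spec.domain)}"
                )
            row[spec.name] = val
        values[obj] = row
    return DecisionTable(objects, schema, values)


# -- decision classes and unions -----------------------------------------

def decision_classes(table: DecisionTable) -> dict:
    """Partition of the universe by decision value, in decision-domain order."""
    d = table.decision
    out = {v: set() for v in d.domain}
    for o in table.objects:
        out[table.value(o, d.name)].add(o)
    return {v: frozenset(s) for v, s in out.items()}


def class_unions(table: DecisionTable) -> list:
    """All upward and downward unions of decision classes.

    For a decision domain of size n this returns 2n unions; the upward
    union at the lowest cut and the downward union at the highest cut both
    equal the universe.
    """
    d = table.decision
    if len(d.domain) < 2:
        raise UnorderedDomainError(
            "class unions need at least two ordered decision classes"
        )
    classes = decision_classes(table)
    unions = []
    for t, v in enumerate(d.domain):
        up = frozenset().union(*(classes[w] for w in d.domain[t:]))
        unions.append(ClassUnion(">=", t, v, up))
    for t, v in enumerate(d.domain):
        down = frozenset().union(*(classes[w] for w in d.domain[: t + 1]))
        unions.append(ClassUnion("<=", t, v, down))
    return unions


def upward_union(table: DecisionTable, cut_value) -> ClassUnion:
    t = table.decision.domain.index(cut_value)
    return next(u for u in class_unions(table)
                if u.direction == ">=" and u.cut_index == t)


def downward_union(table: DecisionTable, cut_value) -> ClassUnion:
    t = table.decision.domain.index(cut_value)
    return next(u for u in class_unions(table)
                if u.direction == "<=" and u.cut_index == t)
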