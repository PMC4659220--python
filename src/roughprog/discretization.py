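"""Raw-to-categorical mapping of clinical attributes.

Severity scoring systems of the APACHE III family map each physiologic
variable to an integer score that rises monotonically with risk of death:
a normal pulse of 50-99 bpm scores 0 while both the elevated 100-109 bpm
and the depressed 40-49 bpm bands score 5.  A scheme here is therefore a
list of half-open/closed intervals per attribute, where several disjoint
intervals may share one output score (U-shaped risk), and the output
categories carry an explicit preference order on the risk scale.  Applying
a scheme turns raw numeric columns into ordered gain criteria, ready for
the dominance-based machinery.

Full APACHE III tables are not shipped; beyond the verified pulse fragment
and the coma-score / blood-gas / hospital-day categorizations below,
schemes come from user configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .decision_table import AttributeSpec, DecisionTable
from .errors import SchemaError, UncoveredValueError

INF = math.inf


@dataclass(frozen=True)
class Bin:
    """One raw-value interval mapped to an output category.

    Closure is explicit per endpoint because clinical tables mix
    conventions: coma-score bins are right-closed "(a, b]" while the
    blood-gas bins are left-closed "[a, b)".
    """

    lo: float
    hi: float
    score: object
    lo_closed: bool = False
    hi_closed: bool = True

    def contains(self, value: float) -> bool:
        if value < self.lo or (value == self.lo and not self.lo_closed):
            return False
        if value > self.hi or (value == self.hi and not self.hi_closed):
            return False
        return True


@dataclass(frozen=True)
class AttributeBins:
    """All bins for one attribute plus the ordered output categories.

    ``categories`` are listed worst-outcome-last: the order is the
    preference order of the resulting gain criterion (higher category =
    higher risk score = more indicative of the positive outcome).
    """

    attribute: str
    bins: tuple
    categories: tuple

    def __post_init__(self):
        for b in self.bins:
            if b.score not in self.categories:
                raise SchemaError(
                    f"{self.attribute!r}: bin score {b.score!r} missing from "
                    f"declared categories"
                )

    def map_value(self, obj: str, value: float):
        for b in self.bins:
            if b.contains(value):
                return b.score
        raise UncoveredValueError(
            f"object {obj!r}: value {value!r} of attribute "
            f"{self.attribute!r} falls in no bin"
        )


@dataclass(frozen=True)
class DiscretizationScheme:
    per_attribute: Mapping[str, AttributeBins]

    def __post_init__(self):
        object.__setattr__(self, "per_attribute", dict(self.per_attribute))

    def attributes(self) -> tuple:
        return tuple(self.per_attribute)

    def merged_with(self, other: "DiscretizationScheme") -> "DiscretizationScheme":
        combined = dict(self.per_attribute)
        combined.update(other.per_attribute)
        return DiscretizationScheme(combined)


def builtin_scheme() -> DiscretizationScheme:
    """Verified default bins: coma score, blood gasses, hospital day, pulse.

    The coma-score (``scoma``) and hospital-day (``hday``) bins are
    right-closed, the blood-gas ratio (``pafi``) bins left-closed.  The
    pulse fragment covers only the published 40-109 bpm bands; remaining
    severity-score tables are user-supplied configuration.
    """
    return DiscretizationScheme({
        "scoma": AttributeBins(
            "scoma",
            bins=(
                Bin(-INF, 9, "Minor", lo_closed=False, hi_closed=True),
                Bin(9, 44, "Moderate", lo_closed=False, hi_closed=True),
                Bin(44, INF, "Severe", lo_closed=False, hi_closed=False),
            ),
            categories=("Minor", "Moderate", "Severe"),
        ),
        "pafi": AttributeBins(
            "pafi",
            bins=(
                Bin(0, 200, "ARDS", lo_closed=True, hi_closed=False),
                Bin(200, 300, "Severe defect", lo_closed=True, hi_closed=False),
                Bin(300, INF, "Normal", lo_closed=True, hi_closed=False),
            ),
            # risk rises as the ratio falls
            categories=("Normal", "Severe defect", "ARDS"),
        ),
        "hday": AttributeBins(
            "hday",
            bins=(
                Bin(-INF, 44, "Short", lo_closed=False, hi_closed=True),
                Bin(44, INF, "Long", lo_closed=False, hi_closed=True),
            ),
            categories=("Short", "Long"),
        ),
        "pulse": AttributeBins(
            "pulse",
            bins=(
                Bin(40, 50, 5, lo_closed=True, hi_closed=False),
                Bin(50, 100, 0, lo_closed=True, hi_closed=False),
                Bin(100, 110, 5, lo_closed=True, hi_closed=False),
            ),
            categories=(0, 5),
        ),
    })


def apply_scheme(raw_table: DecisionTable,
                 scheme: DiscretizationScheme) -> DecisionTable:
    """Replace each covered numeric attribute by its ordered category.

    Covered attributes become gain criteria whose domain is the scheme's
    category order; attributes absent from the scheme pass through
    unchanged, so re-applying a scheme to an already-discretized table is
    a no-op on the untouched columns.
    """
    new_schema = []
    for spec in raw_table.schema:
        if spec.name in scheme.per_attribute:
            ab = scheme.per_attribute[spec.name]
            new_schema.append(AttributeSpec(
                name=spec.name, role="gain_criterion", domain=ab.categories,
            ))
        else:
            new_schema.append(spec)
    values = {}
    for o in raw_table.objects:
        row = raw_table.row(o)
        for name, ab in scheme.per_attribute.items():
            if name in row:
                v = row[name]
                if not isinstance(v, (int, float)):
                    raise SchemaError(
                        f"attribute {name!r} is not numeric in the raw table"
                    )
                row[name] = ab.map_value(o, float(v))
        values[o] = row
    return DecisionTable(raw_table.objects, new_schema, values)


# -- scheme config I/O ---------------------------------------------------

def _endpoint(v):
    if v in (None, "inf", "+inf"):
        return INF
    if v == "-inf":
        return -INF
    return float(v)


def scheme_from_dicts(config: Mapping) -> DiscretizationScheme:
    """Build a scheme from config: attribute -> {categories, bins:[...]}.

    Each bin entry carries ``lo``, ``hi`` (numbers or "-inf"/"inf"),
    ``lo_closed``, ``hi_closed`` and ``score``.
    """
    per = {}
    for attr, entry in config.items():
        bins = tuple(
            Bin(
                lo=_endpoint(b.get("lo", "-inf")),
                hi=_endpoint(b.get("hi", "inf")),
                score=b["score"],
                lo_closed=bool(b.get("lo_closed", False)),
                hi_closed=bool(b.get("hi_closed", True)),
            )
            for b in entry["bins"]
        )
        per[attr] = AttributeBins(attr, bins, tuple(entry["categories"]))
    return DiscretizationScheme(per)


def load_scheme(path) -> DiscretizationScheme:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return scheme_from_dicts(data)
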