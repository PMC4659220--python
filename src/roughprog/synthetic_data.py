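"""Fixtures and generators for testing the rough-set pipeline.

Three sources of data:

* the seven-patient coronary-disease table used throughout the package
  documentation (a tiny fully-worked example with known approximations);
* a generator of SUPPORT-like cohorts: 13 numeric physiology/demographic
  attributes drawn inside the ranges observed in the SUPPORT study of
  seriously ill hospitalized adults, a categorical diagnosis group and
  cancer status, and a binary six-month death outcome at a configurable
  prevalence (default 47%), with an optional controlled rate of
  conflicting duplicate profiles (inconsistency);
* planted-rule tables whose decision is exactly the disjunction of known
  monotone rules, for rule-recovery testing.

The SUPPORT-like generator emulates the schema, value ranges, prevalence
and monotone risk structure of the real cohort, not its joint
distribution; its discretization bins are synthetic stand-ins for the
unpublished clinical score tables (only the coma-score, blood-gas,
hospital-day and pulse fragments in :mod:`roughprog.discretization` are
verified defaults).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .decision_table import AttributeSpec, DecisionTable
from .discretization import AttributeBins, Bin, DiscretizationScheme, INF, apply_scheme, builtin_scheme
from .errors import ContradictoryRulesError, RoughprogError


# -- the 7-patient worked example ----------------------------------------

def table1_schema() -> list:
    lmh = ("L", "M", "H")
    yn = ("No", "Yes")
    return [
        AttributeSpec("Gender", "attribute", ("F", "M")),
        AttributeSpec("Age", "gain_criterion", lmh),
        AttributeSpec("SystBP", "gain_criterion", lmh),
        AttributeSpec("HDL", "gain_criterion", lmh),
        AttributeSpec("Diabetic", "gain_criterion", yn),
        AttributeSpec("Smoker", "gain_criterion", yn),
        AttributeSpec("Coronary disease", "decision", yn),
    ]


_TABLE1_ROWS = {
    "x1": ("F", "H", "M", "L", "No", "No", "No"),
    "x2": ("M", "L", "L", "L", "No", "Yes", "No"),
    "x3": ("F", "M", "M", "H", "No", "No", "No"),
    "x4": ("F", "M", "M", "H", "No", "No", "Yes"),
    "x5": ("M", "H", "H", "L", "Yes", "Yes", "Yes"),
    "x6": ("M", "H", "H", "L", "Yes", "Yes", "Yes"),
    "x7": ("F", "M", "M", "H", "No", "No", "Yes"),
}


def table1_fixture() -> DecisionTable:
    """Seven patients, six prognostic factors, binary coronary-disease
    outcome; Gender is a plain attribute, the rest are gain criteria."""
    schema = table1_schema()
    names = [a.name for a in schema]
    values = {o: dict(zip(names, row)) for o, row in _TABLE1_ROWS.items()}
    return DecisionTable(list(_TABLE1_ROWS), schema, values)


# -- SUPPORT-like cohorts ------------------------------------------------

# (range lo, range hi, per-severity-level sampling interval)
# Levels are ordered by risk; raw values are drawn uniformly inside the
# interval of the drawn level, so discretization recovers the level.
_NUMERIC_LEVELS = {
    "age":    ((18, 101),   [(18, 45), (45, 65), (65, 101)]),
    "alb":    ((0.4, 29),   [(3.5, 5.5), (2.5, 3.5), (0.4, 2.5)]),
    "bili":   ((0.1, 63),   [(0.1, 2.0), (2.0, 8.0), (8.0, 63)]),
    "crea":   ((0.09, 21.5), [(0.09, 1.5), (1.5, 3.0), (3.0, 21.5)]),
    "hday":   ((1, 148),    [(1, 44), (44.5, 148)]),
    "hrt":    ((0, 300),    [(50, 99), (100, 124), (125, 300)]),
    "meanbp": ((0, 195),    [(70, 109), (110, 129), (130, 195)]),
    "pafi":   ((12, 890.4), [(300, 890), (200, 299), (12, 199)]),
    "resp":   ((0, 90),     [(12, 24), (25, 34), (35, 90)]),
    "scoma":  ((0, 100),    [(0, 9), (10, 44), (45, 100)]),
    "sod":    ((110, 181),  [(135, 147), (148, 154), (155, 181)]),
    "temp":   ((31.7, 41.7), [(36, 38.4), (38.5, 39.9), (40, 41.7)]),
    "wblc":   ((0.05, 200), [(3, 10.9), (11, 24.9), (25, 200)]),
}

_DZGROUPS = (
    ("ARF/MOSF w. sepsis", 0.3859, 0.5),
    ("CHF", 0.1523, -1.0),
    ("Cirrhosis", 0.0556, 0.5),
    ("Colon cancer", 0.0562, 0.5),
    ("Coma", 0.0654, 2.0),
    ("COPD", 0.1060, -1.0),
    ("Lung cancer", 0.0997, 1.5),
    ("MOSF w. malignancy", 0.0781, 2.0),
)

_CA = (("No", 0.6584, 0.0), ("Yes", 0.1375, 0.5), ("Metastasis", 0.2040, 1.5))


def support_like_scheme() -> DiscretizationScheme:
    """Discretization used by the generator: the verified built-in
    fragments plus synthetic three-level severity bins for the remaining
    numeric attributes (these stand in for unpublished score tables)."""
    def three(attr, cut1, cut2, labels=(0, 1, 2)):
        return AttributeBins(attr, bins=(
            Bin(-INF, cut1, labels[0], hi_closed=False),
            Bin(cut1, cut2, labels[1], lo_closed=True, hi_closed=False),
            Bin(cut2, INF, labels[2], lo_closed=True, hi_closed=True),
        ), categories=tuple(labels))

    synth = DiscretizationScheme({
        "age": three("age", 45, 65),
        "alb": AttributeBins("alb", bins=(
            Bin(3.5, INF, 0, lo_closed=True, hi_closed=True),
            Bin(2.5, 3.5, 1, lo_closed=True, hi_closed=False),
            Bin(-INF, 2.5, 2, hi_closed=False),
        ), categories=(0, 1, 2)),
        "bili": three("bili", 2.0, 8.0),
        "crea": three("crea", 1.5, 3.0),
        "hrt": three("hrt", 100, 125),
        "meanbp": three("meanbp", 110, 130),
        "resp": three("resp", 25, 35),
        "sod": three("sod", 148, 155),
        "temp": three("temp", 38.5, 40),
        "wblc": three("wblc", 11, 25),
    })
    keep = {k: v for k, v in builtin_scheme().per_attribute.items()
            if k in ("scoma", "pafi", "hday")}
    return synth.merged_with(DiscretizationScheme(keep))


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for the SUPPORT-like and planted-rule generators.

    ``signal`` maps attribute names to latent-risk weights (default 1 for
    every numeric severity score); ``inconsistency_rate`` is the fraction
    of objects drawn into conflicting duplicate-profile pairs.
    """

    n: int = 500
    seed: int = 0
    prevalence: float = 0.47
    inconsistency_rate: float = 0.0
    signal: Mapping[str, float] = field(default_factory=dict)
    n_criteria: int = 4
    n_levels: int = 4
    planted_rules: tuple = ()

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise RoughprogError("prevalence must lie in (0,1)")
        if not 0 <= self.inconsistency_rate <= 1:
            raise RoughprogError("inconsistency rate must lie in [0,1]")


def support_like_schema() -> list:
    schema = [AttributeSpec(a, "attribute", None) for a in _NUMERIC_LEVELS]
    schema.append(AttributeSpec("dzgroup", "attribute",
                                tuple(g for g, _, _ in _DZGROUPS)))
    schema.append(AttributeSpec("ca", "gain_criterion",
                                tuple(c for c, _, _ in _CA)))
    schema.append(AttributeSpec("d.6months", "decision", ("No", "Yes")))
    return schema


def generate_support_like(config: GeneratorConfig):
    """Seeded SUPPORT-like cohort; returns (raw table, discretized table).

    Each patient carries a latent frailty; per-attribute severity levels
    are drawn with frailty-shifted probabilities and raw values uniformly
    inside the drawn level's interval.  The six-month death outcome is a
    deterministic threshold on the weighted sum of severity levels plus
    diagnosis-group and cancer offsets, cut at the (1 - prevalence)
    quantile, so the marginal prevalence tracks the target.  The optional
    inconsistency injection overwrites condition profiles of sampled
    recipients with a donor's profile and the opposite decision, creating
    boundary regions of controlled size.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    frailty = rng.normal(size=n)

    levels: dict = {}
    raw: dict = {}
    for attr, (_, intervals) in _NUMERIC_LEVELS.items():
        k = len(intervals)
        # ordered draw: frailty shifts mass toward higher severity levels
        cuts = np.linspace(-0.8, 0.8, k - 1)
        noise = rng.normal(scale=0.9, size=n)
        lev = (0.7 * frailty + noise)[:, None] > cuts[None, :]
        levels[attr] = lev.sum(axis=1)
        lows = np.array([intervals[i][0] for i in levels[attr]])
        highs = np.array([intervals[i][1] for i in levels[attr]])
        raw[attr] = np.round(lows + rng.random(n) * (highs - lows), 2)

    # realized severity levels: re-derive from the rounded raw values so
    # the outcome is an exact function of the discretized profile
    scheme = support_like_scheme()
    for attr in _NUMERIC_LEVELS:
        ab = scheme.per_attribute[attr]
        cats = ab.categories
        levels[attr] = np.array(
            [cats.index(ab.map_value("gen", float(v))) for v in raw[attr]]
        )

    dz_names = [g for g, _, _ in _DZGROUPS]
    dz_p = np.array([p for _, p, _ in _DZGROUPS])
    dz = rng.choice(len(dz_names), size=n, p=dz_p / dz_p.sum())
    ca_names = [c for c, _, _ in _CA]
    ca_p = np.array([p for _, p, _ in _CA])
    ca = rng.choice(len(ca_names), size=n, p=ca_p / ca_p.sum())

    weights = {a: config.signal.get(a, 1.0) for a in _NUMERIC_LEVELS}
    risk = sum(weights[a] * levels[a] for a in _NUMERIC_LEVELS).astype(float)
    risk += np.array([_DZGROUPS[i][2] for i in dz])
    risk += np.array([_CA[i][2] for i in ca])
    # deterministic profile-hash jitter splits risk ties at the quantile
    # cut (identical profiles share a jitter, so consistency is intact)
    profiles = [
        tuple(int(levels[a][i]) for a in _NUMERIC_LEVELS) + (int(dz[i]), int(ca[i]))
        for i in range(n)
    ]
    jitter = np.array([zlib.crc32(repr(p).encode()) / 2 ** 32 for p in profiles])
    risk = risk + 1e-6 * jitter
    cut = np.quantile(risk, 1 - config.prevalence)
    decision = np.where(risk >= cut, "Yes", "No")

    schema = support_like_schema()
    objects = [str(i + 1) for i in range(n)]
    values = {}
    for i, o in enumerate(objects):
        row = {a: float(raw[a][i]) for a in _NUMERIC_LEVELS}
        row["dzgroup"] = dz_names[dz[i]]
        row["ca"] = ca_names[ca[i]]
        row["d.6months"] = str(decision[i])
        values[o] = row

    n_pairs = int(round(config.inconsistency_rate * n / 2))
    if n_pairs:
        picks = rng.choice(n, size=2 * n_pairs, replace=False)
        cond_names = [a.name for a in schema if a.role != "decision"]
        for d_i, r_i in zip(picks[:n_pairs], picks[n_pairs:]):
            donor, recip = objects[d_i], objects[r_i]
            for a in cond_names:
                values[recip][a] = values[donor][a]
            values[recip]["d.6months"] = (
                "No" if values[donor]["d.6months"] == "Yes" else "Yes"
            )

    raw_table = DecisionTable(objects, schema, values)
    disc_table = apply_scheme(raw_table, scheme)
    return raw_table, disc_table


# -- planted-rule tables -------------------------------------------------

def planted_rule_fires(rule: Mapping[str, int], row: Mapping) -> bool:
    return all(row[a] >= v for a, v in rule.items())


def generate_planted_rules(config: GeneratorConfig):
    """Table whose decision is the disjunction of planted monotone rules.

    Criteria ``c1..ck`` have integer severity domains ``0..n_levels-1``;
    objects are uniform over the condition space and positive exactly when
    some planted rule (a conjunction of at-least conditions) fires.
    Returns ``(table, covers)`` where ``covers[i]`` is the ground-truth
    object set of planted rule i.
    """
    names = [f"c{i + 1}" for i in range(config.n_criteria)]
    domain = tuple(range(config.n_levels))
    for rule in config.planted_rules:
        for a, v in rule.items():
            if a not in names:
                raise ContradictoryRulesError(f"planted rule names unknown criterion {a!r}")
            if v not in domain:
                raise ContradictoryRulesError(f"planted threshold {v!r} outside domain")
    rng = np.random.default_rng(config.seed)
    draws = rng.integers(0, config.n_levels, size=(config.n, config.n_criteria))
    schema = [AttributeSpec(a, "gain_criterion", domain) for a in names]
    schema.append(AttributeSpec("outcome", "decision", ("No", "Yes")))
    objects = [str(i + 1) for i in range(config.n)]
    values = {}
    for i, o in enumerate(objects):
        row = {a: int(draws[i, j]) for j, a in enumerate(names)}
        row["outcome"] = "Yes" if any(
            planted_rule_fires(r, row) for r in config.planted_rules) else "No"
        values[o] = row
    table = DecisionTable(objects, schema, values)
    covers = [
        frozenset(o for o in objects
                  if planted_rule_fires(r, values[o]))
        for r in config.planted_rules
    ]
    return table, covers
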