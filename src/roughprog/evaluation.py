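"""Performance evaluation: ROC/AUC, Cohen's kappa, cross-validation, grids.

The classifier's positive-class score is swept over thresholds to build an
empirical ROC curve; overall discrimination is its area (equivalently the
probability a random positive outscores a random negative, ties counted
half).  The operating point reported is the threshold whose (false
positive rate, true positive rate) lies nearest the ideal corner (0, 1).
Uncovered (undefined) objects either enter with an imputed score of 0.5 or
are excluded; both policies are supported and the active one is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import score_table
from .decision_table import DecisionTable
from .errors import RoughprogError
from .rule_induction import InductionConfig, modlem_induce, vcdomlem_induce


class SingleClassError(RoughprogError):
    """ROC analysis needs at least one positive and one negative label."""


# -- elementary metrics --------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the empirical ROC curve.

    Computed as the normalized Mann-Whitney statistic (ties counted half),
    which equals trapezoidal integration of the ROC with tied scores
    collapsed to midpoints.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("labels contain a single class")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2 + 1  # midrank, 1-based
        i = j + 1
    rank_sum = ranks[labels].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def confusion_at(scores, labels, tau: float):
    """2x2 confusion counts with positive prediction iff score > tau."""
    tp = fn = fp = tn = 0
    for s, y in zip(scores, labels):
        pred = s > tau
        if y:
            tp, fn = tp + pred, fn + (not pred)
        else:
            fp, tn = fp + pred, tn + (not pred)
    return tp, fn, fp, tn


def best_operating_point(scores: Sequence[float],
                         labels: Sequence[bool]) -> tuple:
    """Threshold at the ROC point nearest (0, 1), with its sensitivity and
    specificity; ties resolved toward the smaller threshold."""
    scores = list(map(float, scores))
    labels = list(map(bool, labels))
    if not any(labels) or all(labels):
        raise SingleClassError("labels contain a single class")
    best = None
    for tau in sorted(set(scores)):
        tp, fn, fp, tn = confusion_at(scores, labels, tau)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        dist = ((1 - spec) ** 2 + (1 - sens) ** 2) ** 0.5
        if best is None or dist < best[0] - 1e-15:
            best = (dist, tau, sens, spec)
    _, tau, sens, spec = best
    return tau, sens, spec


def cohens_kappa(tp: int, fn: int, fp: int, tn: int) -> float:
    """Chance-corrected agreement from a 2x2 confusion table."""
    n = tp + fn + fp + tn
    if n == 0:
        raise RoughprogError("empty confusion table")
    p_o = (tp + tn) / n
    p_e = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / (n * n)
    if p_e == 1:
        import warnings
        warnings.warn("degenerate marginals: chance agreement is 1; kappa set to 0")
        return 0.0
    return (p_o - p_e) / (1 - p_e)


# -- cross-validation ----------------------------------------------------

@dataclass(frozen=True)
class FoldResult:
    fold: int
    auc: float
    kappa: float
    sensitivity: float
    specificity: float
    threshold_star: float
    coverage: float
    rules_fired: tuple  # (min, median, max) over test objects
    n_rules: int
    n_test: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold metrics with their means and standard deviations."""

    method: str
    level: float
    k: int
    seed: int
    undefined_policy: str
    folds: tuple

    def _series(self, attr):
        return np.array([getattr(f, attr) for f in self.folds], dtype=float)

    def mean(self, attr: str) -> float:
        return float(self._series(attr).mean())

    def sd(self, attr: str) -> float:
        return float(self._series(attr).std(ddof=1)) if len(self.folds) > 1 else 0.0

    @property
    def auc(self):
        return self.mean("auc")

    @property
    def kappa(self):
        return self.mean("kappa")

    @property
    def sensitivity(self):
        return self.mean("sensitivity")

    @property
    def specificity(self):
        return self.mean("specificity")

    @property
    def threshold_star(self):
        return self.mean("threshold_star")

    @property
    def coverage(self):
        return self.mean("coverage")

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"fold": f.fold, "auc": f.auc, "kappa": f.kappa,
             "sensitivity": f.sensitivity, "specificity": f.specificity,
             "threshold": f.threshold_star, "coverage": f.coverage,
             "n_rules": f.n_rules, "n_test": f.n_test}
            for f in self.folds
        ]
        return pd.DataFrame(rows)


def stratified_folds(table: DecisionTable, k: int, seed: int) -> list:
    """Seeded class-stratified partition of the objects into k folds."""
    if k < 2:
        raise RoughprogError("need at least two folds")
    rng = np.random.default_rng(seed)
    dname = table.decision.name
    by_class: dict = {}
    for o in table.objects:
        by_class.setdefault(table.value(o, dname), []).append(o)
    folds = [[] for _ in range(k)]
    offset = 0
    for v in table.decision.domain:
        group = by_class.get(v, [])
        rng.shuffle(group)
        for i, o in enumerate(group):
            folds[(i + offset) % k].append(o)
        offset += len(group)
    return [tuple(f) for f in folds]


def subset_table(table: DecisionTable, objects) -> DecisionTable:
    keep = set(objects)
    ordered = [o for o in table.objects if o in keep]
    return DecisionTable(ordered, table.schema,
                         {o: table.row(o) for o in ordered})


def _induce(table, method, config):
    if method == "modlem":
        return modlem_induce(table, config)
    if method == "vcdomlem":
        return vcdomlem_induce(table, config)
    raise RoughprogError(f"unknown induction method {method!r}")


def make_config(method: str, level: float) -> InductionConfig:
    measure = "entropy" if method == "modlem" else "mu"
    return InductionConfig(consistency_threshold=level, condition_measure=measure)


def cross_validate(table: DecisionTable, method: str,
                   config: InductionConfig, k: int = 5, seed: int = 0,
                   positive_class=None,
                   undefined_policy: str = "impute") -> EvaluationReport:
    """Stratified k-fold evaluation of an induced rule-voting classifier.

    Per fold: rules are induced on the training part, test objects are
    scored, and AUC, Cohen's kappa plus sensitivity/specificity at the
    ROC-optimal threshold, coverage, and rules-fired statistics are
    recorded.  ``undefined_policy`` controls uncovered test objects:
    ``impute`` assigns them score 0.5, ``exclude`` drops them from the
    metrics (they always count against coverage).
    """
    if undefined_policy not in ("impute", "exclude"):
        raise RoughprogError(f"unknown undefined policy {undefined_policy!r}")
    positive = positive_class if positive_class is not None else table.decision.domain[-1]
    dname = table.decision.name
    folds = stratified_folds(table, k, seed)
    results = []
    for i, test_ids in enumerate(folds):
        train_ids = [o for o in table.objects if o not in set(test_ids)]
        train = subset_table(table, train_ids)
        test = subset_table(table, test_ids)
        rules = _induce(train, method, config)
        class_scores = score_table(rules, test, positive)
        truth = [test.value(cs.object, dname) == positive for cs in class_scores]
        covered = [cs.covered for cs in class_scores]
        coverage = sum(covered) / len(covered)
        if undefined_policy == "impute":
            s = [cs.score[positive] if cs.covered else 0.5 for cs in class_scores]
            y = truth
        else:
            s = [cs.score[positive] for cs in class_scores if cs.covered]
            y = [t for t, c in zip(truth, covered) if c]
        if not any(y) or all(y):
            raise SingleClassError(f"fold {i}: test labels are single-class")
        auc = roc_auc(s, y)
        tau, sens, spec = best_operating_point(s, y)
        kappa = cohens_kappa(*confusion_at(s, y, tau))
        fired = [len(cs.fired_rules) for cs in class_scores]
        results.append(FoldResult(
            fold=i, auc=auc, kappa=kappa, sensitivity=sens, specificity=spec,
            threshold_star=tau, coverage=coverage,
            rules_fired=(min(fired), float(median(fired)), max(fired)),
            n_rules=len(rules), n_test=len(test_ids),
        ))
    return EvaluationReport(
        method=method, level=config.consistency_threshold, k=k, seed=seed,
        undefined_policy=undefined_policy, folds=tuple(results),
    )


def grid_search(table: DecisionTable, method: str, levels: Sequence[float],
                k: int = 5, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Cross-validate at each consistency level; one row per level with
    mean AUC and mean coverage (plus their standard deviations)."""
    rows = []
    for level in levels:
        report = cross_validate(table, method, make_config(method, level),
                                k=k, seed=seed, **kwargs)
        rows.append({
            "level": level, "auc": report.auc, "coverage": report.coverage,
            "auc_sd": report.sd("auc"), "coverage_sd": report.sd("coverage"),
        })
    return pd.DataFrame(rows, columns=["level", "auc", "coverage",
                                       "auc_sd", "coverage_sd"])
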