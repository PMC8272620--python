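"""Hyperparameter exploration of the rough-set rule pipeline.

One experimental run: subsample surplus zero-decile cases, discretize the
outcome deciles into A/B/C with the (d1, d2) ranges, split 85:15 (stratified
on the outcome label), fit attribute cuts on the training part only, compute
the reduct, induce rules, apply the model-level rule filtration, and score the
held-out cases.  Each hyperparameter configuration is repeated 10 times with
independent filtration and splits, and the grid search returns the
configuration maximizing mean accuracy; rejected models score zero, which
makes filtration costly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import rough_core as rc
from .wavelet_features import DECISION, debias_subsample, discretize_outcome, \
    validate_outcome_range

__all__ = [
    "HyperParams",
    "RunResult",
    "CrossValStats",
    "GridSearchResult",
    "Metrics",
    "enumerate_outcome_ranges",
    "run_once",
    "cross_validate",
    "grid_search",
    "compute_metrics",
    "train_model",
]

PATTERNS = ("periodic-like", "intermediate", "normal")

_DISCRETIZE_CODES = {"q": "unsup_quantiles", "i": "unsup_intervals",
                     "n": "global_discernibility"}
_REDUCT_CODES = {"d": "daar", "g": "greedy"}


@dataclass(frozen=True, order=True)
class HyperParams:
    """One grid cell: pattern, cut count, methods and outcome ranges.

    ``discretize`` accepts the short codes q/i/n; ``reduct`` accepts d/g.
    """

    pattern: str = "normal"
    c: int = 2
    discretize: str = "unsup_quantiles"
    reduct: str = "greedy"
    rule: str = "LEM2"
    d1: int = 3
    d2: int = 6

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.c not in (1, 2, 3):
            raise ValueError("c must be 1, 2 or 3")
        object.__setattr__(self, "discretize",
                           _DISCRETIZE_CODES.get(self.discretize, self.discretize))
        object.__setattr__(self, "reduct",
                           _REDUCT_CODES.get(self.reduct, self.reduct))
        object.__setattr__(self, "rule", self.rule.upper())
        if self.discretize not in rc.DISCRETIZE_METHODS:
            raise ValueError(f"unknown discretization {self.discretize!r}")
        if self.reduct not in rc.REDUCT_METHODS:
            raise ValueError(f"unknown reduct method {self.reduct!r}")
        if self.rule not in rc.RULE_METHODS:
            raise ValueError(f"unknown rule method {self.rule!r}")
        validate_outcome_range(self.d1, self.d2)


class Metrics(NamedTuple):
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float


@dataclass(frozen=True)
class RunResult:
    """Held-out performance of one train/test run; rejected models score zero."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    n_rules: int
    rejected: bool = False
    reject_reason: str | None = None


@dataclass(frozen=True)
class CrossValStats:
    """Per-repeat results with boxplot-ready accuracy summaries."""

    results: tuple
    accuracy_summary: dict
    n_rules_median: float
    mean_accuracy: float
    mean_f1: float


@dataclass(frozen=True)
class GridSearchResult:
    best: HyperParams | None
    best_stats: CrossValStats | None
    results_long: pd.DataFrame
    accuracy_matrix: pd.DataFrame
    f1_matrix: pd.DataFrame
    no_model: bool = False


def enumerate_outcome_ranges() -> list[tuple[int, int]]:
    """All valid (d1, d2): d1 in 1..5, width 2..5, d2 < 9, lexicographic."""
    out = []
    for d1 in range(1, 6):
        for width in range(2, 6):
            d2 = d1 + width
            if d2 < 9:
                out.append((d1, d2))
    return out


def compute_metrics(y_true: Sequence, y_pred: Sequence,
                    classes: Sequence = ("A", "B", "C")) -> Metrics:
    """Accuracy and macro precision/recall/F1 over the fixed class set.

    Classes absent from both truth and prediction contribute zero terms to the
    macro averages.  Computed directly from the confusion counts so library
    implementations can serve as an independent cross-check.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if not y_true:
        raise ValueError("empty label vectors")
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    precs, recs, f1s = [], [], []
    for cls in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    k = len(list(classes))
    return Metrics(acc, sum(precs) / k, sum(recs) / k, sum(f1s) / k)


def _rejected_result(rules, reason: str) -> RunResult:
    return RunResult(0.0, 0.0, 0.0, 0.0, n_rules=len(rules), rejected=True,
                     reject_reason=reason)


def train_model(train: pd.DataFrame, hp: HyperParams, seed: int | None = None):
    """Fit cuts, reduct and rules on a discretized-outcome training table.

    Returns ``(RuleSet | None, FilterResult)``; a ``None`` rule set means the
    model was rejected by filtration.
    """
    cuts, train_disc = rc.discretize_attributes(train, hp.discretize, hp.c)
    reduct = rc.compute_reduct(train_disc, hp.reduct, seed=seed)
    rules = rc.induce_rules(train_disc[reduct + [DECISION]], hp.rule)
    filt = rc.filter_rules(rules)
    if not filt.accepted:
        return None, filt
    fallback = rc._majority(train[DECISION].tolist())
    ruleset = rc.RuleSet(rules=list(filt.rules), fallback=fallback, cuts=cuts,
                         classes=tuple(sorted(set(train[DECISION]), key=str)))
    return ruleset, filt


def run_once(table: pd.DataFrame, hp: HyperParams, seed: int) -> RunResult:
    """One filtration + split + train + filter + test run; deterministic."""
    ss = np.random.SeedSequence(seed)
    s_filter, s_split, s_reduct = (int(x) for x in ss.generate_state(3))
    t = debias_subsample(table, s_filter).reset_index(drop=True)
    labels = t[DECISION].map(lambda d: discretize_outcome(int(d), hp.d1, hp.d2))
    t = t.drop(columns=[DECISION]).assign(**{DECISION: labels})
    try:
        train, test = train_test_split(
            t, test_size=0.15, stratify=t[DECISION],
            random_state=s_split % (2 ** 32 - 1))
    except ValueError:  # a class too small to stratify
        train, test = train_test_split(
            t, test_size=0.15, random_state=s_split % (2 ** 32 - 1))
    train = train.reset_index(drop=True)
    test = test.reset_index(drop=True)
    ruleset, filt = train_model(train, hp, seed=s_reduct)
    if ruleset is None:
        return _rejected_result(filt.rules, filt.reason)
    preds = rc.classify_table(ruleset, test)
    m = compute_metrics(test[DECISION].tolist(), preds)
    return RunResult(m.accuracy, m.precision_macro, m.recall_macro,
                     m.f1_macro, n_rules=len(ruleset.rules))


def _five_number(values: Sequence[float]) -> dict:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max())}


def cross_validate(table: pd.DataFrame, hp: HyperParams, repeats: int = 10,
                   seed: int = 0) -> CrossValStats:
    """Repeat ``run_once`` with independent filtration/splits and summarize."""
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    children = np.random.SeedSequence(seed).spawn(repeats)
    results = tuple(run_once(table, hp, int(c.generate_state(1)[0]))
                    for c in children)
    accs = [r.accuracy for r in results]
    return CrossValStats(
        results=results,
        accuracy_summary=_five_number(accs),
        n_rules_median=float(np.median([r.n_rules for r in results])),
        mean_accuracy=float(np.mean(accs)),
        mean_f1=float(np.mean([r.f1_macro for r in results])),
    )


def grid_search(table: pd.DataFrame, grid: Iterable[HyperParams],
                seed: int = 0, repeats: int = 10) -> GridSearchResult:
    """Evaluate every configuration and return the mean-accuracy argmax.

    Ties go to the configuration with fewer median rules, then lexicographic
    hyperparameter order.  The returned matrices hold, per (d1, d2) cell, the
    best configuration's mean accuracy / mean macro-F1 (Table 5/6-shaped).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    stats: dict[HyperParams, CrossValStats] = {}
    for hp in grid:
        cv = cross_validate(table, hp, repeats=repeats, seed=seed)
        stats[hp] = cv
        for i, r in enumerate(cv.results):
            rows.append({
                "pattern": hp.pattern, "d1": hp.d1, "d2": hp.d2, "c": hp.c,
                "discretize": hp.discretize, "reduct": hp.reduct,
                "rule": hp.rule, "repeat": i, "accuracy": r.accuracy,
                "precision": r.precision_macro, "recall": r.recall_macro,
                "f1": r.f1_macro, "n_rules": r.n_rules, "rejected": r.rejected,
            })
    results_long = pd.DataFrame(rows)
    ranked = sorted(
        grid, key=lambda hp: (-stats[hp].mean_accuracy,
                              stats[hp].n_rules_median, hp))
    best = ranked[0]
    no_model = all(r.rejected for hp in grid for r in stats[hp].results)

    cells_acc: dict[tuple[int, int], float] = {}
    cells_f1: dict[tuple[int, int], float] = {}
    for hp in grid:
        key = (hp.d1, hp.d2)
        if key not in cells_acc or stats[hp].mean_accuracy > cells_acc[key]:
            cells_acc[key] = stats[hp].mean_accuracy
            cells_f1[key] = stats[hp].mean_f1

    def _pivot(cells):
        d1s = sorted({d1 for d1, _ in cells})
        d2s = sorted({d2 for _, d2 in cells})
        mat = pd.DataFrame(index=d1s, columns=d2s, dtype=float)
        for (d1, d2), v in cells.items():
            mat.loc[d1, d2] = v
        mat.index.name = "d1"
        mat.columns.name = "d2"
        return mat

    return GridSearchResult(
        best=None if no_model else best,
        best_stats=None if no_model else stats[best],
        results_long=results_long,
        accuracy_matrix=_pivot(cells_acc),
        f1_matrix=_pivot(cells_f1),
        no_model=no_model,
    )
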