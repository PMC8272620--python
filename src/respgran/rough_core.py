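"""From-scratch rough-set machinery.

A decision table is a pandas DataFrame whose condition attributes are the
non-decision columns and whose ``decision`` column carries the class label.
Objects are addressed by row position (0..n−1).

Implemented here, without delegating to any rough-set library:

* indiscernibility partitions (objects equal on every attribute of a subset
  share a block) and lower/upper approximations of decision classes with the
  approximation accuracy |lower| / |upper|;
* attribute discretization into left-closed, right-open intervals — equal
  width, equal frequency, or supervised global-discernibility cuts chosen
  greedily to maximize newly discerned pairs of objects with different
  decisions;
* reducts: a greedy positive-region heuristic with backward elimination, and a
  DAAR-style variant that accepts an attribute only when its gain beats a
  permutation probe in at least (1−α) of the probes — attributes whose gain is
  indistinguishable from chance are rejected, so DAAR may return an
  approximate reduct;
* rule induction: LEM2 local covering, CN2 beam search, AQ star generation,
  and one-rule-per-indiscernibility-class induction; every rule carries its
  support and Laplace confidence (n_correct + 1) / (n_matched + k);
* model-level rule filtration (reject < 2 rules or mean Laplace confidence
  < 0.6; cap at 100 rules) and specificity-first classification.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DECISION",
    "EquivalencePartition",
    "Approximation",
    "CutSet",
    "DecisionRule",
    "RuleSet",
    "FilterResult",
    "compute_partition",
    "approximate_class",
    "positive_region",
    "discretize_attributes",
    "compute_reduct",
    "induce_rules",
    "laplace_confidence",
    "filter_rules",
    "classify",
    "classify_table",
]

DECISION = "decision"

DISCRETIZE_METHODS = ("global_discernibility", "unsup_intervals", "unsup_quantiles")
REDUCT_METHODS = ("greedy", "daar")
RULE_METHODS = ("LEM2", "CN2", "AQ", "IND")


# ---------------------------------------------------------------------------
# partitions and approximations

@dataclass(frozen=True)
class EquivalencePartition:
    """Blocks of mutually indiscernible objects for an attribute subset."""

    attrs: tuple
    blocks: tuple  # tuple[frozenset[int], ...]
    n_objects: int


@dataclass(frozen=True)
class Approximation:
    """Lower/upper approximation of a decision class and its accuracy."""

    class_objects: frozenset
    lower: frozenset
    upper: frozenset
    accuracy: float


def _condition_attrs(table: pd.DataFrame, decision: str) -> list[str]:
    return [c for c in table.columns if c != decision]


def compute_partition(table: pd.DataFrame, attrs: Iterable[str],
                      decision: str = DECISION) -> EquivalencePartition:
    """Partition the objects into maximal sets identical on all ``attrs``.

    An empty attribute set discerns nothing: all objects share one block.
    """
    attrs = tuple(attrs)
    unknown = [a for a in attrs if a not in table.columns]
    if unknown:
        raise ValueError(f"unknown attributes: {unknown}")
    n = len(table)
    if not attrs:
        blocks = (frozenset(range(n)),) if n else ()
        return EquivalencePartition(attrs, blocks, n)
    groups: dict[tuple, list[int]] = {}
    cols = [table[a].tolist() for a in attrs]
    for i, key in enumerate(zip(*cols)):
        groups.setdefault(key, []).append(i)
    blocks = tuple(frozenset(v) for v in groups.values())
    return EquivalencePartition(attrs, blocks, n)


def approximate_class(partition: EquivalencePartition,
                      class_objects: Iterable[int]) -> Approximation:
    """Lower/upper approximation of a class under the given partition.

    The empty class is vacuously crisp: both approximations are empty and the
    accuracy is defined as 1 (the 0/0 case of |lower|/|upper|).
    """
    cls = frozenset(class_objects)
    universe = frozenset(range(partition.n_objects))
    if not cls <= universe:
        raise ValueError("class_objects must be a subset of the universe")
    lower: set[int] = set()
    upper: set[int] = set()
    for b in partition.blocks:
        if b <= cls:
            lower |= b
        if b & cls:
            upper |= b
    accuracy = len(lower) / len(upper) if upper else 1.0
    return Approximation(cls, frozenset(lower), frozenset(upper), accuracy)


def positive_region(table: pd.DataFrame, attrs: Iterable[str],
                    decision: str = DECISION) -> frozenset:
    """Objects whose indiscernibility block is decision-pure."""
    part = compute_partition(table, attrs, decision)
    dec = table[decision].to_numpy()
    pos: set[int] = set()
    for b in part.blocks:
        it = iter(b)
        first = dec[next(it)]
        if all(dec[i] == first for i in it):
            pos |= b
    return frozenset(pos)


# ---------------------------------------------------------------------------
# attribute discretization

def _fmt(v: float) -> str:
    return format(float(v), ".6g")


def _interval_labels(cuts: Sequence[float]) -> list[str]:
    if not cuts:
        return ["[-Inf,Inf]"]
    pts = ["-Inf"] + [_fmt(c) for c in cuts] + ["Inf"]
    labels = []
    for i in range(len(pts) - 1):
        close = "]" if i == len(pts) - 2 else ")"
        labels.append(f"[{pts[i]},{pts[i + 1]}{close}")
    return labels


@dataclass(frozen=True)
class CutSet:
    """Per-attribute cut points defining left-closed, right-open intervals."""

    cuts: Mapping[str, tuple[float, ...]]

    def labels(self, attr: str) -> list[str]:
        return _interval_labels(self.cuts[attr])

    def apply_column(self, attr: str, values) -> np.ndarray:
        cuts = np.asarray(self.cuts[attr], dtype=float)
        labels = np.asarray(self.labels(attr), dtype=object)
        idx = np.searchsorted(cuts, np.asarray(values, dtype=float), side="right")
        return labels[idx]

    def apply(self, table: pd.DataFrame, decision: str = DECISION) -> pd.DataFrame:
        out = table.copy()
        for attr in self.cuts:
            if attr in out.columns:
                out[attr] = self.apply_column(attr, out[attr].to_numpy())
        return out

    def to_dict(self) -> dict:
        return {a: list(c) for a, c in self.cuts.items()}


def _equal_width_cuts(values: np.ndarray, c: int) -> tuple[float, ...]:
    lo, hi = float(values.min()), float(values.max())
    return tuple(np.linspace(lo, hi, c + 2)[1:-1])


def _equal_freq_cuts(values: np.ndarray, c: int) -> tuple[float, ...]:
    qs = [i / (c + 1) for i in range(1, c + 1)]
    cuts = np.quantile(values, qs)
    return tuple(np.unique(cuts))


def _global_discernibility_cuts(table: pd.DataFrame, attrs: Sequence[str],
                                c: int, decision: str) -> dict[str, tuple[float, ...]]:
    """Greedy supervised cuts: maximize newly discerned decision-different pairs.

    Candidate cuts are midpoints between consecutive distinct sorted values of
    each attribute; cuts are added one at a time (at most ``c`` per attribute)
    while any candidate still discerns a not-yet-discerned pair of objects
    with different decisions.  O(n²) per candidate evaluation.
    """
    n = len(table)
    dec = table[decision].to_numpy()
    diff = dec[:, None] != dec[None, :]
    discerned = np.zeros((n, n), dtype=bool)
    vals = {a: table[a].to_numpy(dtype=float) for a in attrs}
    candidates: dict[str, list[float]] = {}
    for a in attrs:
        dv = np.unique(vals[a])
        candidates[a] = [float(m) for m in (dv[:-1] + dv[1:]) / 2.0]
    chosen: dict[str, list[float]] = {a: [] for a in attrs}
    while True:
        best = None
        best_gain = 0
        for a in attrs:
            if len(chosen[a]) >= c:
                continue
            for cut in candidates[a]:
                if cut in chosen[a]:
                    continue
                side = vals[a] < cut
                new = (side[:, None] != side[None, :]) & diff & ~discerned
                gain = int(new.sum())
                if gain > best_gain:
                    best, best_gain = (a, cut, side), gain
        if best is None or best_gain == 0:
            break
        a, cut, side = best
        chosen[a].append(cut)
        discerned |= (side[:, None] != side[None, :]) & diff
    return {a: tuple(sorted(v)) for a, v in chosen.items()}


def discretize_attributes(
    table: pd.DataFrame,
    method: str = "unsup_quantiles",
    c: int = 2,
    decision: str = DECISION,
    attrs: Sequence[str] | None = None,
):
    """Fit ``c`` cuts per numeric condition attribute and apply them.

    * ``unsup_intervals`` — equal-width cuts over the observed range;
    * ``unsup_quantiles`` — equal-frequency cuts (linear-interpolation
      quantiles);
    * ``global_discernibility`` — greedy supervised midpoint selection.

    Attributes with a single distinct value get zero cuts (one interval) and a
    warning.  Returns ``(CutSet, discretized table)``; non-numeric columns and
    the decision are passed through unchanged.
    """
    if method not in DISCRETIZE_METHODS:
        raise ValueError(f"unknown discretization method {method!r}")
    if c not in (1, 2, 3):
        raise ValueError("c must be 1, 2 or 3")
    if attrs is None:
        attrs = [a for a in _condition_attrs(table, decision)
                 if pd.api.types.is_numeric_dtype(table[a])]
    degenerate = [a for a in attrs if np.unique(table[a].to_numpy()).size < 2]
    for a in degenerate:
        warnings.warn(f"attribute {a!r} has a single distinct value; "
                      "no cuts fitted", stacklevel=2)
    live = [a for a in attrs if a not in degenerate]
    if method == "global_discernibility":
        if decision not in table.columns:
            raise ValueError("supervised discretization requires a decision column")
        cuts = _global_discernibility_cuts(table, live, c, decision)
    else:
        fn = _equal_width_cuts if method == "unsup_intervals" else _equal_freq_cuts
        cuts = {a: fn(table[a].to_numpy(dtype=float), c) for a in live}
    for a in degenerate:
        cuts[a] = ()
    cutset = CutSet(cuts={a: tuple(cuts[a]) for a in attrs})
    return cutset, cutset.apply(table, decision)


# ---------------------------------------------------------------------------
# reducts

def _pos_size(keys: list[tuple] | None, extra: np.ndarray | None,
              dec: np.ndarray) -> int:
    """|positive region| for the partition induced by keys (+ optional column)."""
    groups: dict[tuple, object] = {}
    n = dec.shape[0]
    CONFLICT = object()
    counts: dict[tuple, int] = {}
    for i in range(n):
        key = keys[i] if keys is not None else ()
        if extra is not None:
            key = key + (extra[i],)
        d = groups.get(key, None)
        if d is None:
            groups[key] = dec[i]
            counts[key] = 1
        elif d is CONFLICT:
            pass
        elif d == dec[i]:
            counts[key] += 1
        else:
            groups[key] = CONFLICT
            counts[key] = 0
    return sum(counts[k] for k, v in groups.items() if v is not CONFLICT)


def _combine_keys(table: pd.DataFrame, attrs: Sequence[str]) -> list[tuple]:
    if not attrs:
        return [()] * len(table)
    cols = [table[a].tolist() for a in attrs]
    return list(zip(*cols))


def compute_reduct(
    table: pd.DataFrame,
    method: str = "greedy",
    decision: str = DECISION,
    seed: int | None = None,
    n_probes: int = 100,
    alpha: float = 0.05,
) -> list[str]:
    """Attribute subset preserving (greedy) or approximating (DAAR) the
    positive region of the full attribute set.

    ``greedy`` adds the attribute with the largest positive-region growth
    until the full-attribute positive region is reached, then drops redundant
    attributes by backward elimination; the result is irredundant, hence
    minimal (no proper subset preserves the positive region).

    ``daar`` follows the same greedy order but accepts an attribute only if
    its gain exceeds the gain obtained with that attribute's values randomly
    permuted in at least ``(1 − alpha) · n_probes`` of ``n_probes`` probes;
    when no remaining candidate passes, the search stops, possibly short of
    the full positive region.
    """
    if method not in REDUCT_METHODS:
        raise ValueError(f"unknown reduct method {method!r}")
    if len(table) == 0:
        raise ValueError("empty decision table")
    attrs = _condition_attrs(table, decision)
    dec = np.asarray(table[decision].tolist(), dtype=object)
    full_pos = _pos_size(_combine_keys(table, attrs), None, dec)

    cols = {a: np.asarray(table[a].tolist(), dtype=object) for a in attrs}
    chosen: list[str] = []
    keys = [()] * len(table)
    cur_pos = _pos_size(keys, None, dec)

    if method == "greedy":
        remaining = list(attrs)
        while cur_pos < full_pos and remaining:
            gains = [( _pos_size(keys, cols[a], dec) - cur_pos, a) for a in remaining]
            best_gain = max(g for g, _ in gains)
            # ties (including all-zero gains) resolved by column order so the
            # search always progresses and terminates
            best = next(a for g, a in gains if g == best_gain)
            chosen.append(best)
            remaining.remove(best)
            keys = [k + (cols[best][i],) for i, k in enumerate(keys)]
            cur_pos = _pos_size(keys, None, dec)
    else:  # daar
        rng = np.random.default_rng(seed)
        remaining = list(attrs)
        n = len(table)
        # gain = how many of the not-yet-discerned different-decision pairs
        # the candidate newly discerns; finer than positive-region growth, so
        # informative attributes score before any block becomes pure.  The
        # probe permutes the candidate's values, which keeps the probe
        # statistic on exactly the same pair base as the true gain (a
        # calibrated test: a pure-noise attribute passes with probability
        # close to alpha)
        undisc = ~np.eye(n, dtype=bool)
        diff_cols = {a: cols[a][:, None] != cols[a][None, :] for a in attrs}
        dec_diff = dec[:, None] != dec[None, :]

        def pair_gain(col_diff):
            return int((col_diff & dec_diff & undisc).sum())

        # the "dynamically adjusted" part: the per-candidate significance
        # level is Bonferroni-corrected for the number of condition attributes
        # under consideration, so the chance of ever admitting a pure-noise
        # attribute stays near alpha for the whole search
        alpha_eff = alpha / max(1, len(attrs))

        while cur_pos < full_pos and remaining:
            gains = sorted(
                ((pair_gain(diff_cols[a]), a) for a in remaining),
                key=lambda ga: (-ga[0], attrs.index(ga[1])),
            )
            accepted = None
            for gain, a in gains:
                if gain <= 0:
                    break
                wins = 0
                for _ in range(n_probes):
                    perm = cols[a][rng.permutation(n)]
                    perm_diff = perm[:, None] != perm[None, :]
                    if gain > pair_gain(perm_diff):
                        wins += 1
                if wins >= math.ceil((1.0 - alpha_eff) * n_probes):
                    accepted = a
                    break
                remaining.remove(a)
            if accepted is None:
                break
            chosen.append(accepted)
            remaining.remove(accepted)
            undisc &= ~diff_cols[accepted]
            keys = [k + (cols[accepted][i],) for i, k in enumerate(keys)]
            cur_pos = _pos_size(keys, None, dec)

    # backward elimination: drop any attribute whose removal keeps the
    # positive region achieved by the selected set; for DAAR the achieved
    # discernibility of decision-different pairs must be kept as well (the
    # positive region of a noisy table can be empty, which would otherwise
    # make every attribute look redundant)
    def pairs_discerned(subset: Sequence[str]) -> int:
        if not subset:
            return 0
        dd = dec[:, None] != dec[None, :]
        disc = np.zeros_like(dd)
        for a in subset:
            col = np.asarray(table[a].tolist(), dtype=object)
            disc |= col[:, None] != col[None, :]
        return int((dd & disc).sum())

    target_pos = _pos_size(_combine_keys(table, chosen), None, dec)
    target_pairs = pairs_discerned(chosen) if method == "daar" else None
    for a in list(chosen):
        trial = [x for x in chosen if x != a]
        if _pos_size(_combine_keys(table, trial), None, dec) < target_pos:
            continue
        if target_pairs is not None and pairs_discerned(trial) < target_pairs:
            continue
        chosen = trial
    return [a for a in attrs if a in chosen]


# ---------------------------------------------------------------------------
# rules

@dataclass(frozen=True)
class DecisionRule:
    """IF attr=interval AND ... THEN decision=label, with support and Laplace."""

    antecedent: tuple  # tuple[(attr, value), ...]
    consequent: object
    support: int
    laplace: float
    index: int = 0

    def matches(self, obj: Mapping) -> bool:
        return all(a in obj and obj[a] == v for a, v in self.antecedent)

    def to_dict(self) -> dict:
        return {
            "if": {a: v for a, v in self.antecedent},
            "then": self.consequent,
            "support": self.support,
            "laplace": self.laplace,
        }


@dataclass
class RuleSet:
    """A trained rule model: rules, fallback label and the training cuts."""

    rules: list
    fallback: object
    cuts: CutSet | None = None
    classes: tuple = ()

    def to_json(self) -> str:
        return json.dumps({
            "rules": [r.to_dict() for r in self.rules],
            "fallback": self.fallback,
            "cuts": self.cuts.to_dict() if self.cuts else {},
            "classes": list(self.classes),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        d = json.loads(text)
        rules = [
            DecisionRule(
                antecedent=tuple(r["if"].items()),
                consequent=r["then"], support=r["support"],
                laplace=r["laplace"], index=i,
            )
            for i, r in enumerate(d["rules"])
        ]
        cuts = CutSet({a: tuple(v) for a, v in d.get("cuts", {}).items()}) \
            if d.get("cuts") else None
        return cls(rules=rules, fallback=d["fallback"], cuts=cuts,
                   classes=tuple(d.get("classes", ())))


def laplace_confidence(n_matching_class: int, n_matching: int, k: int) -> float:
    """Smoothed rule precision (n_correct + 1) / (n_matched + k)."""
    if not 0 <= n_matching_class <= n_matching:
        raise ValueError("need 0 <= n_matching_class <= n_matching")
    if k < 2:
        raise ValueError("k (number of classes) must be >= 2")
    return (n_matching_class + 1) / (n_matching + k)


def _match_mask(cols: Mapping[str, np.ndarray], n: int,
                conditions: Sequence[tuple]) -> np.ndarray:
    m = np.ones(n, dtype=bool)
    for a, v in conditions:
        m &= cols[a] == v
    return m


def _make_rule(cols, dec, n, conditions, consequent, k, index) -> DecisionRule:
    m = _match_mask(cols, n, conditions)
    n_match = int(m.sum())
    support = int((m & (dec == consequent)).sum())
    return DecisionRule(
        antecedent=tuple(conditions), consequent=consequent, support=support,
        laplace=laplace_confidence(support, n_match, k), index=index,
    )


def _class_order(dec: np.ndarray) -> list:
    return sorted(set(dec.tolist()), key=str)


def _majority(labels: Iterable) -> object:
    counts: dict = {}
    for v in labels:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    return sorted((k for k, v in counts.items() if v == top), key=str)[0]


def _lem2(cols, dec, attrs, n):
    """LEM2 local covering of each class's lower approximation."""
    all_keys = list(zip(*(cols[a].tolist() for a in attrs))) if attrs \
        else [()] * n
    blocks: dict[tuple, list[int]] = {}
    for i, key in enumerate(all_keys):
        blocks.setdefault(key, []).append(i)
    rules: list[tuple[tuple, object]] = []
    for K in _class_order(dec):
        concept = {i for i in range(n) if dec[i] == K}
        lower: set[int] = set()
        for b in blocks.values():
            if set(b) <= concept:
                lower |= set(b)
        G = set(lower)
        while G:
            T: list[tuple] = []
            TG = set(G)
            while True:
                m = _match_mask(cols, n, T)
                covered = set(np.flatnonzero(m).tolist())
                if T and covered <= lower:
                    break
                best = None
                used = {a for a, _ in T}
                for a in attrs:
                    if a in used:
                        continue
                    col = cols[a]
                    vals = sorted({col[i] for i in TG}, key=str)
                    for v in vals:
                        rel = sum(1 for i in TG if col[i] == v)
                        blk = int((col == v).sum())
                        key = (rel, -blk)
                        if best is None or key > best[0]:
                            best = (key, a, v)
                if best is None:
                    break
                _, a, v = best
                T.append((a, v))
                TG = {i for i in TG if cols[a][i] == v}
            # minimalize: drop conditions whose removal keeps [T] inside the
            # lower approximation
            for cond in list(T):
                if len(T) == 1:
                    break
                trial = [x for x in T if x != cond]
                m = _match_mask(cols, n, trial)
                if set(np.flatnonzero(m).tolist()) <= lower:
                    T.remove(cond)
            rules.append((tuple(T), K))
            G -= set(np.flatnonzero(_match_mask(cols, n, T)).tolist())
    return rules


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _cn2(cols, dec, attrs, n, beam_width: int = 5):
    """CN2 sequential covering with entropy-ranked beam search, no pruning."""
    remaining = np.ones(n, dtype=bool)
    rules: list[tuple[tuple, object]] = []
    pairs = [(a, v) for a in attrs for v in sorted(set(cols[a].tolist()), key=str)]
    while remaining.any():
        best_cx, best_key = None, None

        def score(cx):
            # entropy over the complex's full-table coverage (so emitted rules
            # are as pure as the data allows globally, not just on the rows
            # still uncovered); a complex must still cover something new
            m = _match_mask(cols, n, cx)
            cov_rem = int((m & remaining).sum())
            if cov_rem == 0:
                return None
            return (_entropy(dec[m]), -cov_rem, len(cx))

        star: list[tuple] = [()]
        for _ in range(len(attrs)):
            new = []
            seen = set()
            for cx in star:
                used = {a for a, _ in cx}
                for a, v in pairs:
                    if a in used:
                        continue
                    nc = tuple(sorted(cx + ((a, v),), key=lambda av: str(av)))
                    if nc in seen:
                        continue
                    seen.add(nc)
                    key = score(nc)
                    if key is not None:
                        new.append((key, nc))
            if not new:
                break
            new.sort(key=lambda kv: kv[0])
            improved = False
            for key, nc in new[:beam_width]:
                if best_key is None or key < best_key:
                    best_key, best_cx = key, nc
                    improved = True
            star = [nc for _, nc in new[:beam_width]]
            if not improved:
                break
        if best_cx is None:
            break
        m = _match_mask(cols, n, best_cx)
        K = _majority(dec[m].tolist())
        rules.append((best_cx, K))
        remaining &= ~m
    return rules


def _aq(cols, dec, attrs, n, star_size: int = 5):
    """AQ: per class, grow stars around seed examples against the negatives."""
    rules: list[tuple, object] = []
    for K in _class_order(dec):
        pos = [i for i in range(n) if dec[i] == K]
        uncovered = set(pos)
        neg_mask = dec != K
        guard = 0
        while uncovered and guard <= len(pos) + 1:
            guard += 1
            seed_i = min(uncovered)
            star: list[tuple] = [()]
            while True:
                viol = None
                for cx in star:
                    m = _match_mask(cols, n, cx) & neg_mask
                    hit = np.flatnonzero(m)
                    if hit.size:
                        viol = int(hit[0])
                        break
                if viol is None:
                    break
                new: list[tuple] = []
                seen = set()
                for cx in star:
                    if not _match_mask(cols, n, cx)[viol]:
                        if cx not in seen:
                            seen.add(cx)
                            new.append(cx)
                        continue
                    used = {a for a, _ in cx}
                    for a in attrs:
                        if a in used:
                            continue
                        if cols[a][seed_i] != cols[a][viol]:
                            nc = cx + ((a, cols[a][seed_i]),)
                            if nc not in seen:
                                seen.add(nc)
                                new.append(nc)
                if not new:
                    # seed indiscernible from a negative: fall back to the
                    # seed's full description (inconsistent table)
                    star = [tuple((a, cols[a][seed_i]) for a in attrs)]
                    break

                def lef(cx):
                    m = _match_mask(cols, n, cx)
                    cov = sum(1 for i in uncovered if m[i])
                    return (-cov, len(cx))

                new.sort(key=lef)
                star = new[:star_size]
            best = min(
                star,
                key=lambda cx: (
                    -sum(1 for i in uncovered if _match_mask(cols, n, cx)[i]),
                    len(cx),
                ),
            )
            rules.append((best, K))
            m = _match_mask(cols, n, best)
            uncovered -= set(np.flatnonzero(m).tolist())
    return rules


def _ind(cols, dec, attrs, n):
    """One rule per indiscernibility block; consequent = block majority."""
    keys = list(zip(*(cols[a].tolist() for a in attrs))) if attrs else [()] * n
    blocks: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        blocks.setdefault(key, []).append(i)
    rules = []
    for key, members in sorted(blocks.items(), key=lambda kv: min(kv[1])):
        K = _majority(dec[members].tolist())
        conditions = tuple(zip(attrs, key))
        rules.append((conditions, K))
    return rules


def induce_rules(table: pd.DataFrame, method: str = "LEM2",
                 decision: str = DECISION) -> list[DecisionRule]:
    """Induce decision rules from a discretized table.

    The table should already be restricted to the reduct attributes.  Every
    returned rule carries its training support and Laplace confidence.
    """
    method = method.upper()
    if method not in RULE_METHODS:
        raise ValueError(f"unknown rule induction method {method!r}")
    attrs = _condition_attrs(table, decision)
    n = len(table)
    dec = np.asarray(table[decision].tolist(), dtype=object)
    cols = {a: np.asarray(table[a].tolist(), dtype=object) for a in attrs}
    k = max(2, len(set(dec.tolist())))
    inducer = {"LEM2": _lem2, "CN2": _cn2, "AQ": _aq, "IND": _ind}[method]
    raw = inducer(cols, dec, attrs, n)
    return [
        _make_rule(cols, dec, n, conds, K, k, i)
        for i, (conds, K) in enumerate(raw)
    ]


@dataclass(frozen=True)
class FilterResult:
    """Outcome of model-level rule filtration; rejection is a value, not an error."""

    accepted: bool
    rules: tuple
    reason: str | None = None


def filter_rules(rules: Sequence[DecisionRule], min_rules: int = 2,
                 mean_lc_threshold: float = 0.6,
                 max_rules: int = 100) -> FilterResult:
    """Reject models with < ``min_rules`` rules or mean Laplace confidence
    below the threshold; cap accepted models at ``max_rules`` rules (kept by
    descending Laplace confidence, ties by support then original order)."""
    rules = list(rules)
    if len(rules) < min_rules:
        return FilterResult(False, tuple(rules), "fewer than minimum rules")
    mean_lc = float(np.mean([r.laplace for r in rules]))
    if mean_lc < mean_lc_threshold:
        return FilterResult(False, tuple(rules),
                            f"mean Laplace confidence {mean_lc:.4f} below threshold")
    if len(rules) > max_rules:
        kept = sorted(rules, key=lambda r: (-r.laplace, -r.support, r.index))[:max_rules]
        kept = sorted(kept, key=lambda r: r.index)
        return FilterResult(True, tuple(kept), None)
    return FilterResult(True, tuple(rules), None)


def classify(rules: Sequence[DecisionRule] | RuleSet, obj: Mapping,
             fallback=None):
    """Classify one discretized object: the most specific matching rule wins.

    Ties are broken by higher Laplace confidence, then support, then rule
    order; an object matching no rule gets the fallback label (training
    majority).  Attribute values absent from an antecedent's interval simply
    fail to match — never an error.
    """
    if isinstance(rules, RuleSet):
        if fallback is None:
            fallback = rules.fallback
        rules = rules.rules
    best = None
    best_key = None
    for r in rules:
        if r.matches(obj):
            key = (len(r.antecedent), r.laplace, r.support, -r.index)
            if best_key is None or key > best_key:
                best, best_key = r, key
    if best is None:
        return fallback
    return best.consequent


def classify_table(ruleset: RuleSet, table: pd.DataFrame,
                   decision: str = DECISION) -> list:
    """Classify raw-valued rows by applying the training cuts first."""
    disc = ruleset.cuts.apply(table, decision) if ruleset.cuts else table
    cols = [c for c in disc.columns if c != decision]
    return [
        classify(ruleset.rules, dict(zip(cols, row)), ruleset.fallback)
        for row in disc[cols].itertuples(index=False, name=None)
    ]
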