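"""k-NN robustness baseline with 5×2 cross-validation and UMAP export.

The same decision tables used by the rough-set models are classified with
k-nearest neighbours under a Minkowski metric, after one of five normalization
schemes (none; per-column division by the maximum absolute value; per-column
scaling to <−1, 1>; per-column standardization; per-row unit-length scaling).
Performance is estimated by twofold cross-validation repeated five times
(ten macro-F1 values); the summary assumes a Gaussian performance metric, so
the 95% confidence interval is mean ∓ 1.96·std.  Neighbour search and CV
splitting delegate to scikit-learn; UMAP delegates to umap-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .model_search import compute_metrics, enumerate_outcome_ranges
from .wavelet_features import DECISION, validate_outcome_range

__all__ = [
    "KnnConfig",
    "CvSummary",
    "NORMALIZATIONS",
    "MINKOWSKI_PS",
    "normalize",
    "minkowski_distance",
    "encode_features",
    "five_by_two_cv",
    "build_knn_grid",
    "grid_cardinality",
    "knn_grid_search",
    "ranking_table",
    "confidence_interval95",
    "umap_embed",
]

NORMALIZATIONS = ("none", "maxabs", "minmax", "standardize", "row_unit")
MINKOWSKI_PS = (1.0, 1.25, 1.5, 1.75, 2.0)
K_RANGE = tuple(range(2, 51))


@dataclass(frozen=True)
class KnnConfig:
    """One grid cell: outcome ranges, normalization, k and Minkowski exponent."""

    d_range: tuple[int, int]
    normalization: str = "none"
    k: int = 5
    p: float = 2.0

    def __post_init__(self):
        validate_outcome_range(*self.d_range)
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")


@dataclass(frozen=True)
class CvSummary:
    """Descriptive statistics of the ten 5×2CV macro-F1 estimates."""

    f1_values: tuple

    @property
    def f1_min(self) -> float:
        return float(np.min(self.f1_values))

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.f1_values))

    @property
    def f1_max(self) -> float:
        return float(np.max(self.f1_values))

    @property
    def f1_std(self) -> float:
        return float(np.std(self.f1_values, ddof=1))

    @property
    def ci95(self) -> tuple[float, float]:
        return confidence_interval95(self.f1_mean, self.f1_std)


def confidence_interval95(mean: float, std: float) -> tuple[float, float]:
    """Gaussian 95% interval: mean ∓ 1.96·std."""
    return (mean - 1.96 * std, mean + 1.96 * std)


def normalize(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Apply one of the five normalization schemes to the numeric columns.

    ``maxabs``, ``minmax`` (to <−1, 1>) and ``standardize`` act per column;
    ``row_unit`` rescales each row vector to unit length; ``none`` is the
    identity.  Zero-variance columns under ``standardize`` and zero-length
    rows under ``row_unit`` are left at zero with a warning.
    """
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}")
    out = table.copy()
    num = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    X = out[num].to_numpy(dtype=float)
    if method == "none":
        return out
    if method == "maxabs":
        denom = np.abs(X).max(axis=0)
        denom[denom == 0] = 1.0
        X = X / denom
    elif method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        span[span == 0] = 1.0
        X = 2.0 * (X - lo) / span - 1.0
    elif method == "standardize":
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn("zero-variance column(s) left at 0 under "
                          "standardization", stacklevel=2)
            sd[zero] = 1.0
        X = (X - mu) / sd
    elif method == "row_unit":
        norms = np.linalg.norm(X, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn("zero-length row(s) left as zeros under row_unit",
                          stacklevel=2)
            norms[zero] = 1.0
        X = X / norms[:, None]
    out[num] = X
    return out


def minkowski_distance(x: Sequence[float], y: Sequence[float], p: float) -> float:
    """(Σ|x_i − y_i|^p)^(1/p); p = 1 is Manhattan, p = 2 Euclidean."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("points must have equal dimension")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


def encode_features(table: pd.DataFrame, decision: str = DECISION):
    """Numeric feature matrix and label vector; sex coded M=1, F=0."""
    X = table.drop(columns=[decision]).copy()
    if "Sex" in X.columns and not pd.api.types.is_numeric_dtype(X["Sex"]):
        X["Sex"] = (X["Sex"] == "M").astype(float)
    return X.astype(float), table[decision].to_numpy()


def five_by_two_cv(X: pd.DataFrame, y: Sequence, k: int, p: float,
                   seed: int = 0, classes: Sequence = ("A", "B", "C")) -> CvSummary:
    """Five independent stratified 50:50 splits, each fold tested both ways."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 objects for 5x2CV")
    Xv = np.asarray(X, dtype=float)
    seeds = np.random.SeedSequence(seed).generate_state(5)
    f1s = []
    for s in seeds:
        skf = StratifiedKFold(n_splits=2, shuffle=True,
                              random_state=int(s) % (2 ** 32 - 1))
        for tr, te in skf.split(Xv, y):
            kk = min(k, len(tr))
            clf = KNeighborsClassifier(n_neighbors=kk, metric="minkowski",
                                       p=p, algorithm="brute")
            clf.fit(Xv[tr], y[tr])
            pred = clf.predict(Xv[te])
            f1s.append(compute_metrics(y[te], pred, classes=classes).f1_macro)
    return CvSummary(f1_values=tuple(f1s))


def build_knn_grid(
    d_ranges: Sequence[tuple[int, int]] | None = None,
    normalizations: Sequence[str] = NORMALIZATIONS,
    ks: Sequence[int] = K_RANGE,
    ps: Sequence[float] = MINKOWSKI_PS,
) -> list[KnnConfig]:
    """Full factorial grid; defaults reproduce the 17×5×49×5 = 20825 cells."""
    if d_ranges is None:
        d_ranges = enumerate_outcome_ranges()
    return [
        KnnConfig(d_range=tuple(d), normalization=nm, k=k, p=p)
        for d in d_ranges for nm in normalizations for k in ks for p in ps
    ]


def grid_cardinality(**kwargs) -> int:
    return len(build_knn_grid(**kwargs))


def knn_grid_search(
    table_builder: Callable[[tuple[int, int]], pd.DataFrame],
    grid: Iterable[KnnConfig],
    seed: int = 0,
) -> list[tuple[KnnConfig, CvSummary]]:
    """Evaluate every configuration; rank by the largest F1 obtained.

    ``table_builder(d_range)`` must return a decision table whose decision
    column already carries the A/B/C labels for that outcome range.
    """
    grid = list(grid)
    cache: dict[tuple, tuple[pd.DataFrame, np.ndarray]] = {}
    results = []
    for cfg in grid:
        key = (cfg.d_range, cfg.normalization)
        if key not in cache:
            table = table_builder(cfg.d_range)
            X, y = encode_features(table)
            cache[key] = (normalize(X, cfg.normalization), y)
        Xn, y = cache[key]
        results.append((cfg, five_by_two_cv(Xn, y, cfg.k, cfg.p, seed=seed)))
    results.sort(key=lambda cs: -cs[1].f1_max)
    return results


def ranking_table(results: Sequence[tuple[KnnConfig, CvSummary]],
                  top: int = 20) -> pd.DataFrame:
    """Ranked summary in the printed layout: d, normalization, k, p, F1 stats."""
    rows = []
    for cfg, s in results[:top]:
        lo, hi = s.ci95
        rows.append({
            "d": "{%d,%d}" % cfg.d_range, "normalization": cfg.normalization,
            "k": cfg.k, "p": cfg.p, "f1_min": s.f1_min, "f1_mean": s.f1_mean,
            "f1_max": s.f1_max, "f1_std": s.f1_std, "ci95_lo": lo, "ci95_hi": hi,
        })
    return pd.DataFrame(rows)


def umap_embed(X: pd.DataFrame, seed: int = 0,
               labels: Sequence | None = None) -> pd.DataFrame:
    """2-D UMAP embedding of the (already normalized) feature table.

    Delegates to umap-learn with a fixed random state for reproducibility;
    returns one (umap1, umap2[, label]) row per object.
    """
    Xv = np.asarray(X, dtype=float)
    if Xv.shape[0] < 4:
        raise ValueError("UMAP embedding needs at least 4 objects")
    import umap  # heavy import (numba); deferred

    n_neighbors = min(15, Xv.shape[0] - 1)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(Xv)
    out = pd.DataFrame(coords, columns=["umap1", "umap2"])
    if labels is not None:
        out["label"] = list(labels)
    return out
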