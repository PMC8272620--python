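"""Signal standardization, DWT granulation and quartile descriptors.

Each respiratory signal is standardized to zero mean and unit (population)
standard deviation, decomposed with a multilevel discrete wavelet transform,
and reduced to a small set of quartile descriptors: for each retained scale of
interest the first, second and third quartiles (Q1, Q2, Q3) and the
interquartile range IQR = Q3 − Q1 of the detail coefficients.  The seven
finest decomposition components are dropped by default (at 1000 Sa/s this
leaves a first retained component of roughly 4500–4700 samples for a 20-min
recording), and the retained components are re-indexed 1..K from the finest
retained; "scales 5, 6, 7" always refer to that retained indexing, i.e.
absolute detail levels ``drop_finest + 5 .. drop_finest + 7`` whose time spans
(about 4–16 s at the reference configuration) bracket a breathing period.

Mother wavelets are ranked by the spread criterion: a better-suited wavelet
yields a broader coefficient distribution on standardized signals, measured as
the IQR of all retained scalogram values, averaged over signals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt

from .synthetic_cohort import Signal, SubjectRecord

__all__ = [
    "Scalogram",
    "standardize_signal",
    "dwt_scalogram",
    "drop_finest_for_rate",
    "rank_mother_wavelets",
    "extract_descriptors",
    "build_decision_table",
    "cohort_decision_table",
    "discretize_outcome",
    "validate_outcome_range",
    "debias_subsample",
    "decile_from_percentage",
    "TABLE_COLUMNS",
    "DESCRIPTOR_COLUMNS",
    "DECISION",
]

DEFAULT_WAVELET = "rbio3.1"
DEFAULT_DROP_FINEST = 7
DEFAULT_SCALES = (5, 6, 7)
DECISION = "decision"

DESCRIPTOR_COLUMNS = [
    f"Scale{s}_{q}" for s in DEFAULT_SCALES for q in ("q1", "q2", "q3", "IQR")
]
TABLE_COLUMNS = DESCRIPTOR_COLUMNS + ["Age", "Sex", "BMI", "WHR", DECISION]

_PATTERN_FIELD = {
    "periodic-like": "contribution_periodic",
    "intermediate": "contribution_intermediate",
    "normal": "contribution_normal",
}


@dataclass(frozen=True)
class Scalogram:
    """Retained DWT detail components of one signal.

    ``levels`` maps the retained-scale index (1 = finest retained) to the
    detail-coefficient array of absolute decomposition level
    ``dropped_levels + index``.
    """

    wavelet_name: str
    levels: Mapping[int, np.ndarray]
    dropped_levels: int
    rate: float


def standardize_signal(signal: Signal) -> Signal:
    """Zero-mean, unit-variance standardization (population std, divide by n)."""
    x = signal.samples
    if x.size < 2:
        raise ValueError("standardization needs at least two samples")
    sd = x.std()  # population (ddof=0)
    if sd == 0:
        raise ValueError("degenerate input: constant signal has zero variance")
    return Signal(samples=(x - x.mean()) / sd, rate=signal.rate)


def drop_finest_for_rate(rate: float, reference_rate: float = 1000.0,
                         reference_drop: int = DEFAULT_DROP_FINEST) -> int:
    """Number of finest components to drop so retained scales keep their spans.

    The reference configuration drops 7 components at 1000 Sa/s; a signal
    decimated by 2**k needs k fewer drops for retained scale s to cover the
    same time span.  ``rate`` must be the reference rate divided by a power of
    two.
    """
    k = math.log2(reference_rate / rate)
    if abs(k - round(k)) > 1e-9:
        raise ValueError("rate must be reference_rate / 2**k for integer k")
    drop = reference_drop - int(round(k))
    if drop < 0:
        raise ValueError("rate too low for the reference scale mapping")
    return drop


def dwt_scalogram(
    signal: Signal,
    wavelet_name: str = DEFAULT_WAVELET,
    max_level: int | None = None,
    drop_finest: int = DEFAULT_DROP_FINEST,
) -> Scalogram:
    """Multilevel DWT detail components with the finest ``drop_finest`` dropped.

    Retained components are re-indexed 1..K starting from the finest retained.
    By default the decomposition depth is ``drop_finest + 7`` so retained
    scales up to 7 exist.
    """
    if drop_finest < 0:
        raise ValueError("drop_finest must be >= 0")
    w = pywt.Wavelet(wavelet_name)
    if max_level is None:
        max_level = drop_finest + 7
    if max_level <= drop_finest:
        raise ValueError("max_level must exceed drop_finest")
    min_len = (w.dec_len - 1) * 2 ** max_level
    if signal.samples.size < min_len:
        raise ValueError(
            f"signal too short for a level-{max_level} decomposition with "
            f"{wavelet_name}: need at least {min_len} samples, got "
            f"{signal.samples.size}"
        )
    coeffs = pywt.wavedec(signal.samples, w, level=max_level)
    # coeffs = [cA_max, cD_max, ..., cD_1]; absolute detail level l sits at
    # index len(coeffs) - l
    levels = {
        s: np.asarray(coeffs[len(coeffs) - (drop_finest + s)])
        for s in range(1, max_level - drop_finest + 1)
    }
    return Scalogram(wavelet_name=wavelet_name, levels=levels,
                     dropped_levels=drop_finest, rate=signal.rate)


def _pooled_iqr(scalogram: Scalogram) -> float:
    pooled = np.concatenate([np.ravel(v) for v in scalogram.levels.values()])
    q1, q3 = np.percentile(pooled, [25, 75])
    return float(q3 - q1)


def rank_mother_wavelets(
    signals: Sequence[Signal],
    candidates: Sequence[str] | None = None,
    *,
    max_level: int | None = None,
    drop_finest: int = DEFAULT_DROP_FINEST,
):
    """Rank candidate mother wavelets by mean pooled-coefficient IQR.

    For each candidate the IQR of all retained scalogram coefficients is
    computed per signal and averaged; candidates are returned sorted by
    descending mean IQR (ties broken lexicographically by name).  Candidates
    that fail to decompose any signal are excluded with a warning.  Returns
    ``(ranking, per_signal_iqr, failures)`` where ``ranking`` is a list of
    ``(name, mean_iqr)`` and ``per_signal_iqr`` keeps the raw values for
    boxplot export.
    """
    if not signals:
        raise ValueError("at least one signal is required")
    if candidates is None:
        candidates = pywt.wavelist(kind="discrete")
    if not candidates:
        raise ValueError("at least one candidate wavelet is required")
    per_signal: dict[str, list[float]] = {}
    failures: dict[str, str] = {}
    for name in candidates:
        iqrs = []
        try:
            for sig in signals:
                sc = dwt_scalogram(sig, name, max_level=max_level,
                                   drop_finest=drop_finest)
                iqrs.append(_pooled_iqr(sc))
        except Exception as exc:  # noqa: BLE001 - any decomposition failure
            failures[name] = str(exc)
            warnings.warn(f"wavelet {name} excluded from ranking: {exc}",
                          stacklevel=2)
            continue
        per_signal[name] = iqrs
    ranking = sorted(
        ((name, float(np.mean(v))) for name, v in per_signal.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return ranking, per_signal, failures


def extract_descriptors(scalogram: Scalogram, scales: Iterable[int] = DEFAULT_SCALES):
    """Quartile descriptors (Q1, Q2, Q3, IQR) for the requested retained scales.

    Quartiles use linear interpolation between order statistics; IQR is
    computed as Q3 − Q1 exactly.
    """
    out: dict[str, float] = {}
    for s in scales:
        if s not in scalogram.levels:
            raise ValueError(f"scale {s} not present in scalogram "
                             f"(available: {sorted(scalogram.levels)})")
        coeffs = scalogram.levels[s]
        q1, q2, q3 = (float(v) for v in np.percentile(coeffs, [25, 50, 75]))
        out[f"Scale{s}_q1"] = q1
        out[f"Scale{s}_q2"] = q2
        out[f"Scale{s}_q3"] = q3
        out[f"Scale{s}_IQR"] = q3 - q1
    return out


def decile_from_percentage(pct: float) -> int:
    """Map a 0–100 pattern percentage to the integer decile scale 0..10."""
    if not 0 <= pct <= 100:
        raise ValueError("percentage must lie in [0, 100]")
    return int(round(pct / 10.0))


def build_decision_table(
    descriptor_rows: Sequence[Mapping[str, float]],
    records: Sequence[SubjectRecord],
    pattern: str,
) -> pd.DataFrame:
    """Assemble the decision table: 12 signal descriptors + Age, Sex, BMI, WHR.

    The decision column is the chosen pattern's contribution decile (0..10);
    the column order is the fixed layout ``Scale5_q1 .. Scale7_IQR, Age, Sex,
    BMI, WHR, decision``.
    """
    if pattern not in _PATTERN_FIELD:
        raise ValueError(f"unknown pattern {pattern!r}")
    if len(descriptor_rows) != len(records):
        raise ValueError("one descriptor row per subject record is required")
    rows = []
    for desc, rec in zip(descriptor_rows, records):
        missing = [c for c in DESCRIPTOR_COLUMNS if c not in desc]
        if missing:
            raise ValueError(f"descriptor row missing attributes: {missing}")
        row = {c: desc[c] for c in DESCRIPTOR_COLUMNS}
        row["Age"] = rec.age
        row["Sex"] = rec.sex
        row["BMI"] = rec.bmi
        row["WHR"] = rec.whr
        row[DECISION] = getattr(rec, _PATTERN_FIELD[pattern])
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def cohort_decision_table(
    cohort: Sequence[tuple[SubjectRecord, Signal]],
    pattern: str,
    *,
    wavelet_name: str = DEFAULT_WAVELET,
    drop_finest: int | None = None,
    scales: Iterable[int] = DEFAULT_SCALES,
    max_level: int | None = None,
) -> pd.DataFrame:
    """Standardize, decompose and granulate a whole cohort into a decision table.

    ``drop_finest`` defaults to the rate-adjusted value so retained scales 5–7
    keep their reference time spans regardless of sampling rate.
    """
    records = [rec for rec, _ in cohort]
    descs = []
    for _, sig in cohort:
        if sig is None:
            raise ValueError("cohort entry has no signal")
        df = drop_finest_for_rate(sig.rate) if drop_finest is None else drop_finest
        sc = dwt_scalogram(standardize_signal(sig), wavelet_name,
                           max_level=max_level, drop_finest=df)
        descs.append(extract_descriptors(sc, scales))
    return build_decision_table(descs, records, pattern)


def validate_outcome_range(d1: int, d2: int) -> None:
    """Valid (d1, d2): d1 in 1..5, width d2−d1 in 2..5, and d2 < 9."""
    if d1 not in (1, 2, 3, 4, 5):
        raise ValueError("d1 must lie in 1..5")
    if d2 - d1 not in (2, 3, 4, 5):
        raise ValueError("d2 - d1 must lie in 2..5")
    if not d2 < 9:
        raise ValueError("d2 < 9 must hold")


def discretize_outcome(decile: int, d1: int, d2: int) -> str:
    """Map a contribution decile to A ([0,d1)), B ([d1,d2)) or C ([d2,10])."""
    validate_outcome_range(d1, d2)
    if not 0 <= decile <= 10:
        raise ValueError("decile must lie in 0..10")
    if decile < d1:
        return "A"
    if decile < d2:
        return "B"
    return "C"


def debias_subsample(table: pd.DataFrame, seed: int, decision: str = DECISION) -> pd.DataFrame:
    """Reduce the surplus of zero-decile cases by uniform random subsampling.

    The zero-decile count is reduced to the rounded mean of the counts of
    deciles 1..10 (absent deciles count as zero); tables already at or below
    that mean are returned unchanged.  Row order of the retained cases is
    preserved; deterministic for a fixed seed.
    """
    dec = table[decision].to_numpy()
    nonzero = int((dec != 0).sum())
    if nonzero == 0:
        raise ValueError("table has no nonzero-decile cases")
    counts = pd.Series(dec).value_counts()
    mean_nonzero = sum(int(counts.get(d, 0)) for d in range(1, 11)) / 10.0
    target = int(round(mean_nonzero))
    zero_idx = np.flatnonzero(dec == 0)
    if zero_idx.size <= target:
        return table.copy()
    rng = np.random.default_rng(seed)
    keep_zero = rng.choice(zero_idx, size=target, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(dec != 0), keep_zero]))
    return table.iloc[keep].reset_index(drop=True)
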