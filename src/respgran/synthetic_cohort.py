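"""Synthetic respiratory-belt signals and cohort tables.

Real respiratory-belt recordings of this kind are private clinical data, so the
analysis pipeline is exercised on synthetic material that reproduces the
structure the downstream stages rely on:

* inhale–exhale events with a person-consistent triangular shape and a
  breathing period of roughly 3–6 s;
* "periodic-like" stretches in which breath amplitudes wax and wane under a
  slow sinusoidal envelope (tens of seconds per cycle);
* apneas, operationalised as stretches with no respiratory activity lasting
  longer than three breathing cycles;
* an anthropometric cohort table (age, sex, weight, height, waist, hip, BMI,
  WHR) in which the periodic-like and intermediate groups are stochastically
  heavier, more centrally obese, and more often male than the normal group;
* per-recording "percentage contribution" deciles of the three patterns, with
  the expert label defined as intermediate whenever neither the normal nor the
  periodic-like contribution reaches 70%.

A single integer seed controls every random draw; per-subject generators are
split off the master ``numpy.random.SeedSequence`` so regenerating a cohort
with the same seed is bit-exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BreathingParams",
    "Signal",
    "SubjectRecord",
    "ApneaEvent",
    "DEFAULT_RATE",
    "LABELS",
    "EXPERT_CODE",
    "synthesize_signal",
    "generate_cohort",
    "detect_apneas",
    "compute_anthropometrics",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

#: Default sampling rate of synthetic recordings, in samples per second.  The
#: study hardware sampled at 1000 Sa/s; synthetic material uses a power-of-two
#: decimation of that rate so DWT levels map onto the same time spans (see
#: :func:`respgran.wavelet_features.drop_finest_for_rate`).
DEFAULT_RATE = 125.0

LABELS = ("normal", "intermediate", "periodic-like")
EXPERT_CODE = {"normal": 1, "intermediate": 2, "periodic-like": 3}

#: Waxing–waning modulation depth used for signal segments of each pattern.
SEGMENT_DEPTH = {"normal": 0.0, "intermediate": 0.5, "periodic-like": 0.9}

#: Apnea insertion rate (events per minute) by expert label.
LABEL_APNEA_RATE = {"normal": 0.0, "intermediate": 0.1, "periodic-like": 0.2}

#: Label-conditional anthropometric distributions.  Pooled study moments were
#: BMI 28.8 ± 4.9 kg/m² and WHR 0.92 ± 0.10; the per-label shifts are free
#: parameters of the generator chosen so the periodic-like/intermediate groups
#: sit above the normal group in weight, waist, BMI, WHR and male fraction.
DEFAULT_ANTHRO = {
    "normal": {"bmi_mean": 26.5, "bmi_sd": 4.0, "whr_mean": 0.87, "whr_sd": 0.07, "male_frac": 0.42},
    "intermediate": {"bmi_mean": 29.5, "bmi_sd": 4.5, "whr_mean": 0.94, "whr_sd": 0.08, "male_frac": 0.62},
    "periodic-like": {"bmi_mean": 30.5, "bmi_sd": 4.5, "whr_mean": 0.96, "whr_sd": 0.08, "male_frac": 0.68},
}

COHORT_COLUMNS = [
    "subject_id", "age", "sex", "weight_kg", "height_cm", "waist_cm", "hip_cm",
    "bmi", "whr", "apnea_count", "apneas_per_min", "apnea_mean_dur_s",
    "contrib_periodic", "contrib_intermediate", "contrib_normal", "expert_label",
]


@dataclass(frozen=True)
class BreathingParams:
    """Morphological parameters of one synthetic respiratory recording.

    ``apnea_duration_cycles`` must exceed 3: a cessation only counts as an
    apnea once it lasts longer than three breathing cycles.
    """

    breath_period_s: float = 4.0
    breath_amplitude: float = 1.0
    triangle_duty: float = 0.6
    modulation_depth: float = 0.0
    modulation_period_s: float = 40.0
    apnea_rate_per_min: float = 0.0
    apnea_duration_cycles: float = 5.0
    noise_sd: float = 0.0

    def validate(self) -> None:
        if self.breath_period_s <= 0:
            raise ValueError("breath_period_s must be positive")
        if self.breath_amplitude <= 0:
            raise ValueError("breath_amplitude must be positive")
        if not 0 < self.triangle_duty <= 1:
            raise ValueError("triangle_duty must lie in (0, 1]")
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.modulation_period_s <= 0:
            raise ValueError("modulation_period_s must be positive")
        if self.apnea_rate_per_min < 0:
            raise ValueError("apnea_rate_per_min must be >= 0")
        if self.apnea_rate_per_min > 0 and self.apnea_duration_cycles <= 3:
            raise ValueError(
                "apnea_duration_cycles must exceed 3 breathing cycles; shorter "
                "gaps are pauses, not apneas"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class Signal:
    """A single-channel sample stream with its sampling rate in Sa/s."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class ApneaEvent:
    start_s: float
    duration_s: float


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort-table row: anthropometrics, apnea statistics, pattern deciles."""

    subject_id: int
    age: int
    sex: str
    weight: float
    height: float
    waist: float
    hip: float
    bmi: float
    whr: float
    apnea_count: int
    apneas_per_min: float
    apnea_mean_duration: float
    contribution_periodic: int
    contribution_intermediate: int
    contribution_normal: int
    expert_label: int

    def __post_init__(self):
        deciles = (self.contribution_periodic, self.contribution_intermediate,
                   self.contribution_normal)
        if sum(deciles) != 10 or any(not 0 <= d <= 10 for d in deciles):
            raise ValueError("contribution deciles must be in 0..10 and sum to 10")
        if self.expert_label not in (1, 2, 3):
            raise ValueError("expert_label must be 1, 2 or 3")


def compute_anthropometrics(weight: float, height: float, waist: float, hip: float):
    """BMI (kg/m²) and waist-to-hip ratio, rounded to 4 decimals for table output."""
    for name, v in (("weight", weight), ("height", height), ("waist", waist), ("hip", hip)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    bmi = weight / (height / 100.0) ** 2
    whr = waist / hip
    return round(bmi, 4), round(whr, 4)


def _render(
    params: BreathingParams,
    duration_s: float,
    rate: float,
    rng: np.random.Generator | None,
    depth_fn: Callable[[float], float],
    fill: bool = True,
):
    """Render a breath-by-breath triangular event train.

    Apneas are inserted on a deterministic schedule: one event per
    ``60 / apnea_rate_per_min`` seconds, the first at half that interval, so
    the number of inserted events in a recording of known length is exact.
    Returns ``(samples, events)``; ``samples`` is ``None`` when ``fill`` is
    False (schedule-only evaluation).
    """
    n = int(round(duration_s * rate))
    x = np.zeros(n) if fill else None
    T = params.breath_period_s
    width = params.triangle_duty * T
    half = 0.5 * width
    if params.apnea_rate_per_min > 0:
        interval = 60.0 / params.apnea_rate_per_min
        gap = params.apnea_duration_cycles * T
        next_apnea = 0.5 * interval
    else:
        interval = math.inf
        gap = 0.0
        next_apnea = math.inf
    events: list[ApneaEvent] = []
    t = 0.0
    while t + 1.0 / rate < duration_s:
        if t >= next_apnea and t + gap <= duration_s:
            events.append(ApneaEvent(start_s=t, duration_s=gap))
            t += gap
            next_apnea += interval
            continue
        peak_t = t + half
        depth = depth_fn(peak_t)
        amp = params.breath_amplitude * (
            1.0 + depth * math.sin(2.0 * math.pi * peak_t / params.modulation_period_s)
        )
        if fill:
            start = t * rate
            i0 = int(math.ceil(start))
            i1 = min(n - 1, int(math.floor(start + width * rate)))
            if i1 >= i0:
                # offsets relative to breath onset: bit-identical events when
                # breath onsets fall on the sample grid
                offs = (np.arange(i0, i1 + 1) - start) / rate
                tri = 1.0 - np.abs(offs - half) / half
                x[i0:i1 + 1] += amp * np.clip(tri, 0.0, None)
        t += T
    if fill and params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested but no RNG supplied")
        x += rng.normal(0.0, params.noise_sd * params.breath_amplitude, size=n)
    return x, events


def synthesize_signal(
    params: BreathingParams,
    duration_s: float,
    seed: int,
    rate: float = DEFAULT_RATE,
    return_events: bool = False,
):
    """Generate a synthetic respiratory-belt signal.

    The signal is a train of triangular inhale–exhale events (one per breathing
    period, occupying ``triangle_duty`` of it).  When ``modulation_depth`` > 0
    the per-breath peak amplitude follows a slow sinusoidal envelope
    ``1 + depth·sin(2πt/T_mod)``.  Apneas are inserted as activity-free gaps of
    ``apnea_duration_cycles`` breathing cycles (strictly more than three).
    Deterministic for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    params.validate()
    rng = np.random.default_rng(seed)
    x, events = _render(params, duration_s, rate, rng,
                        depth_fn=lambda t: params.modulation_depth)
    sig = Signal(samples=x, rate=rate)
    if return_events:
        return sig, events
    return sig


def detect_apneas(signal: Signal, breath_period_s: float, activity_threshold: float = 0.1):
    """Count apneas: gaps where a moving envelope stays quiet for > 3 cycles.

    The envelope is a moving RMS of the zero-mean, unit-variance signal over
    one breathing period; a maximal run below ``activity_threshold`` times the
    median envelope counts as an apnea only when strictly longer than three
    breathing cycles.  Returns ``(count, events_per_minute, mean_duration_s)``.
    """
    if breath_period_s <= 0:
        raise ValueError("breath_period_s must be positive")
    x = signal.samples
    win = int(round(breath_period_s * signal.rate))
    if x.size < win or win < 1:
        raise ValueError("signal shorter than one breathing cycle")
    sd = x.std()
    if sd == 0:
        raise ValueError("signal has zero variance")
    z = (x - x.mean()) / sd
    kernel = np.ones(win) / win
    # moving standard deviation over one breathing period: a level-offset in
    # a quiet stretch (the standardized baseline) must still read as inactive
    m1 = np.convolve(z, kernel, mode="same")
    m2 = np.convolve(z * z, kernel, mode="same")
    env = np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))
    thr = activity_threshold * np.median(env)
    below = env < thr
    # maximal runs of quiet samples
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1) if edges.size else []
    ends = list(edges[below[edges]] + 1) if edges.size else []
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)
    min_len = 3.0 * breath_period_s * signal.rate
    durations = [
        (e - s) / signal.rate for s, e in zip(starts, ends) if (e - s) > min_len
    ]
    count = len(durations)
    per_min = count / (x.size / signal.rate / 60.0)
    mean_dur = float(np.mean(durations)) if durations else 0.0
    return count, per_min, mean_dur


def _allocate_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n subjects to the three labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.asarray(proportions, dtype=float)
    if p.size != len(LABELS) or (p < 0).any():
        raise ValueError("class_mix must be three non-negative proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    raw = p * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts.tolist()


def _draw_deciles(label: str, rng: np.random.Generator, profile: str):
    """Pattern-contribution deciles (periodic, intermediate, normal)."""
    if profile == "study":
        if label == "normal":
            dn = int(rng.integers(7, 11))
            dp = int(rng.integers(0, 10 - dn + 1))
            di = 10 - dn - dp
        elif label == "periodic-like":
            dp = int(rng.integers(7, 11))
            dn = int(rng.integers(0, 10 - dp + 1))
            di = 10 - dp - dn
        else:  # neither normal nor periodic-like reaches 70%
            di = int(rng.integers(4, 7))
            dn = int(rng.integers(0, 10 - di + 1))
            dp = 10 - di - dn
    elif profile == "separated":
        # deciles concentrated so the periodic-like contribution cleanly maps
        # to A / B / C under the (d1, d2) = (3, 6) outcome discretization
        if label == "normal":
            dp = int(rng.integers(0, 2))
            di = int(rng.integers(0, 2))
            dn = 10 - dp - di
        elif label == "intermediate":
            dp = int(rng.integers(4, 6))
            dn = 10 - dp
            di = 0
        else:
            dp = int(rng.integers(9, 11))
            dn = 10 - dp
            di = 0
    else:
        raise ValueError(f"unknown decile profile {profile!r}")
    return dp, di, dn


def _expert_label(dp: int, dn: int) -> int:
    if dn >= 7:
        return EXPERT_CODE["normal"]
    if dp >= 7:
        return EXPERT_CODE["periodic-like"]
    return EXPERT_CODE["intermediate"]


def _make_subject(
    subject_id: int,
    label: str,
    rng: np.random.Generator,
    *,
    rate: float,
    duration_s: float,
    with_signal: bool,
    profile: str,
    anthro: dict,
):
    cfg = anthro[label]
    sex = "M" if rng.random() < cfg["male_frac"] else "F"
    height = float(round(rng.normal(177, 7) if sex == "M" else rng.normal(164, 6)))
    bmi_draw = float(np.clip(rng.normal(cfg["bmi_mean"], cfg["bmi_sd"]), 17.0, 45.0))
    weight = round(bmi_draw * (height / 100.0) ** 2, 2)
    hip = round(float(np.clip(rng.normal(103, 8), 80.0, 140.0)), 1)
    whr_draw = float(np.clip(rng.normal(cfg["whr_mean"], cfg["whr_sd"]), 0.6, 1.2))
    waist = float(round(whr_draw * hip))
    bmi = weight / (height / 100.0) ** 2
    whr = waist / hip
    age = int(np.clip(round(rng.normal(51.4, 11.0)), 18, 90))

    dp, di, dn = _draw_deciles(label, rng, profile)

    if profile == "separated":
        # the well-separated regime keeps the nuisance morphology tight: a
        # narrow breath-period band stops wavelet energy drifting across an
        # octave between subjects, leaving the pattern mixture as the only
        # systematic source of descriptor variation
        period = float(rng.uniform(3.8, 4.6))
        mod_period = float(rng.uniform(36.0, 44.0))
    else:
        period = float(rng.uniform(3.0, 6.0))
        mod_period = float(rng.uniform(30.0, 60.0))
    params = BreathingParams(
        breath_period_s=period,
        breath_amplitude=float(rng.uniform(0.8, 1.2)),
        triangle_duty=float(rng.uniform(0.5, 0.7)),
        modulation_period_s=mod_period,
        apnea_rate_per_min=LABEL_APNEA_RATE[label],
        apnea_duration_cycles=5.0,
        noise_sd=0.05,
    )
    # ten segments, one per contribution decile, in shuffled order
    seg_types = ["periodic-like"] * dp + ["intermediate"] * di + ["normal"] * dn
    seg_types = [seg_types[i] for i in rng.permutation(10)]
    seg_len = duration_s / 10.0

    def depth_fn(t: float) -> float:
        idx = min(int(t / seg_len), 9)
        return SEGMENT_DEPTH[seg_types[idx]]

    samples, events = _render(params, duration_s, rate, rng, depth_fn, fill=with_signal)
    signal = Signal(samples=samples, rate=rate) if with_signal else None

    record = SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        weight=weight,
        height=height,
        waist=waist,
        hip=hip,
        bmi=bmi,
        whr=whr,
        apnea_count=len(events),
        apneas_per_min=len(events) / (duration_s / 60.0),
        apnea_mean_duration=(
            float(np.mean([e.duration_s for e in events])) if events else 0.0
        ),
        contribution_periodic=dp,
        contribution_intermediate=di,
        contribution_normal=dn,
        expert_label=_expert_label(dp, dn),
    )
    return record, signal


def generate_cohort(
    n: int,
    class_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
    *,
    rate: float = DEFAULT_RATE,
    signal_duration_s: float = 160.0,
    with_signals: bool = True,
    decile_profile: str = "study",
    anthro: dict | None = None,
):
    """Generate ``n`` subjects as ``(SubjectRecord, Signal)`` pairs.

    ``class_mix`` gives the proportions of (normal, intermediate,
    periodic-like) subjects; counts are allocated by largest remainder so a
    mix proportional to integer counts reproduces them exactly.  Each
    subject's signal is a concatenation of ten pattern segments matching its
    contribution deciles.  ``decile_profile='separated'`` concentrates the
    periodic-like deciles into cleanly separated low/middle/high bands, which
    is the well-separated regime used for end-to-end recovery experiments.
    """
    counts = _allocate_counts(n, class_mix)
    anthro = anthro or DEFAULT_ANTHRO
    labels = [lab for lab, c in zip(LABELS, counts) for _ in range(c)]
    master = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(master.spawn(1)[0])
    labels = [labels[i] for i in shuffle_rng.permutation(n)]
    out = []
    for sid, (label, child) in enumerate(zip(labels, master.spawn(n)), start=1):
        rng = np.random.default_rng(child)
        out.append(
            _make_subject(
                sid, label, rng,
                rate=rate, duration_s=signal_duration_s,
                with_signal=with_signals, profile=decile_profile, anthro=anthro,
            )
        )
    return out


def _records_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id, "age": r.age, "sex": r.sex,
            "weight_kg": r.weight, "height_cm": r.height, "waist_cm": r.waist,
            "hip_cm": r.hip, "bmi": r.bmi, "whr": r.whr,
            "apnea_count": r.apnea_count, "apneas_per_min": r.apneas_per_min,
            "apnea_mean_dur_s": r.apnea_mean_duration,
            "contrib_periodic": r.contribution_periodic,
            "contrib_intermediate": r.contribution_intermediate,
            "contrib_normal": r.contribution_normal,
            "expert_label": r.expert_label,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(
    records: Sequence[SubjectRecord],
    signals: Sequence[Signal],
    directory: str | Path,
    *,
    rate: float | None = None,
    seed: int | None = None,
    params: dict | None = None,
) -> list[Path]:
    """Write a cohort CSV, one signal file per subject, and a JSON manifest.

    Signal files hold one ASCII float per line; the sampling rate lives in the
    manifest, not in the signal files.
    """
    if len(records) != len(signals):
        raise ValueError("records and signals must be aligned")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = directory / "cohort.csv"
    # repr() of a python float is its shortest exact representation: record
    # fields round-trip through the CSV bit-exactly
    _records_frame(records).to_csv(csv_path, index=False,
                                   float_format=lambda v: repr(float(v)))
    written.append(csv_path)
    rates = {s.rate for s in signals}
    if rate is None:
        if len(rates) > 1:
            raise ValueError("signals have mixed rates; pass rate explicitly")
        rate = rates.pop() if rates else DEFAULT_RATE
    for rec, sig in zip(records, signals):
        p = directory / f"subject_{rec.subject_id}.txt"
        np.savetxt(p, sig.samples, fmt="%.8g")
        written.append(p)
    manifest = {
        "rate": rate,
        "seed": seed,
        "n_subjects": len(records),
        "generator_params": params or {},
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    written.append(mpath)
    return written


def read_cohort(directory: str | Path, load_signals: bool = True):
    """Round-trip reader for :func:`write_cohort` output."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    df = pd.read_csv(directory / "cohort.csv", float_precision="round_trip")
    records, signals = [], []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=int(row.subject_id), age=int(row.age), sex=str(row.sex),
                weight=float(row.weight_kg), height=float(row.height_cm),
                waist=float(row.waist_cm), hip=float(row.hip_cm),
                bmi=float(row.bmi), whr=float(row.whr),
                apnea_count=int(row.apnea_count),
                apneas_per_min=float(row.apneas_per_min),
                apnea_mean_duration=float(row.apnea_mean_dur_s),
                contribution_periodic=int(row.contrib_periodic),
                contribution_intermediate=int(row.contrib_intermediate),
                contribution_normal=int(row.contrib_normal),
                expert_label=int(row.expert_label),
            )
        )
        if load_signals:
            samples = np.loadtxt(directory / f"subject_{int(row.subject_id)}.txt")
            signals.append(Signal(samples=samples, rate=float(manifest["rate"])))
    return records, signals, manifest
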