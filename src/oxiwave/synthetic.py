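"""Synthetic overnight SpO2 recordings with known ground truth.

The generator emulates the gross morphology of a nocturnal pulse-oximetry
trace: a subject-specific baseline in the 95-99% range, a slow sinusoidal
drift (posture/perfusion changes), smooth low-bandwidth sensor noise, and
transient desaturation events planted by a Poisson process whose per-hour
rate is the subject's true event rate.  Each event is a raised-cosine fall
to (baseline - depth) over 30% of its duration followed by a raised-cosine
recovery; depths are capped at 0.6 x duration (%/s budget) so that event
slopes stay below the 4%/s artifact-rejection threshold and preprocessing
cannot erase planted truth.  Samples are clipped to [70, 100] and
quantized to 0.01%, matching the resolution of clinical recordings.

For labeling, the planted event rate is identified with the AHI (every
simulated respiratory event causes a >=3% desaturation).  That idealized
equivalence is a property of the simulation, not of real physiology,
where ODI3 systematically undercounts the AHI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import round_half_away
from .records import AHI_CUTOFF, SpO2Record


@dataclass(frozen=True)
class CohortSpec:
    """Sampling laws and sizes defining a synthetic cohort.

    True event rates are log-uniform: 0.5-4.5 e/h for the AHI < 5 group
    and 5-30 e/h for the AHI >= 5 group, so class labels are always
    consistent with the planted rate.  Depths are uniform on [3, 15] %
    (subject to the slope-budget cap), durations uniform on [10, 60] s,
    baselines uniform on [95, 99] %.
    """

    n_subjects: int = 120
    positive_fraction: float = 0.5
    rate_range_negative: tuple[float, float] = (0.5, 4.5)
    rate_range_positive: tuple[float, float] = (5.0, 30.0)
    event_depth_pct: tuple[float, float] = (3.0, 15.0)
    event_duration_s: tuple[float, float] = (10.0, 60.0)
    baseline_pct: tuple[float, float] = (95.0, 99.0)
    drift_amp_pct: float = 1.0
    drift_period_h: float = 1.0
    noise_sd_pct: float = 0.15
    duration_h: float = 8.0
    fs: float = 25.0
    seed: int = 0

    #: events are separated by at least this many seconds of baseline
    min_gap_s: float = 20.0


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian noise drawn at 1 Hz and linearly interpolated to fs.

    Pulse oximeters average over seconds internally; drawing white noise
    at the full 25 Hz would create sample-to-sample slopes far above the
    4%/s artifact threshold, which real oximetry does not show.
    """
    n_knots = max(int(np.ceil(n / fs)) + 1, 2)
    knots = rng.normal(0.0, sd, size=n_knots)
    t = np.arange(n) / fs
    return np.interp(t, np.arange(n_knots), knots)


def _event_dip(fs: float, duration_s: float, depth: float) -> np.ndarray:
    """Raised-cosine fall (30% of the duration) and recovery (70%)."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    fall_t = 0.3 * duration_s
    dip = np.where(
        t < fall_t,
        0.5 * (1.0 - np.cos(np.pi * t / fall_t)),
        0.5 * (1.0 + np.cos(np.pi * (t - fall_t) / (duration_s - fall_t))),
    )
    return depth * dip


def simulate_recording(
    spec: CohortSpec,
    seed,
    *,
    rate: float | None = None,
    subject_id: str = "",
) -> tuple[SpO2Record, pd.DataFrame]:
    """Simulate one overnight recording; byte-reproducible per seed.

    ``rate`` fixes the true event rate (events/hour); when omitted, the
    subject's class is drawn from ``positive_fraction`` and the rate from
    that class's law.  Returns the record and a ground-truth table with
    one row per planted event (start_s, end_s, depth_pct).
    """
    if spec.duration_h <= 0:
        raise ValueError("duration_h must be positive")
    rng = np.random.default_rng(seed)
    if rate is None:
        positive = rng.random() < spec.positive_fraction
        lo, hi = (
            spec.rate_range_positive if positive else spec.rate_range_negative
        )
        rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    fs = spec.fs
    total_s = spec.duration_h * 3600.0
    n = int(round(total_s * fs))
    baseline = rng.uniform(*spec.baseline_pct)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    drift = spec.drift_amp_pct * np.sin(
        2.0 * np.pi * t / (spec.drift_period_h * 3600.0) + phase
    )
    x = baseline + drift + _smooth_noise(rng, n, fs, spec.noise_sd_pct)

    n_events = rng.poisson(rate * spec.duration_h)
    truth_rows = []
    if n_events > 0:
        durations = rng.uniform(*spec.event_duration_s, size=n_events)
        depths = rng.uniform(*spec.event_depth_pct, size=n_events)
        # slope budget: a raised-cosine fall over 0.3*dur peaks at
        # (pi/2)*depth/(0.3*dur); capping depth at 0.6*dur keeps it ~3.1%/s
        depths = np.minimum(depths, 0.6 * durations)
        occupied = durations + spec.min_gap_s
        free = total_s - float(occupied.sum())
        if free <= 0:
            raise ValueError(
                f"rate {rate:g} e/h cannot be placed without overlapping events"
            )
        # uniform non-overlapping placement: drop events into the free space
        offsets = np.sort(rng.uniform(0.0, free, size=n_events))
        starts = offsets + np.concatenate(([0.0], np.cumsum(occupied)[:-1]))
        for s, d, dep in zip(starts, durations, depths):
            i0 = int(round(s * fs))
            dip = _event_dip(fs, d, dep)
            i1 = min(i0 + dip.size, n)
            x[i0:i1] -= dip[: i1 - i0]
            truth_rows.append({"start_s": s, "end_s": s + d, "depth_pct": dep})

    x = round_half_away(np.clip(x, 70.0, 100.0), 2)
    rec = SpO2Record(x, fs, subject_id=subject_id)
    truth = pd.DataFrame(truth_rows, columns=["start_s", "end_s", "depth_pct"])
    return rec, truth


@dataclass
class CohortTruth:
    """Labels and per-subject ground-truth event tables."""

    labels: pd.DataFrame  # columns: subject_id, ahi, group
    events: dict[str, pd.DataFrame] = field(default_factory=dict)


def draw_cohort_rates(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """True event rates for a balanced cohort: positives first."""
    n_pos = int(round(spec.n_subjects * spec.positive_fraction))
    n_neg = spec.n_subjects - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cohort must contain both classes")
    pos = np.exp(
        rng.uniform(*np.log(spec.rate_range_positive), size=n_pos)
    )
    neg = np.exp(
        rng.uniform(*np.log(spec.rate_range_negative), size=n_neg)
    )
    return np.concatenate([pos, neg])


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[SpO2Record], pd.DataFrame, CohortTruth]:
    """Simulate a full cohort; returns (recordings, labels, truth).

    The label table has one row per subject with the planted rate as its
    AHI and the implied binary group.  Per-subject seeds are spawned from
    the cohort seed, so the cohort is reproducible end to end.
    """
    if spec.n_subjects < 2:
        raise ValueError("need at least two subjects")
    ss = np.random.SeedSequence(spec.seed)
    rate_rng = np.random.default_rng(ss.spawn(1)[0])
    rates = draw_cohort_rates(spec, rate_rng)
    children = ss.spawn(spec.n_subjects + 1)[1:]
    records, rows, events = [], [], {}
    for i, (rate, child) in enumerate(zip(rates, children)):
        sid = f"subj{i:04d}"
        rec, truth = simulate_recording(spec, child, rate=rate, subject_id=sid)
        records.append(rec)
        events[sid] = truth
        rows.append(
            {"subject_id": sid, "ahi": float(rate), "group": rate >= AHI_CUTOFF}
        )
    labels = pd.DataFrame(rows)
    return records, labels, CohortTruth(labels=labels, events=events)


def iter_cohort(spec: CohortSpec):
    """Memory-light variant of :func:`simulate_cohort`: yields
    (subject_id, rate, record, truth) one subject at a time with the same
    seeds and rates as the list-returning form."""
    if spec.n_subjects < 2:
        raise ValueError("need at least two subjects")
    ss = np.random.SeedSequence(spec.seed)
    rate_rng = np.random.default_rng(ss.spawn(1)[0])
    rates = draw_cohort_rates(spec, rate_rng)
    children = ss.spawn(spec.n_subjects + 1)[1:]
    for i, (rate, child) in enumerate(zip(rates, children)):
        sid = f"subj{i:04d}"
        rec, truth = simulate_recording(spec, child, rate=rate, subject_id=sid)
        yield sid, float(rate), rec, truth
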