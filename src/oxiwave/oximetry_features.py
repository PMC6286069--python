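"""Conventional oximetry features: ODI3, time-domain moments, Welch PSD.

ODI3 counts desaturations of at least 3% below the running baseline per
hour of valid recording.  The baseline is the maximum of the preceding
100 s of signal (a running-max tracker, the usual operational definition
in automated oximetry scoring); an event starts when saturation falls 3%
or more below it and ends on recovery to within 1% of it.  Duration gates
of 5-180 s exclude noise spikes and slow drifts.  All thresholds are
keyword parameters.

Spectral features come from a Welch periodogram (2**13-sample Hamming
window, 50% overlap, 2**14-point DFT at 25 Hz) summarized over the
0.018-0.050 Hz band in which apneic events recur, plus the spectral
entropy of the full one-sided spectrum.  The signal mean is retained
before the PSD and the 0 Hz bin participates in the entropy
normalization; both are exposed as toggles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import welch

from ._stats import four_moments, shannon_entropy
from .errors import TooShortError
from .records import SpO2Record

#: Recurrence band of apneic events in the saturation spectrum (Hz).
PSD_BAND = (0.018, 0.050)

WELCH_NPERSEG = 2**13
WELCH_NFFT = 2**14


@dataclass(frozen=True)
class DesaturationEvent:
    """One scored desaturation: [start_s, end_s), depth below baseline."""

    start_s: float
    end_s: float
    depth_pct: float
    baseline_pct: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_desaturations(
    rec: SpO2Record,
    *,
    min_drop_pct: float = 3.0,
    recovery_margin_pct: float = 1.0,
    baseline_window_s: float = 100.0,
    min_duration_s: float = 5.0,
    max_duration_s: float = 180.0,
) -> list[DesaturationEvent]:
    """Score desaturation events against a running-max baseline.

    The baseline at sample t is the maximum of the preceding
    ``baseline_window_s`` seconds (excluding t itself).  A candidate event
    is a maximal run of samples at least ``recovery_margin_pct`` below
    baseline; it is kept if it dips at least ``min_drop_pct`` below
    baseline somewhere and its duration is inside the gates.  Events are
    returned sorted and non-overlapping by construction.
    """
    x = rec.samples
    w = int(round(baseline_window_s * rec.fs))
    if x.size <= w:
        raise TooShortError(
            f"recording shorter than the {baseline_window_s:g} s baseline window"
        )
    # trailing window [t-w+1, t], shifted one sample to exclude t
    trail = maximum_filter1d(x, size=w, mode="nearest", origin=(w - 1) // 2)
    baseline = np.empty_like(x)
    baseline[0] = x[0]
    baseline[1:] = trail[:-1]

    shallow = x <= baseline - recovery_margin_pct
    deep = x <= baseline - min_drop_pct

    events: list[DesaturationEvent] = []
    # run-length extraction of candidate (shallow) regions
    padded = np.concatenate(([False], shallow, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    for s, e in zip(run_starts, run_ends):
        if not deep[s:e].any():
            continue
        dur = (e - s) / rec.fs
        if dur < min_duration_s or dur > max_duration_s:
            continue
        drop = baseline[s:e] - x[s:e]
        k = int(np.argmax(drop))
        events.append(
            DesaturationEvent(
                start_s=s / rec.fs,
                end_s=e / rec.fs,
                depth_pct=float(drop[k]),
                baseline_pct=float(baseline[s + k]),
            )
        )
    return events


def odi3(rec: SpO2Record, **kwargs) -> float:
    """Desaturation events (>=3% below baseline) per hour of valid
    recording time."""
    hours = rec.valid_duration_s / 3600.0
    if hours <= 0:
        raise ValueError("recording has no valid samples")
    return len(detect_desaturations(rec, **kwargs)) / hours


@dataclass(frozen=True)
class TimeMoments:
    m1_t: float
    m2_t: float
    m3_t: float
    m4_t: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def time_moments(rec: SpO2Record) -> TimeMoments:
    """First-to-fourth statistical moments of the valid samples."""
    x = rec.samples[rec.valid_mask]
    m1, m2, m3, m4 = four_moments(x)
    return TimeMoments(m1, m2, m3, m4)


def welch_psd(
    rec: SpO2Record,
    *,
    nperseg: int = WELCH_NPERSEG,
    nfft: int = WELCH_NFFT,
    remove_mean: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD with a Hamming window and 50% overlap.

    Returns (frequencies, psd).  The mean is retained by default; pass
    ``remove_mean=True`` to detrend by the constant.
    """
    if rec.n_samples < nperseg:
        raise TooShortError(
            f"Welch PSD needs at least {nperseg} samples, got {rec.n_samples}"
        )
    f, p = welch(
        rec.samples,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend="constant" if remove_mean else False,
        scaling="density",
        return_onesided=True,
    )
    return f, p


@dataclass(frozen=True)
class SpectralFeatures:
    m1_psd: float
    m2_psd: float
    m3_psd: float
    m4_psd: float
    max_psd: float
    se_psd: float
    band: tuple[float, float] = PSD_BAND

    def as_dict(self) -> dict[str, float]:
        d = dict(self.__dict__)
        d.pop("band")
        return d


def psd_features(
    frequencies: np.ndarray,
    psd: np.ndarray,
    *,
    band: tuple[float, float] = PSD_BAND,
    exclude_dc_from_entropy: bool = False,
) -> SpectralFeatures:
    """Moments and maximum of the PSD inside the band of interest (bin
    centers in the closed interval) plus the spectral entropy of the full
    spectrum."""
    frequencies = np.asarray(frequencies, dtype=float)
    psd = np.asarray(psd, dtype=float)
    in_band = (frequencies >= band[0]) & (frequencies <= band[1])
    if not in_band.any():
        raise ValueError(f"no frequency bins inside band {band}")
    amp = psd[in_band]
    m1, m2, m3, m4 = four_moments(amp)
    full = psd[frequencies > 0] if exclude_dc_from_entropy else psd
    return SpectralFeatures(
        m1_psd=m1,
        m2_psd=m2,
        m3_psd=m3,
        m4_psd=m4,
        max_psd=float(amp.max()),
        se_psd=shannon_entropy(full),
        band=band,
    )
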