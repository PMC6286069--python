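"""Reading, validation, preprocessing and segmentation of SpO2 recordings.

The preprocessing chain mirrors standard oximetry practice for pediatric
apnea screening: saturation values below 50% and intervals steeper than
4%/s are treated as sensor artifacts, recordings are brought to a common
25 Hz rate, and samples are rounded to two decimals so that recordings
from different devices share one resolution.  Artifact samples are masked
and bridged by linear interpolation (rather than dropped) so that the
fixed-length dyadic segmentation downstream stays aligned in time;
recordings with more than 50% artifact samples are rejected.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from ._stats import round_half_away
from .errors import FormatError, QualityError, TooShortError
from .records import SEGMENT_LENGTH, Segment, SpO2Record

logger = logging.getLogger(__name__)

TARGET_FS = 25.0

#: Artifact rules: samples below this saturation are physiologically
#: implausible, and first-difference slopes above this magnitude (%/s)
#: indicate probe disconnection or motion.
MIN_VALID_SPO2 = 50.0
MAX_SLOPE_PCT_PER_S = 4.0

#: Recordings with more than this fraction of artifact samples are rejected.
MAX_INVALID_FRACTION = 0.5


# ---------------------------------------------------------------------------
# reading


def read_spo2(
    path,
    format: str = "csv",
    fs: float | None = None,
    channel: str | None = None,
    subject_id: str | None = None,
) -> SpO2Record:
    """Read a single-channel SpO2 recording from CSV or EDF.

    CSV dialects accepted: a header row with ``time_s,spo2`` columns (the
    rate is inferred from the time stamps unless ``fs`` overrides it), or a
    single ``spo2`` column -- with or without header -- plus a declared
    ``fs``.  For EDF, the channel whose label contains "SpO2"
    (case-insensitive) is used unless ``channel`` names one explicitly.
    """
    path = str(path)
    sid = subject_id if subject_id is not None else path
    if format == "csv":
        return _read_csv(path, fs, sid)
    if format == "edf":
        return _read_edf(path, channel, sid)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'edf'")


def _read_csv(path: str, fs: float | None, subject_id: str) -> SpO2Record:
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise IOError(f"cannot read {path}") from exc

    tokens = [t.strip().lower() for t in first.strip().split(",")]
    if "spo2" in tokens and "time_s" in tokens:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        t = df["time_s"].to_numpy(float)
        x = df["spo2"].to_numpy(float)
        if x.size == 0:
            raise FormatError(f"{path}: empty signal")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise FormatError(f"{path}: time stamps are not strictly increasing")
            inferred = 1.0 / float(np.median(dt))
        else:
            inferred = None
        if fs is None:
            if inferred is None:
                raise FormatError(f"{path}: cannot infer fs from a single row")
            fs = inferred
    elif tokens == ["spo2"]:
        if fs is None:
            raise ValueError(f"{path}: single-column CSV requires a declared fs")
        x = pd.read_csv(path)["spo2"].to_numpy(float)
    else:
        # headerless single column
        if fs is None:
            raise ValueError(f"{path}: headerless CSV requires a declared fs")
        try:
            x = pd.read_csv(path, header=None)[0].to_numpy(float)
        except (ValueError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"{path}: cannot parse as CSV of numbers") from exc
    if x.size == 0:
        raise FormatError(f"{path}: empty signal")
    return SpO2Record(samples=x, fs=float(fs), subject_id=subject_id)


def _read_edf(path: str, channel: str | None, subject_id: str) -> SpO2Record:
    import mne  # deferred: slow import, only needed for EDF input

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for broken files
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    names = raw.ch_names
    if channel is not None:
        if channel not in names:
            raise FormatError(f"{path}: no channel named {channel!r} (have {names})")
        pick = channel
    else:
        matches = [n for n in names if "spo2" in n.lower()]
        if not matches:
            raise FormatError(f"{path}: no SpO2 channel found among {names}")
        pick = matches[0]
    x = raw.get_data(picks=[pick])[0]
    if x.size == 0:
        raise FormatError(f"{path}: empty signal")
    return SpO2Record(samples=x, fs=float(raw.info["sfreq"]), subject_id=subject_id)


# ---------------------------------------------------------------------------
# preprocessing


def remove_artifacts(rec: SpO2Record) -> SpO2Record:
    """Mask artifact samples and bridge them by linear interpolation.

    A sample is an artifact if its value is below 50% or if it is an
    endpoint of a first difference whose slope magnitude exceeds 4%/s.
    Because interpolated bridges must themselves satisfy the rules, the
    mask-and-interpolate step is iterated to a fixed point; this makes the
    operation idempotent.

    Raises
    ------
    QualityError
        If more than half of the samples end up masked, or no valid
        sample remains.
    """
    samples = rec.samples.copy()
    mask = rec.valid_mask.copy()
    n = samples.size
    if n == 0:
        raise QualityError("empty recording")

    for _ in range(1000):
        bad = samples < MIN_VALID_SPO2
        if n > 1:
            steep = np.abs(np.diff(samples)) * rec.fs > MAX_SLOPE_PCT_PER_S
            bad[:-1] |= steep
            bad[1:] |= steep
        bad &= mask
        if not bad.any():
            break
        mask &= ~bad
        if not mask.any():
            raise QualityError("no valid samples remain after artifact removal")
        samples = _bridge_invalid(samples, mask)

    frac = 1.0 - float(mask.mean())
    logger.info("fraction_invalid=%.4f for %s", frac, rec.subject_id or "<record>")
    if frac > MAX_INVALID_FRACTION:
        raise QualityError(
            f"{frac:.1%} of samples are artifacts (> {MAX_INVALID_FRACTION:.0%}); "
            "recording rejected"
        )
    return SpO2Record(samples, rec.fs, mask, rec.subject_id)


def _bridge_invalid(samples: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked samples by linear interpolation between flanking
    valid samples; runs touching the edges take the nearest valid value."""
    idx = np.arange(samples.size)
    out = samples.copy()
    out[~mask] = np.interp(idx[~mask], idx[mask], samples[mask])
    return out


def resample_to_25hz(rec: SpO2Record) -> SpO2Record:
    """Band-limited polyphase resampling to the common 25 Hz rate.

    Identity when the record is already at 25 Hz.  The validity mask is
    carried over by nearest-neighbour lookup so valid-time accounting
    survives the rate change.
    """
    if rec.fs == TARGET_FS:
        return rec.copy()
    ratio = Fraction(TARGET_FS / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    y = resample_poly(rec.samples, up, down, padtype="line")
    n_new = y.size
    src = np.clip(
        np.round(np.arange(n_new) * rec.fs / TARGET_FS).astype(int),
        0,
        rec.n_samples - 1,
    )
    return SpO2Record(y, TARGET_FS, rec.valid_mask[src], rec.subject_id)


def quantize(rec: SpO2Record) -> SpO2Record:
    """Round samples to two decimals, half away from zero (0.01% device
    resolution)."""
    return SpO2Record(
        round_half_away(rec.samples, 2), rec.fs, rec.valid_mask.copy(), rec.subject_id
    )


def preprocess(rec: SpO2Record) -> SpO2Record:
    """Full chain: artifact removal -> resample to 25 Hz -> quantize."""
    return quantize(resample_to_25hz(remove_artifacts(rec)))


# ---------------------------------------------------------------------------
# segmentation


def segment(rec: SpO2Record, length: int = SEGMENT_LENGTH) -> list[Segment]:
    """Cut the recording into consecutive non-overlapping windows of
    ``length`` samples (default 2**13); a trailing remainder shorter than
    one window is dropped rather than zero-padded, since padding would
    distort the low-frequency coefficients the wavelet features rely on.
    """
    n_seg = rec.n_samples // length
    if n_seg == 0:
        raise TooShortError(
            f"recording has {rec.n_samples} samples; at least {length} required"
        )
    return [
        Segment(rec.samples[i * length : (i + 1) * length], i, rec.fs)
        for i in range(n_seg)
    ]


def segment_count(n_samples: int, length: int = SEGMENT_LENGTH) -> int:
    return n_samples // length


def dyadic_depth_for(duration_s: float = 300.0, fs: float = TARGET_FS) -> int:
    """Depth of the dyadic decomposition implied by the analysis window:
    the exponent of the smallest power of two covering ``duration_s``
    seconds at ``fs`` Hz (5 min at 25 Hz -> 2**13 samples -> depth 13)."""
    return int(math.ceil(math.log2(duration_s * fs)))
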