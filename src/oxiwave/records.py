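"""Core in-memory containers for oximetry signals and subject labels.

An :class:`SpO2Record` holds a sampled blood-oxygen-saturation signal in
percent together with its sampling rate and a per-sample validity mask.
The mask marks samples that were flagged as artifacts; their values are
bridged by interpolation so that fixed-length segmentation and spectral
analysis remain possible, but they are excluded from time statistics and
from the valid-time denominator of hour-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import TooShortError

#: Threshold (events/hour) separating moderate-to-severe disease from the rest.
AHI_CUTOFF = 5.0

#: Segment length used for dyadic wavelet analysis: the smallest power of two
#: covering 5 minutes at 25 Hz (2**13 samples = 5.46 min).
SEGMENT_LENGTH = 8192


@dataclass
class SpO2Record:
    """A single-channel SpO2 recording.

    Parameters
    ----------
    samples
        Saturation values in percent.
    fs
        Sampling rate in Hz.
    valid_mask
        Boolean array, same length as ``samples``; ``False`` marks samples
        that were identified as artifacts (their stored value is
        interpolated).
    subject_id
        Opaque identifier used to join with label tables.
    """

    samples: np.ndarray
    fs: float
    valid_mask: np.ndarray = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.samples.shape:
            raise ValueError("valid_mask must have the same length as samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds."""
        return self.samples.size / self.fs

    @property
    def valid_duration_s(self) -> float:
        """Seconds of artifact-free signal."""
        return float(self.valid_mask.sum()) / self.fs

    @property
    def fraction_invalid(self) -> float:
        """Fraction of samples flagged as artifacts."""
        if self.samples.size == 0:
            return 0.0
        return 1.0 - float(self.valid_mask.mean())

    def copy(self) -> "SpO2Record":
        return replace(
            self, samples=self.samples.copy(), valid_mask=self.valid_mask.copy()
        )


@dataclass(frozen=True)
class SubjectLabel:
    """Diagnostic label of one subject: the apnea-hypopnea index (events/h)
    and the binary group it implies at the 5 e/h cutoff."""

    subject_id: str
    ahi: float

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ValueError("AHI must be non-negative")

    @property
    def group(self) -> bool:
        """True for the moderate-to-severe group (AHI >= 5 e/h)."""
        return self.ahi >= AHI_CUTOFF


@dataclass(frozen=True)
class Segment:
    """A fixed-length analysis window of 2**13 saturation samples."""

    samples: np.ndarray = field(repr=False)
    segment_index: int = 0
    fs: float = 25.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size != SEGMENT_LENGTH:
            raise TooShortError(
                f"segment must hold exactly {SEGMENT_LENGTH} samples, "
                f"got {self.samples.size}"
            )
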