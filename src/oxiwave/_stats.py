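"""Shared statistical helpers.

All moment features in the pipeline use the same conventions: population
(biased) variance, skewness as the standardized third central moment and
kurtosis as the raw standardized fourth central moment (not excess), so a
Gaussian has kurtosis 3.  Entropies are reported in nats.
"""

from __future__ import annotations

import warnings

import numpy as np


def four_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population variance, skewness and (non-excess) kurtosis.

    For a constant input the standardized moments are undefined; they are
    returned as NaN and a warning is emitted.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("at least two samples are required for moments")
    m1 = float(np.mean(x))
    d = x - m1
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        warnings.warn(
            "zero variance: skewness and kurtosis are undefined", RuntimeWarning
        )
        return m1, 0.0, float("nan"), float("nan")
    m3 = float(np.mean(d**3)) / m2**1.5
    m4 = float(np.mean(d**4)) / m2**2
    return m1, m2, m3, m4


def shannon_entropy(weights: np.ndarray) -> float:
    """Entropy in nats of the distribution obtained by normalizing
    ``weights`` to sum to one, with the 0*ln(0) := 0 convention."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero weight vector")
    p = w / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def round_half_away(x: np.ndarray, decimals: int = 2) -> np.ndarray:
    """Round half away from zero (clinical-display convention), unlike
    numpy's round-half-to-even."""
    x = np.asarray(x, dtype=float)
    scale = 10.0**decimals
    return np.copysign(np.floor(np.abs(x) * scale + 0.5), x) / scale
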