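"""Fast correlation-based filter (FCBF) feature selection with a
bootstrap-consensus rule.

FCBF ranks features by their symmetrical uncertainty (SU) with the target
-- a normalization of information gain to [0, 1] --

    SU(x, y) = 2 * IG(x|y) / (H(x) + H(y)),   IG(x|y) = H(x) - H(x|y),

then scans the ranking from the top, discarding any lower-ranked feature
that shares more information with a surviving higher-ranked feature than
with the target (SU(x_j, x_i) >= SU(x_j, y)).  Entropies are Shannon
entropies in nats computed from empirical joint frequencies of discretized
values; continuous features are discretized into equal-frequency bins.

To decouple the selected subset from one particular sample, FCBF is run on
bootstrap replicates (sampling subjects with replacement); features chosen
in more than half of the replicates form the consensus subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BINS = 10
DEFAULT_REPLICATES = 1000


def _entropy_from_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def symmetric_uncertainty(x, y) -> float:
    """SU(x, y) in [0, 1] between two discrete vectors (nats throughout).

    SU is 1 when the vectors determine each other, 0 when independent.
    When both entropies are zero (both vectors constant), SU is defined
    as 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size == 0:
        raise ValueError("empty input")
    _, xc = np.unique(x, return_inverse=True)
    _, yc = np.unique(y, return_inverse=True)
    hx = _entropy_from_codes(xc)
    hy = _entropy_from_codes(yc)
    denom = hx + hy
    if denom == 0.0:
        return 0.0
    ny = int(yc.max()) + 1
    hxy = _entropy_from_codes(xc * ny + yc)
    ig = hx - (hxy - hy)  # H(x) - H(x|y)
    return float(np.clip(2.0 * ig / denom, 0.0, 1.0))


def discretize(values, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency (quantile) binning into integer codes 0..bins-1.

    Samples are ordered by value (ties broken by position, stable sort)
    and cut into ``bins`` contiguous rank blocks; with fewer distinct
    values than bins, fewer bins are realized.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    order = np.argsort(v, kind="stable")
    codes = np.empty(v.size, dtype=np.int64)
    codes[order] = np.arange(v.size) * bins // v.size
    # identical values must land in one bin: collapse ties onto the bin of
    # their first occurrence (lowest rank under the stable sort)
    _, first, inverse = np.unique(v, return_index=True, return_inverse=True)
    return codes[first][inverse]


def fcbf(
    table: pd.DataFrame, target, *, bins: int = DEFAULT_BINS
) -> list[str]:
    """Relevance/redundancy selection; returns survivors in rank order.

    ``table`` holds one feature per column (continuous values are
    discretized internally); ``target`` is the discrete label vector.
    Features with SU(x, y) = 0 are never selected.  SU ties in the
    ranking are broken by column-name order for determinism.
    """
    if table.shape[1] == 0 or table.shape[0] == 0:
        raise ValueError("empty feature table")
    y = np.asarray(target)
    codes = {c: discretize(table[c].to_numpy(), bins) for c in table.columns}
    su_y = {c: symmetric_uncertainty(codes[c], y) for c in table.columns}
    ranked = sorted(
        (c for c in table.columns if su_y[c] > 0.0),
        key=lambda c: (-su_y[c], c),
    )
    selected: list[str] = []
    for cand in ranked:
        redundant = any(
            symmetric_uncertainty(codes[cand], codes[kept]) >= su_y[cand]
            for kept in selected
        )
        if not redundant:
            selected.append(cand)
    return selected


@dataclass
class SelectionResult:
    """Per-feature bootstrap selection counts and the consensus subset."""

    counts: dict[str, int]
    n_replicates: int
    threshold: float
    subset: list[str] = field(init=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.subset = sorted(
            (f for f, c in self.counts.items() if c > self.threshold),
            key=lambda f: (-self.counts[f], f),
        )


def bootstrap_fcbf(
    table: pd.DataFrame,
    target,
    *,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    threshold_frac: float = 0.5,
    bins: int = DEFAULT_BINS,
) -> SelectionResult:
    """Consensus FCBF over bootstrap replicates of the subjects.

    Each replicate resamples rows with replacement at full size,
    re-discretizes on the replicate's own data, and runs FCBF; a feature
    enters the consensus subset when selected in strictly more than
    ``threshold_frac`` of the replicates (the > 50%-of-runs rule by
    default).  One master seed spawns an independent substream per
    replicate, so results are reproducible for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if table.shape[0] == 0:
        raise ValueError("empty feature table")
    y = pd.Series(np.asarray(target), index=table.index)
    n = table.shape[0]
    counts = {c: 0 for c in table.columns}
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        picked = fcbf(table.iloc[idx], y.iloc[idx].to_numpy(), bins=bins)
        for c in picked:
            counts[c] += 1
    return SelectionResult(
        counts=counts,
        n_replicates=n_replicates,
        threshold=threshold_frac * n_replicates,
        seed=seed,
    )
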