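"""Shared fixtures.

The two session-scoped fixtures run the expensive end-to-end simulations
once (ODI3 parameter recovery over a rate grid; the full 120-subject
screening study) and are shared between property tests and the
acceptance suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import oxiwave as ow

RECOVERY_RATES = (2.0, 5.0, 10.0, 20.0)
RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def odi3_recovery():
    """Measured ODI3 per planted rate: {rate: array of 20 seeded 8 h runs}."""
    spec = ow.CohortSpec(duration_h=8.0)
    out = {}
    for rate in RECOVERY_RATES:
        vals = []
        for s in range(RECOVERY_SEEDS):
            seed = np.random.SeedSequence((int(rate * 10), s))
            rec, _ = ow.simulate_recording(spec, seed, rate=rate)
            vals.append(ow.odi3(ow.preprocess(rec)))
        out[rate] = np.asarray(vals)
    return out


@pytest.fixture(scope="session")
def screening_study():
    """Full protocol on a 120-subject synthetic cohort with 20 pure-noise
    decoy features, bootstrap B=200; conventional seed 0 throughout."""
    X, labels = ow.cohort_feature_table(
        ow.CohortSpec(n_subjects=120, duration_h=8.0, seed=0)
    )
    Xd = ow.add_noise_features(X, 20, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = ow.run_screening_study(Xd, labels, seed=0, n_replicates=200)
    return result
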