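"""Shared fixtures: small synthetic cohorts and recordings.

Everything is generated programmatically with fixed seeds; heavy objects
are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparsecoh.pipeline import cohort_features
from sparsecoh.preprocess import BipolarRecording, segment_epochs
from sparsecoh.simulate import (
    CohortSpec,
    MixingModel,
    SourceSpec,
    simulate_cohort,
    simulate_session,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def shared_source_epochs(
    snr: float,
    duration: float,
    seed: int,
    fs: float = 500.0,
    power: float = 10.0,
    band=(0.2, 10.0),
):
    """Two channels sharing one band-limited source at the given in-band
    SNR, epoched; the wide source band keeps the scored delta bins away
    from window-leakage edge effects."""
    noise_density = power / snr
    noise_sd = np.sqrt(noise_density * fs / 2.0)
    model = MixingModel(
        loadings=np.array([[1.0], [1.0]]),
        noise_sd=noise_sd,
        fs=fs,
        duration=duration,
        channel_names=("A", "B"),
    )
    session = simulate_session(model, [SourceSpec(*band, power)], seed=seed)
    rec = BipolarRecording(samples=session.samples, fs=fs,
                           site_names=("A", "B"))
    return segment_epochs(rec, 2.0)


@pytest.fixture(scope="session")
def small_cohort():
    """4 + 4 participants, short sessions, default planted delta effect."""
    spec = CohortSpec(n_active=4, n_sham=4, duration=150.0, seed=11)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    spec, sessions = small_cohort
    features, cols, log = cohort_features(sessions, spec.montage)
    return features, cols, log
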