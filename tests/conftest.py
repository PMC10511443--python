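"""Shared fixtures: small seeded cohorts and conditioned sessions."""

from __future__ import annotations

import numpy as np
import pytest

from dualppg import (
    PreprocConfig,
    SimulationConfig,
    condition_channel,
    generate_cohort,
)
from dualppg.synthesize import LatentState


def make_latent(**overrides) -> LatentState:
    """A physiologically ordinary latent state, overridable per test."""
    base = dict(
        stroke_volume=70.0,
        peripheral_resistance=1.0,
        heart_rate=72.0,
        contact_pressure_palmar=1500.0,
        contact_pressure_dorsal=1600.0,
        skin_temp_palmar=33.0,
        skin_temp_dorsal=33.2,
        subject_optical_offset=50_000.0,
    )
    base.update(overrides)
    return LatentState(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 2 sessions x 60 s; enough for LOSO and feature checks."""
    cfg = SimulationConfig(
        n_subjects=4, sessions_per_subject=2, session_duration=60.0, seed=123
    )
    dataset, truths = generate_cohort(cfg)
    return cfg, dataset, truths


@pytest.fixture(scope="session")
def conditioned_session(small_cohort):
    """First session of the small cohort with both PPG channels conditioned."""
    cfg, dataset, truths = small_cohort
    session = dataset.sessions[0]
    pcfg = PreprocConfig()
    return (
        session,
        truths[0],
        condition_channel(session.ppg_palmar, pcfg),
        condition_channel(session.ppg_dorsal, pcfg),
        pcfg,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
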