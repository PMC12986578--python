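"""Shared fixtures: small synthetic sessions and deterministic tone bursts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgtf.preprocess import BurstSegment
from emgtf.synth import SessionSpec, generate_session

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 2000.0


def make_tone_burst(
    freq_hz: float,
    duration_ms: float = 250.0,
    fs: float = FS,
    amplitude: float = 1.0,
    group: str = "tone",
) -> BurstSegment:
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    return BurstSegment(
        samples=amplitude * np.cos(2 * np.pi * freq_hz * t),
        fs=fs,
        onset_s=0.0,
        offset_s=n / fs,
        subject=f"{group}_s00",
        group=group,
        burst_id=0,
    )


@pytest.fixture(scope="session")
def small_session():
    """One subject per condition, 10 bursts each: fast shared synthesis."""
    spec = SessionSpec(
        subjects_per_group=1, bursts_per_subject=10, session_length_s=10.0, seed=101
    )
    return generate_session(spec)
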