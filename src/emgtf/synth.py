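"""Synthetic locomotor-EMG generator.

Emulates bipolar hindlimb-muscle EMG recorded during treadmill locomotion
across a progressively impaired condition series: gait-locked bursts of
~250 ms, a broadband stochastic spectrum whose centroid trajectory compresses
toward lower frequencies across post-lesion weeks, phase-dependent amplitude
modulation, and — in the most-impaired condition — an early (~50 ms) energy
transient during recruitment.

The synthesis model is time-varying filtered Gaussian noise: short sqrt-Hann
sub-windows of white noise are shaped in the frequency domain by a Gaussian
band-pass response centred on the condition's centroid trajectory, then
overlap-added (50% hop, power-complementary), multiplied by a deterministic
burst envelope, and optionally summed with a Gaussian-windowed wideband pulse.
Spectral trajectories are parameterized in normalized burst time (0 = onset,
1 = offset) so duration jitter does not distort the spectral program.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from emgtf.io import CONDITIONS, BurstAnnotation, ChannelMeta, Recording

__all__ = [
    "ConditionProfile",
    "SessionSpec",
    "default_profiles",
    "generate_burst",
    "generate_session",
]

# Analog acquisition band of the emulated recordings (Hz)
BAND_LOW_HZ = 30.0
BAND_HIGH_HZ = 500.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ConditionProfile:
    """Spectral/temporal program of one experimental condition.

    ``centroid_trajectory`` and ``bandwidth_trajectory`` map normalized burst
    time u in [0, 1] to the target spectral centroid and half-bandwidth (Hz).
    ``envelope(t_ms, duration_ms)`` is the dimensionless amplitude gain,
    non-negative and zero outside [0, duration].  ``transient_gain`` > 0 adds
    a Gaussian-windowed wideband pulse (20 ms FWHM) centred at
    ``transient_time_ms``, producing an instantaneous-energy bump without a
    spectral line.
    """

    name: str
    centroid_trajectory: Callable[[np.ndarray], np.ndarray]
    bandwidth_trajectory: Callable[[np.ndarray], np.ndarray]
    envelope: Callable[[np.ndarray, float], np.ndarray]
    transient_gain: float = 0.0
    transient_time_ms: float = 50.0
    transient_fwhm_ms: float = 20.0
    burst_duration_ms: tuple[float, float] = (250.0, 15.0)  # mean, SD
    inter_burst_interval_ms: tuple[float, float] = (400.0, 80.0)

    def validate(self) -> None:
        u = np.linspace(0.0, 1.0, 101)
        c = np.asarray(self.centroid_trajectory(u), dtype=float)
        if np.any(c < BAND_LOW_HZ) or np.any(c > BAND_HIGH_HZ):
            raise ValueError(
                f"{self.name}: centroid trajectory leaves [{BAND_LOW_HZ}, {BAND_HIGH_HZ}] Hz"
            )
        if self.transient_gain < 0:
            raise ValueError(f"{self.name}: transient_gain must be >= 0")
        dur = self.burst_duration_ms[0]
        t = np.linspace(-50.0, dur + 50.0, 301)
        env = np.asarray(self.envelope(t, dur), dtype=float)
        if np.any(env < 0):
            raise ValueError(f"{self.name}: envelope must be non-negative")
        outside = (t < 0) | (t > dur)
        if np.any(env[outside] != 0):
            raise ValueError(f"{self.name}: envelope must vanish outside [0, duration]")

    def max_frequency_hz(self) -> float:
        u = np.linspace(0.0, 1.0, 101)
        return float(
            np.max(
                np.asarray(self.centroid_trajectory(u))
                + np.asarray(self.bandwidth_trajectory(u))
            )
        )


def _ramp_envelope(attack_ms: float = 20.0, decay_start_ms: float = 150.0):
    """Raised-cosine attack, plateau, raised-cosine decay to burst offset."""

    def env(t_ms: np.ndarray, duration_ms: float) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        g = np.zeros_like(t)
        inside = (t >= 0) & (t <= duration_ms)
        ti = t[inside]
        gi = np.ones_like(ti)
        up = ti < attack_ms
        gi[up] = 0.5 * (1 - np.cos(np.pi * ti[up] / attack_ms))
        dstart = min(decay_start_ms, duration_ms)
        down = ti > dstart
        decay_len = max(duration_ms - dstart, 1e-9)
        gi[down] = 0.5 * (1 + np.cos(np.pi * (ti[down] - dstart) / decay_len))
        # attack and decay regions may overlap for very short bursts
        g[inside] = gi
        return g

    return env


def _linear(a: float, b: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda u: a + (b - a) * np.asarray(u, dtype=float)


def default_profiles() -> list[ConditionProfile]:
    """The five study conditions.

    Centroid programs (Hz, over normalized time u):

    * control: high and mildly decreasing, 340 -> 310;
    * week3:   reduced, increasing through the contraction, 260 -> 290;
    * week4:   232 -> 260 (close to week5);
    * week5:   224 -> 252;
    * week6:   markedly compressed with further loss at burst edges,
      140 + 60*sin(pi*u), plus a wideband recruitment transient at 50 ms.

    Time-averaged centroids decrease strictly control > week3 > week4 >
    week5 > week6, with week4 and week5 nearly coincident, and the control
    trajectory exceeds week6 at every u.  Half-bandwidths narrow with lesion
    progression (90 -> 50 Hz), emulating spectral-bandwidth narrowing.
    """
    env = _ramp_envelope()
    mk = ConditionProfile
    return [
        mk("control", _linear(340, 310), _linear(90, 90), env),
        mk("week3", _linear(260, 290), _linear(80, 80), env),
        mk("week4", _linear(232, 260), _linear(70, 70), env),
        mk("week5", _linear(224, 252), _linear(65, 65), env),
        mk(
            "week6",
            lambda u: 140.0 + 60.0 * np.sin(np.pi * np.asarray(u, dtype=float)),
            _linear(50, 50),
            env,
            transient_gain=1.2,
            transient_time_ms=50.0,
        ),
    ]


@dataclass
class SessionSpec:
    """Parameters of one synthetic multi-subject session batch."""

    profiles: Sequence[ConditionProfile] = field(default_factory=default_profiles)
    subjects_per_group: int = 2
    bursts_per_subject: int = 50
    fs: float = 2000.0
    session_length_s: float = 60.0
    seed: int = 0
    baseline_sd: float = 0.05  # fraction of nominal burst RMS (1.0 a.u.)

    def validate(self) -> None:
        for p in self.profiles:
            p.validate()
            if self.fs <= 2.0 * p.max_frequency_hz():
                raise ValueError(
                    f"fs={self.fs} violates Nyquist margin for profile {p.name}"
                )
            need_s = (
                self.bursts_per_subject
                * (p.burst_duration_ms[0] + p.inter_burst_interval_ms[0])
                / 1000.0
            )
            if need_s > self.session_length_s:
                raise ValueError(
                    f"{self.bursts_per_subject} bursts (~{need_s:.1f}s) do not fit in "
                    f"a {self.session_length_s}s session for profile {p.name}"
                )


def _colored_noise_frame(rng: np.random.Generator, n: int, fs: float,
                         centroid_hz: float, half_bw_hz: float) -> np.ndarray:
    """White Gaussian frame shaped by a Gaussian band-pass magnitude response.

    The response has half-power half-width ``half_bw_hz`` and is additionally
    confined to the acquisition band [30, 500] Hz.  The frame is rescaled to
    unit RMS so overall amplitude is controlled by the burst envelope alone.
    """
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = half_bw_hz / np.sqrt(2.0 * np.log(2.0))  # half-power half-width
    G = np.exp(-0.5 * ((f - centroid_hz) / sigma) ** 2)
    G[(f < BAND_LOW_HZ) | (f > BAND_HIGH_HZ)] = 0.0
    y = np.fft.irfft(X * G, n=n)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def generate_burst(
    profile: ConditionProfile,
    fs: float,
    seed: int | np.random.Generator,
    duration_ms: float | None = None,
    frame_ms: float = 20.0,
) -> np.ndarray:
    """Synthesize one burst of the given condition; returns a 1-D sample array.

    Overlap-add of sqrt-Hann-windowed colored-noise frames (hop = frame/2,
    power-complementary) tracks the centroid/bandwidth trajectories; the
    deterministic envelope and optional recruitment transient are applied on
    top.  Duration is drawn from the profile's (mean, SD) unless given.
    """
    if fs < 1000:
        raise ValueError(f"fs must be >= 1000 Hz for EMG-band synthesis, got {fs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration_ms is None:
        mean, sd = profile.burst_duration_ms
        duration_ms = float(np.clip(rng.normal(mean, sd), mean - 3 * sd, mean + 3 * sd))
        duration_ms = max(duration_ms, 170.0)  # keep all three phases populated
    n = int(round(duration_ms * fs / 1000.0))
    frame = max(int(round(frame_ms * fs / 1000.0)) // 2 * 2, 8)
    hop = frame // 2
    w = np.sqrt(np.hanning(frame + 1)[:frame])  # periodic sqrt-Hann: sum of squares = 1

    x = np.zeros(n + frame)
    for lo in range(0, n, hop):
        u = float(np.clip((lo + frame / 2.0) / n, 0.0, 1.0))
        c = float(profile.centroid_trajectory(np.array(u)))
        b = float(profile.bandwidth_trajectory(np.array(u)))
        x[lo : lo + frame] += _colored_noise_frame(rng, frame, fs, c, b) * w
    x = x[:n]

    t_ms = np.arange(n) / fs * 1000.0
    x *= profile.envelope(t_ms, duration_ms)

    if profile.transient_gain > 0:
        sigma_ms = profile.transient_fwhm_ms * _FWHM_TO_SIGMA
        gauss = np.exp(-0.5 * ((t_ms - profile.transient_time_ms) / sigma_ms) ** 2)
        pulse = _colored_noise_frame(
            rng, n, fs, 0.5 * (BAND_LOW_HZ + BAND_HIGH_HZ), BAND_HIGH_HZ - BAND_LOW_HZ
        )
        x += profile.transient_gain * gauss * pulse
    return x


def generate_session(spec: SessionSpec) -> tuple[list[Recording], list[BurstAnnotation]]:
    """Generate one single-channel Recording per synthetic subject plus ground truth.

    Bursts are placed sequentially with inter-burst gaps drawn from the
    profile's inter-burst-interval distribution; the space between bursts is
    low-amplitude Gaussian baseline noise.  Fully reproducible from
    ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    recordings: list[Recording] = []
    annotations: list[BurstAnnotation] = []
    n_total = int(round(spec.session_length_s * spec.fs))

    subject_seeds = root.spawn(len(spec.profiles) * spec.subjects_per_group)
    k = 0
    for profile in spec.profiles:
        for s in range(spec.subjects_per_group):
            rng = np.random.default_rng(subject_seeds[k])
            k += 1
            subject = f"{profile.name}_s{s:02d}"
            sig = rng.normal(0.0, spec.baseline_sd, n_total) if spec.baseline_sd > 0 else np.zeros(n_total)
            pos = 0
            for b in range(spec.bursts_per_subject):
                gmean, gsd = profile.inter_burst_interval_ms
                gap_ms = max(float(rng.normal(gmean, gsd)), 100.0)
                pos += int(round(gap_ms * spec.fs / 1000.0))
                burst = generate_burst(profile, spec.fs, rng)
                if pos + burst.size > n_total:
                    raise ValueError(
                        f"session overflow for subject {subject}: burst {b} does not fit"
                    )
                sig[pos : pos + burst.size] += burst
                annotations.append(
                    BurstAnnotation(
                        subject=subject,
                        group=profile.name,
                        burst_id=b,
                        onset_s=pos / spec.fs,
                        offset_s=(pos + burst.size) / spec.fs,
                    )
                )
                pos += burst.size
            recordings.append(
                Recording(
                    samples=sig[np.newaxis, :],
                    fs=spec.fs,
                    channel_meta=[ChannelMeta(subject, profile.name)],
                )
            )
    return recordings, annotations


def profile_phase_centroid(
    profile: ConditionProfile,
    duration_ms: float,
    start_ms: float,
    end_ms: float,
) -> float:
    """Time-averaged target centroid of a trajectory over [start_ms, end_ms]."""
    u = np.linspace(start_ms / duration_ms, min(end_ms, duration_ms) / duration_ms, 201)
    return float(np.mean(profile.centroid_trajectory(u)))
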