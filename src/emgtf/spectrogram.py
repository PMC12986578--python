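"""STFT spectrograms of bursts and mean/median-frequency trajectories.

Frames are computed only where fully supported by burst samples (no burst
zero-padding), so an L-ms analysis window leaves L/2 ms without spectral
estimates at each end of the burst — with the default 80 ms window on a
250 ms contraction that is 40 ms per edge; with the 30 ms window, 15 ms.

Power is one-sided density-scaled: P = |X|^2 * 2 / (fs * sum(w^2)) (DC and
Nyquist bins not doubled), so summing P over frequency times the bin width
equals the windowed-frame energy divided by the window's sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emgtf.preprocess import BurstSegment

__all__ = [
    "TFMap",
    "SpectralTrajectory",
    "stft_spectrogram",
    "spectral_trajectory",
    "average_trajectories",
]


@dataclass
class TFMap:
    """Time x frequency power map with a per-cell validity mask.

    ``kind`` is "stft" (mask depends on time only; edge regions simply have
    no frames) or "cwt" (mask is the cone of influence, frequency-dependent).
    """

    power: np.ndarray  # (n_times, n_freqs), >= 0
    times_s: np.ndarray
    freqs_hz: np.ndarray
    valid: np.ndarray  # bool, same shape as power
    kind: str = "stft"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.power.shape != (self.times_s.size, self.freqs_hz.size):
            raise ValueError("power shape does not match time/frequency grids")
        if self.valid.shape != self.power.shape:
            raise ValueError("valid mask shape does not match power")
        if np.any(self.power < 0):
            raise ValueError("negative power")
        if np.any(np.diff(self.times_s) <= 0) or np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("time/frequency grids must be strictly increasing")


@dataclass
class SpectralTrajectory:
    """Per-frame mean and median frequency, optionally averaged over bursts."""

    times_s: np.ndarray
    f_mean_hz: np.ndarray
    f_median_hz: np.ndarray
    n_valid: np.ndarray
    f_mean_sem: np.ndarray | None = None
    f_median_sem: np.ndarray | None = None


def stft_spectrogram(
    burst: BurstSegment,
    window_ms: float = 80.0,
    overlap_ms: float = 75.0,
    nfft: int = 160,
) -> TFMap:
    """Hamming-windowed spectrogram of one burst.

    Frame centers run from window/2 to duration - window/2 in hops of
    (window - overlap); each emitted frame is fully supported and marked
    valid.  Defaults follow the 80 ms / 75 ms / 160-point configuration;
    the higher-temporal-resolution alternative is 30 / 25 / 64.
    """
    fs = burst.fs
    if overlap_ms >= window_ms:
        raise ValueError("overlap_ms must be smaller than window_ms")
    win = int(round(window_ms * fs / 1000.0))
    hop = int(round((window_ms - overlap_ms) * fs / 1000.0))
    if hop < 1:
        raise ValueError("window/overlap difference below one sample")
    n = burst.samples.size
    if win > n:
        raise ValueError(
            f"burst ({n / fs * 1000:.0f} ms) shorter than the {window_ms:.0f} ms "
            "analysis window; use the 30 ms configuration for short bursts"
        )
    if nfft < win:
        raise ValueError(f"nfft ({nfft}) must be >= window length in samples ({win})")

    w = np.hamming(win)
    starts = np.arange(0, n - win + 1, hop)
    frames = burst.samples[starts[:, None] + np.arange(win)] * w
    X = np.fft.rfft(frames, n=nfft, axis=1)
    scale = 2.0 / (fs * np.sum(w**2))
    power = (np.abs(X) ** 2) * scale
    power[:, 0] /= 2.0
    if nfft % 2 == 0:
        power[:, -1] /= 2.0

    times = (starts + win / 2.0) / fs
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    valid = np.ones_like(power, dtype=bool)
    return TFMap(power=power, times_s=times, freqs_hz=freqs, valid=valid, kind="stft")


def _column_fmean_fmedian(p: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    total = p.sum()
    if total <= 0:
        return np.nan, np.nan
    fmean = float(np.sum(f * p) / total)
    # cumulative power with each bin's mass centered at its bin frequency,
    # so a tone exactly on a bin yields that bin (no half-bin bias)
    cum_mid = np.cumsum(p) - p / 2.0
    fmedian = float(np.interp(total / 2.0, cum_mid, f))
    return fmean, fmedian


def spectral_trajectory(tfmap: TFMap) -> SpectralTrajectory:
    """F_mean and F_median per time column, restricted to mask-valid cells.

    F_mean is the power-weighted centroid; F_median is the frequency at which
    cumulative power reaches half the column total, linearly interpolated
    between bracketing grid frequencies.  Columns with zero total (or no
    valid cells) yield missing values.
    """
    if not np.any(tfmap.valid):
        raise ValueError("time-frequency map has no valid cells")
    nt = tfmap.times_s.size
    f_mean = np.full(nt, np.nan)
    f_median = np.full(nt, np.nan)
    n_valid = np.zeros(nt, dtype=int)
    for i in range(nt):
        m = tfmap.valid[i]
        if not m.any():
            continue
        fm, fmed = _column_fmean_fmedian(tfmap.power[i, m], tfmap.freqs_hz[m])
        f_mean[i], f_median[i] = fm, fmed
        n_valid[i] = int(np.isfinite(fm))
    return SpectralTrajectory(
        times_s=tfmap.times_s.copy(),
        f_mean_hz=f_mean,
        f_median_hz=f_median,
        n_valid=n_valid,
    )


def average_trajectories(trajectories: list[SpectralTrajectory]) -> SpectralTrajectory:
    """Pointwise mean and SEM over bursts, aligned at burst onset.

    All inputs must share frame timing (same window/hop, onset-aligned);
    times are truncated to the shortest contributing trajectory.  SEM uses
    the n-1 denominator and is 0 where a single burst contributes.
    """
    if not trajectories:
        raise ValueError("no trajectories to average")
    n_frames = min(t.times_s.size for t in trajectories)
    ref = trajectories[0].times_s[:n_frames]
    for t in trajectories:
        if not np.allclose(t.times_s[:n_frames], ref, atol=1e-9):
            raise ValueError("trajectories have mismatched frame times")

    def _stack(attr: str) -> np.ndarray:
        return np.vstack([getattr(t, attr)[:n_frames] for t in trajectories])

    out = {}
    for attr, key in (("f_mean_hz", "mean"), ("f_median_hz", "median")):
        vals = _stack(attr)
        finite = np.isfinite(vals)
        n = finite.sum(axis=0)
        safe = np.where(finite, vals, 0.0)
        mean = np.where(n > 0, safe.sum(axis=0) / np.maximum(n, 1), np.nan)
        dev2 = np.where(finite, (safe - mean) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(dev2 / np.maximum(n - 1, 1))
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
        sem = np.where(n >= 1, sem, np.nan)
        out[key] = (mean, sem, n)

    return SpectralTrajectory(
        times_s=ref.copy(),
        f_mean_hz=out["mean"][0],
        f_median_hz=out["median"][0],
        n_valid=np.minimum(out["mean"][2], out["median"][2]),
        f_mean_sem=out["mean"][1],
        f_median_sem=out["median"][1],
    )
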