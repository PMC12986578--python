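"""Continuous wavelet transform with the Bump mother wavelet.

The Bump wavelet is analytic with compact Fourier support: in the frequency
domain, psi_hat(xi) = exp(1 - 1/(1 - ((xi - mu)/sigma)^2)) for |xi - mu| <
sigma and 0 elsewhere (xi = s*omega, dimensionless).  Its high spectral
concentration and temporal compactness suit short high-amplitude transients
such as EMG bursts.  Scales map to frequency by the peak-frequency
convention f = mu / (2*pi*s); wavelet energy is |W|^2 / s.

Because the wavelet has no closed-form time expression, the cone of
influence uses the numerically computed e-folding half-width tau_e of the
mother wavelet's time envelope: cells closer than s * tau_e to either burst
edge are masked invalid.  The transform zero-extends the signal (no
reflection) so COI semantics stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from emgtf.preprocess import BurstSegment
from emgtf.spectrogram import TFMap

__all__ = ["BumpWavelet", "bump_cwt", "cone_of_influence"]


@dataclass(frozen=True)
class BumpWavelet:
    """Frequency-domain Bump mother wavelet with bump center mu, half-width sigma."""

    mu: float = 5.0
    sigma: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.sigma < self.mu:
            raise ValueError(
                f"require 0 < sigma < mu for an analytic bump, got "
                f"(mu={self.mu}, sigma={self.sigma})"
            )

    def freq_response(self, xi: np.ndarray) -> np.ndarray:
        """psi_hat evaluated at dimensionless angular frequency xi."""
        xi = np.asarray(xi, dtype=float)
        z = (xi - self.mu) / self.sigma
        out = np.zeros_like(xi)
        inside = np.abs(z) < 1.0
        with np.errstate(divide="ignore", over="ignore"):
            out[inside] = np.exp(1.0 - 1.0 / (1.0 - z[inside] ** 2))
        return out


_TAU_E_CACHE: dict[tuple[float, float], float] = {}


def efolding_halfwidth(wavelet: BumpWavelet, n: int = 1 << 15) -> float:
    """Two-sided e-folding half-width tau_e of the mother wavelet's time envelope.

    Computed once per (mu, sigma) by inverse-transforming psi_hat on a fine
    grid and scanning outward from the envelope peak for the first drop below
    peak/e; cached.
    """
    key = (wavelet.mu, wavelet.sigma)
    if key in _TAU_E_CACHE:
        return _TAU_E_CACHE[key]
    # time step so the bump (support < mu + sigma) sits well inside Nyquist
    dt = np.pi / (2.0 * (wavelet.mu + wavelet.sigma))
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)
    psi = np.fft.ifft(wavelet.freq_response(omega))
    env = np.abs(psi)
    # ifft places t=0 at index 0; envelope is symmetric (psi_hat real)
    half = env[: n // 2]
    peak = half[0]
    below = np.flatnonzero(half < peak / np.e)
    tau_e = float(below[0] * dt) if below.size else float(n // 2 * dt)
    _TAU_E_CACHE[key] = tau_e
    return tau_e


def _scale_grid(fmin: float, fmax: float, voices_per_octave: int) -> np.ndarray:
    n_oct = np.log2(fmax / fmin)
    k = np.arange(int(np.floor(n_oct * voices_per_octave)) + 1)
    freqs = fmin * 2.0 ** (k / voices_per_octave)
    if freqs[-1] < fmax * (1 - 1e-12):
        freqs = np.append(freqs, fmax)
    return freqs


def bump_cwt(
    burst: BurstSegment,
    wavelet: BumpWavelet = BumpWavelet(),
    fmin_hz: float = 30.0,
    fmax_hz: float = 500.0,
    voices_per_octave: int = 16,
) -> TFMap:
    """CWT power map (kind="cwt") on a geometric frequency grid.

    Frequency-domain implementation: W(s, t) = ifft(x_hat(omega) *
    conj(psi_hat(s*omega))) on a zero-extended signal; power = |W|^2 / s.
    The validity mask is the cone of influence.
    """
    fs = burst.fs
    if not 0 < fmin_hz < fmax_hz <= fs / 2.0:
        raise ValueError(f"band ({fmin_hz}, {fmax_hz}) outside (0, fs/2]")
    x = burst.samples
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))  # zero-extension, no reflection
    X = np.fft.fft(x, n=nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)

    freqs = _scale_grid(fmin_hz, fmax_hz, voices_per_octave)
    scales = wavelet.mu / (2.0 * np.pi * freqs)  # peak-frequency convention, seconds
    power = np.empty((n, freqs.size))
    for j, s in enumerate(scales):
        W = np.fft.ifft(X * np.conj(wavelet.freq_response(s * omega)))[:n]
        power[:, j] = (np.abs(W) ** 2) / s

    times = np.arange(n) / fs
    tfmap = TFMap(
        power=power,
        times_s=times,
        freqs_hz=freqs,
        valid=np.ones_like(power, dtype=bool),
        kind="cwt",
    )
    tfmap.valid = cone_of_influence(tfmap, wavelet)
    return tfmap


def cone_of_influence(tfmap: TFMap, wavelet: BumpWavelet = BumpWavelet()) -> np.ndarray:
    """Validity mask: cells within s * tau_e of either burst edge are invalid.

    tau_e is the mother wavelet's e-folding time-envelope half-width (cached
    numerical constant); at scale s the contaminated edge band is s * tau_e
    seconds wide, so lower frequencies (larger scales) lose wider edges.
    """
    if tfmap.kind != "cwt":
        raise ValueError("cone of influence applies to kind='cwt' maps")
    tau_e = efolding_halfwidth(wavelet)
    scales = wavelet.mu / (2.0 * np.pi * tfmap.freqs_hz)
    t = tfmap.times_s - tfmap.times_s[0]
    total = t[-1]
    edge = scales * tau_e  # (n_freqs,)
    return (t[:, None] >= edge[None, :]) & ((total - t)[:, None] >= edge[None, :])
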