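"""NA-MEMD structural properties and Hilbert feature extraction."""

from __future__ import annotations

import numpy as np
import pytest

from emgtf import memd as ememd
from emgtf.io import BurstAnnotation, ChannelMeta, Recording
from emgtf.synth import default_profiles, generate_burst

FS = 1000.0


def _two_tone_recording(duration_s=2.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    x1 = np.cos(2 * np.pi * 50.0 * t) + 0.8 * np.cos(2 * np.pi * 300.0 * t)
    x2 = 0.7 * np.cos(2 * np.pi * 50.0 * t + 0.5) + np.cos(2 * np.pi * 300.0 * t + 1.0)
    return Recording(
        samples=np.vstack([x1, x2]),
        fs=fs,
        channel_meta=[ChannelMeta("a", "x"), ChannelMeta("b", "x")],
    )


@pytest.fixture(scope="module")
def two_tone_imfs():
    rec = _two_tone_recording()
    imfset = ememd.na_memd(rec, seed=3)
    return rec, imfset, ememd.hilbert_if_ie(imfset)


def test_hammersley_directions_unit_norm_and_deterministic():
    d1 = ememd.hammersley_directions(64, 5)
    d2 = ememd.hammersley_directions(64, 5)
    np.testing.assert_array_equal(d1, d2)
    np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0, atol=1e-12)
    assert d1.shape == (64, 5)
    # roughly centered on the sphere
    assert np.linalg.norm(d1.mean(axis=0)) < 0.2


def test_extrema_indices_plateaus_and_strict():
    y = np.array([0.0, 1.0, 1.0, 0.0, -1.0, 0.0, 2.0, 0.0])
    mx, mn = ememd._extrema_indices(y)
    assert 4 in mn and 6 in mx
    assert any(i in (1, 2) for i in mx)  # plateau top counted once
    mx2, mn2 = ememd._extrema_indices(np.arange(5.0))
    assert mx2.size == 0 and mn2.size == 0


def test_direction_count_floor_warns():
    data = np.random.default_rng(0).standard_normal((3, 300))
    with pytest.warns(UserWarning, match="increasing"):
        ememd.memd(data, n_directions=4, max_modes=2)


def test_exact_reconstruction_and_mode_alignment(two_tone_imfs):
    rec, imfset, _ = two_tone_imfs
    recon = imfset.reconstruct()
    # signal channels reproduce the input exactly
    err = np.max(np.abs(recon[imfset.signal_channels()] - rec.samples))
    assert err / np.max(np.abs(rec.samples)) < 1e-10
    # mode alignment: one stack, same mode count for every channel
    assert imfset.imfs.shape[0] == rec.n_channels + 3
    assert imfset.n_modes >= 2
    assert [m.is_noise_channel for m in imfset.channel_meta] == [False] * 2 + [True] * 3


def test_two_tone_separation_aligned_modes(two_tone_imfs):
    _, imfset, series = two_tone_imfs
    sig = imfset.signal_channels()
    f = series.inst_freq_hz[sig]
    w = series.inst_energy[sig]
    finite = np.isfinite(f)
    wmean = (np.where(finite, f * w, 0.0).sum(axis=2)
             / np.where(finite, w, 0.0).sum(axis=2))
    hits = {}
    for tone in (300.0, 50.0):
        modes = [m for m in range(imfset.n_modes)
                 if np.all(np.abs(wmean[:, m] - tone) / tone <= 0.10)]
        assert modes, f"{tone} Hz tone not recovered; mode IFs {np.round(wmean, 1)}"
        hits[tone] = modes
    assert not set(hits[300.0]) & set(hits[50.0])  # distinct modes per tone


def test_na_memd_seeded_determinism():
    rec = _two_tone_recording(duration_s=0.5)
    a = ememd.na_memd(rec, seed=7, n_directions=16, max_modes=4)
    b = ememd.na_memd(rec, seed=7, n_directions=16, max_modes=4)
    np.testing.assert_array_equal(a.imfs, b.imfs)
    c = ememd.na_memd(rec, seed=8, n_directions=16, max_modes=4)
    assert not np.array_equal(a.imfs, c.imfs)


def test_white_noise_quasi_dyadic_ordering():
    """Mean Hilbert IF strictly decreases with mode index on white noise."""
    for seed in range(10):
        w = np.random.default_rng(100 + seed).standard_normal((2, 1500))
        imfs, res = ememd.memd(w, n_directions=32)
        s = ememd.IMFSet(imfs=imfs, residual=res, fs=FS)
        h = ememd.hilbert_if_ie(s)
        mif = np.nanmean(h.inst_freq_hz, axis=(0, 2))
        assert np.all(np.diff(mif) < 0), f"seed {seed}: {np.round(mif, 1)}"


def test_noise_assistance_does_not_increase_mode_mixing():
    """Spectral overlap between successive modes with 3 noise channels is not
    larger than without, at matched seeds (spec'd direction only)."""
    rng = np.random.default_rng(5)
    prof = default_profiles()[0]

    def chan():
        xs = []
        while sum(x.size for x in xs) < int(2 * FS):
            xs.append(generate_burst(prof, FS, rng, duration_ms=250.0))
            xs.append(rng.normal(0, 0.05, int(0.15 * FS)))
        return np.concatenate(xs)[: int(2 * FS)]

    x = np.vstack([chan(), chan()])
    meta = [ChannelMeta("a", "control"), ChannelMeta("b", "control")]
    rec = Recording(samples=x, fs=FS, channel_meta=meta)
    with_noise = ememd.na_memd(rec, n_noise_channels=3, seed=9)
    imfs0, res0 = ememd.memd(x)
    without = ememd.IMFSet(imfs=imfs0, residual=res0, fs=FS, channel_meta=meta)

    def mixing(s):
        _, _, ranges = ememd.imf_marginal_spectra(s)
        return float(np.mean(ememd.dominant_range_overlap(ranges)))

    assert mixing(with_noise) <= mixing(without) + 1e-9


def test_hilbert_tone_if_and_amplitude_floor():
    t = np.arange(int(1.0 * FS)) / FS
    tone = np.cos(2 * np.pi * 80.0 * t)
    silent = np.zeros_like(tone)
    imfs = ememd.IMFSet(imfs=np.stack([[tone, silent]]), residual=np.zeros((1, t.size)),
                        fs=FS)
    h = ememd.hilbert_if_ie(imfs)
    inner = h.inst_freq_hz[0, 0, int(0.01 * FS) : -int(0.01 * FS)]
    assert np.nanmax(np.abs(inner - 80.0)) < 0.5
    assert np.all(np.isnan(h.inst_freq_hz[0, 1]))  # all-zero mode has no IF
    np.testing.assert_allclose(h.inst_energy[0, 1], 0.0)


def test_segment_imfs_tidy_rows(two_tone_imfs):
    _, imfset, series = two_tone_imfs
    anns = [
        BurstAnnotation("a", "x", 0, 0.2, 0.45),
        BurstAnnotation("a", "x", 1, 1.0, 1.14),   # too short: excluded
        BurstAnnotation("b", "x", 0, 0.5, 0.75),
        BurstAnnotation("zz", "x", 0, 0.5, 0.75),  # unknown subject: skipped
        BurstAnnotation("a", "x", 2, 1.9, 2.4),    # outside recording: skipped
    ]
    table = ememd.segment_imfs(imfset, series, anns, modes_of_interest=(1, 2))
    # 2 accepted bursts x 2 modes x 3 phases x 2 metrics
    assert len(table) == 2 * 2 * 3 * 2
    assert set(table["source"]) == {"imf1", "imf2"}
    assert set(table["metric"]) == {"inst_freq_mean", "inst_energy_mean"}
    assert set(table["phase"]) == {"recruitment", "sustained", "derecruitment"}
    assert (table["value"].dropna() >= 0).all()


def test_memd_input_validation():
    with pytest.raises(ValueError):
        ememd.memd(np.zeros((1, 3)))
    rec = _two_tone_recording(0.5)
    with pytest.raises(ValueError):
        ememd.na_memd(rec, n_noise_channels=0)
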