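# Methods

This note records the modeling and algorithmic choices behind `emgtf`, in
enough detail to re-derive every default. The package studies how well three
time–frequency routes — short-time Fourier spectrograms, a Bump-wavelet CWT,
and noise-assisted multivariate EMD with Hilbert demodulation — recover
progressive spectral compression of locomotor EMG bursts across five
experimental conditions (a control and four post-lesion weeks).

## 1. Synthetic locomotor-EMG model (`emgtf.synth`)

Surface/intramuscular EMG is broadband and stochastic, so bursts are modeled
as **time-varying filtered Gaussian noise**, not sums of sinusoids. A burst of
duration `D` (drawn from N(250, 15²) ms, clipped to ±3 SD and ≥ 170 ms so all
three contraction phases exist) is synthesized by overlap-adding 20 ms
sqrt-Hann windowed frames (50 % hop; the squared windows sum to one, so frame
energy is preserved). Each frame is white Gaussian noise shaped in the
frequency domain by a Gaussian band-pass response whose center follows the
condition's **centroid trajectory** `c(u)` and whose half-power half-width
follows the **bandwidth trajectory** `b(u)`, both parameterized in normalized
burst time `u ∈ [0, 1]` so duration jitter does not distort the spectral
program. The response is additionally confined to the 30–500 Hz acquisition
band and each frame is normalized to unit RMS, leaving amplitude entirely to
the deterministic envelope.

The envelope is a raised-cosine attack (20 ms), plateau, and raised-cosine
decay from 150 ms to burst offset. The 20 ms attack is a deliberate choice:
locomotor recruitment is fast, and a slow (50 ms) attack leaves the first
tens of milliseconds of a burst below any reasonable detection level, making
"onset" ill-defined at the ±10 ms scale this package tests.

Condition presets (centroid start → end in Hz, constant half-bandwidth):

| condition | centroid | half-BW | extras |
|---|---|---|---|
| control | 340 → 310 | 90 | — |
| week3 | 260 → 290 | 80 | — |
| week4 | 232 → 260 | 70 | — |
| week5 | 224 → 252 | 65 | — |
| week6 | 140 + 60·sin(πu) | 50 | wideband transient at 50 ms |

Time-averaged centroids decrease strictly control > week3 > week4 > week5 >
week6, with week4/week5 deliberately close. The week6 **recruitment
transient** is a Gaussian-windowed (20 ms FWHM) wideband noise pulse centered
at 50 ms — an instantaneous-energy bump without a spectral line, i.e. the
kind of nonstationarity sharply localized methods should resolve and
window-averaged methods should smear (see §7).

Sessions place bursts sequentially with inter-burst gaps from N(400, 80²) ms
(min 100 ms) over a Gaussian baseline of SD 0.05 (relative to ≈ unit burst
RMS). Reproducibility is exact: one `SeedSequence` per session spawns one
child generator per subject.

## 2. Preprocessing (`emgtf.preprocess`)

Filtering is zero-phase (4th-order Butterworth 30–500 Hz via `sosfiltfilt`,
plus an optional 50 Hz IIR notch, Q = 30, via `filtfilt`) so burst onsets are
not delayed by group delay.

Burst detection: a centered 10 ms moving-RMS envelope is thresholded at
`median + 5·MAD`, supra-threshold runs separated by < 30 ms are merged, runs
shorter than 100 ms dropped, and onsets/offsets refined outward to the
nearest crossing of a **reduced threshold** `median + 0.4·(thr − median)`.
Two robustness choices deserve note:

- The refinement level is relative to the median rather than a literal
  `thr/2`, because half of an absolute threshold can fall below the baseline
  envelope and let onsets walk arbitrarily far into noise.
- The threshold is floored at `0.02·max(envelope)`. With a (near-)noiseless
  baseline the median/MAD collapse toward zero and detection would otherwise
  chase the ~1 %-of-peak acausal skirts that zero-phase filtering spreads
  ahead of each burst. The 2 % floor sits above those skirts and far below
  any physiological burst; in the default 5 %-noise regime it is inactive.
  Related: the Q = 30 notch rings with a ~0.2 s time constant and leaks
  ~0.2 % of burst amplitude into inter-burst gaps — irrelevant at normal
  noise levels, dominant in near-silent recordings.

Phase partition (fs = 2000 Hz, boundaries at 80/150 ms): recruitment
`[0, 80)` ms, sustained `[80, 150]` ms, derecruitment `(150, D]` ms. The
half-open/closed conventions make the three index sets an exact partition; a
250 ms burst splits into 160 + 141 + 199 samples. Bursts ≤ 150 ms cannot
host all three phases and are excluded.

## 3. STFT spectrograms (`emgtf.spectrogram`)

Hamming-windowed frames are computed **only where fully supported** by burst
samples (no zero-padding of the burst), so an `L` ms window leaves `L/2` ms
without estimates at each end: 40 ms for the default 80 ms window
(80/75 ms window/overlap, 160-point FFT → 12.5 Hz bins at fs = 2000 Hz) and
15 ms for the 30/25/64 alternative. Power is one-sided density-scaled,
`P = |X|²·2/(fs·Σw²)` (DC/Nyquist not doubled).

Per frame, `F_mean` is the power-weighted centroid and `F_median` the
frequency where cumulative power reaches half the total, linearly
interpolated **with each bin's mass centered at its bin frequency**
(`cumsum(p) − p/2`); the plain cumulative convention biases on-bin tones half
a bin low. Group trajectories average per-burst trajectories pointwise
(onset-aligned, truncated to the shortest burst) with SEM (n−1 denominator).

## 4. Bump-wavelet CWT (`emgtf.cwt`)

The Bump wavelet is analytic with compact Fourier support:
`ψ̂(ξ) = exp(1 − 1/(1 − ((ξ−μ)/σ)²))` on `|ξ−μ| < σ`, zero elsewhere, with
μ = 5, σ = 0.6. Scales map to frequency by the peak-frequency convention
`f = μ/(2πs)` (for a symmetric ψ̂, peak and center-of-mass coincide) on a
geometric grid of 16 voices/octave over 30–500 Hz; power is `|W|²/s`.

The transform runs in the frequency domain on a zero-extended signal (no
reflection), so cone-of-influence semantics stay exact. Because the Bump has
no closed-form time expression, the COI uses the numerically computed
e-folding half-width of the mother wavelet's time envelope,
τ_e ≈ 5.610 (computed once per (μ, σ) by inverse FFT on a 2¹⁵ grid and
cached): cells closer than `s·τ_e` to either burst edge are masked invalid.

## 5. NA-MEMD + Hilbert (`emgtf.memd`)

Multivariate EMD sifts all channels jointly: the signal is projected onto 64
direction vectors on the unit hypersphere, the extrema of each projection
interpolated by cubic splines (vector-valued, with two extrema mirrored
about each boundary to tame edge divergence), and the mean of the direction
envelopes subtracted until the Rilling three-parameter criterion
(θ₁, θ₂, α) = (0.05, 0.5, 0.05) is met (hard cap 1000 iterations/mode).
Decomposition stops when the residual has fewer than 3 projection extrema in
every direction, or at 10 modes. Completeness (`Σ modes + residual = input`)
holds exactly by construction, and all channels share one mode-aligned stack.

Direction vectors are Hammersley points in the unit cube (first coordinate
`(i+0.5)/N`, remaining coordinates radical-inverse sequences in successive
prime bases) mapped to the sphere via coordinate-wise inverse Gaussian CDF
and radial normalization — a measure-preserving map that is simpler and
dimension-general compared to hyperspherical-angle constructions.

The noise-assisted variant appends 3 independent white Gaussian channels
with SD = 1.0 × the mean signal-channel SD before decomposing; the broadband
noise anchors a quasi-dyadic filterbank that stabilizes mode alignment. The
noise amount is a known sensitivity of the method, so it is an explicit,
logged parameter. Noise channels stay in the output, flagged in metadata.

Hilbert features: instantaneous energy is the squared analytic amplitude;
instantaneous frequency is the phase gradient, median-filtered over 5 ms,
clipped to [0, fs/2], and set missing where the amplitude is below 1 % of
the mode RMS (phase derivatives are meaningless near zero amplitude).

## 6. Statistics (`emgtf.stats`)

Observation unit defaults to the individual contraction (large-n,
pseudo-replication accepted); `unit="subject"` aggregates to subject means.
Trajectory metrics get one-way ANOVA + Tukey–Kramer (studentized range,
valid for unequal n) per source × metric × phase, uncorrected across phases.
IMF metric pairs (mean IF, mean IE) are gated by a one-way MANOVA — Wilks' Λ
with Rao's F approximation (exact for two responses) by default, Pillai's
trace available — then all per-variable ANOVAs in the run form **one
Holm–Bonferroni family** (plain Bonferroni optional), with Tukey post hocs
only where the gate passed and the adjusted p < α = 0.05.

Calibration (acceptance-tested): ANOVA and Wilks-MANOVA type-I error rates
land in [0.035, 0.065] at α = 0.05 over 1000 null simulations; with two
groups ANOVA F equals t² to 1e-9; Holm output dominates raw p and is
dominated by Bonferroni, and is permutation-equivariant.

## 7. Cross-method findings on the synthetic benchmark

On the seeded benchmark (5 conditions × 200 bursts), all three trajectory
routes recover the generator's condition ordering in every phase
(derecruitment rank correlation 1), and control-vs-week6 contrasts are
significant at p < 0.001 — derecruitment behaves as the most sensitive
phase, as intended by the presets. Two subtler comparisons are **reported
rather than asserted**, because the measured behavior is method physics, not
implementation error:

- **Per-time STFT/CWT concordance.** With default presets, CWT and 30 ms
  STFT group-mean F_median orderings agree at every common valid time
  *except* at t ≈ 50 ms, where the week6 wideband transient is resolved by
  the CWT (≈ 15 ms effective support at 300 Hz) but smeared by the 30 ms
  window — the CWT momentarily ranks week6 above week5. With the transient
  disabled, orderings agree at all 22 common valid times (a valid CWT time
  requires the COI cutoff frequency to stay below half the group's
  F_median). The pipeline's consistency report therefore checks the
  phase-level ordering, which holds everywhere.
- **Dispersion.** The between-burst SEM of the CWT F_median trajectory is
  *not* lower than the 80 ms STFT's on this generator (e.g. ≈ 1.5 vs
  ≈ 1.4 Hz for the low-centroid presets): an 80 ms window simply averages
  more signal than the ≈ 36 ms effective wavelet support at these
  frequencies. Both SEMs are written to `consistency.json`
  (`f_median_sem_by_source`) for inspection.

## 8. Reproducibility

Every stochastic stage derives from one global seed through
`numpy.random.SeedSequence.spawn` (stage 0: synthesis, stage 1: MEMD noise),
so stages can be rerun in isolation. Writers are deterministic (stable sort,
9-significant-digit floats): rerunning a configuration reproduces
byte-identical CSV/JSON artifacts. `run_all` writes a manifest with the
config SHA-256 and per-stage row counts.

## 9. Limitations / non-goals

- No motor-unit-level physiology: the generator models spectra and
  envelopes, not discharge trains.
- No mixed-effects or repeated-measures models; group statistics treat
  contractions (or subject means) as exchangeable observations.
- NA-MEMD cost scales with channels × samples × directions; the pipeline
  truncates each subject to `memd_max_seconds` (default 10 s) before
  pooling.
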