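"""End-to-end orchestration: simulate -> filter -> segment -> {STFT, CWT,
NA-MEMD} -> tidy features -> statistics, reproducible from one config + seed.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn`` (stage 0: synthesis, stage 1: MEMD noise),
so stages can be rerun in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emgtf import io as eio
from emgtf import memd as ememd
from emgtf import stats as estats
from emgtf import synth
from emgtf.cwt import BumpWavelet, bump_cwt
from emgtf.preprocess import (
    BurstSegment,
    PhasePartition,
    bandpass_notch,
    detect_bursts,
    extract_segments,
    partition_phases,
)
from emgtf.spectrogram import SpectralTrajectory, average_trajectories, spectral_trajectory, stft_spectrogram

__all__ = [
    "RunConfig",
    "run_all",
    "burst_phase_features",
    "trajectory_features",
    "consistency_report",
    "dispersion_report",
]

DEFAULT_STFT_CONFIGS = (
    {"name": "stft80", "window_ms": 80.0, "overlap_ms": 75.0, "nfft": 160},
    {"name": "stft30", "window_ms": 30.0, "overlap_ms": 25.0, "nfft": 64},
)


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run (JSON-serializable)."""

    seed: int = 0
    # synthesis
    subjects_per_group: int = 2
    bursts_per_subject: int = 50
    fs: float = 2000.0
    session_length_s: float = 60.0
    baseline_sd: float = 0.05
    # preprocessing
    band_low_hz: float = 30.0
    band_high_hz: float = 500.0
    notch_hz: float | None = 50.0
    segmentation: str = "detect"  # or "annotations"
    rms_window_ms: float = 10.0
    k_threshold: float = 5.0
    min_duration_ms: float = 100.0
    merge_gap_ms: float = 30.0
    # phases
    recruit_end_ms: float = 80.0
    sustain_end_ms: float = 150.0
    # time-frequency
    stft_configs: tuple = DEFAULT_STFT_CONFIGS
    cwt_enabled: bool = True
    cwt_fmin_hz: float = 30.0
    cwt_fmax_hz: float = 500.0
    cwt_voices_per_octave: int = 16
    cwt_mu: float = 5.0
    cwt_sigma: float = 0.6
    # NA-MEMD
    memd_enabled: bool = True
    memd_max_seconds: float = 10.0  # per-subject truncation before pooling
    n_noise_channels: int = 3
    noise_sd_ratio: float = 1.0
    n_directions: int = 64
    max_modes: int = 10
    modes_of_interest: tuple[int, ...] = (2, 3, 4)
    # statistics
    stats_enabled: bool = True
    alpha: float = 0.05
    correction: str = "holm"
    unit: str = "burst"

    def partition(self) -> PhasePartition:
        return PhasePartition(self.recruit_end_ms, self.sustain_end_ms)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stft_configs"] = [dict(c) for c in self.stft_configs]
        d["modes_of_interest"] = list(self.modes_of_interest)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "stft_configs" in d:
            d["stft_configs"] = tuple(dict(c) for c in d["stft_configs"])
        if "modes_of_interest" in d:
            d["modes_of_interest"] = tuple(d["modes_of_interest"])
        return cls(**d)


def burst_phase_features(
    traj: SpectralTrajectory,
    burst: BurstSegment,
    partition: PhasePartition,
    source: str,
) -> list[dict]:
    """Phase-averaged F_mean/F_median feature rows for one burst trajectory.

    A frame/sample estimate at time t ms from burst onset contributes to
    recruitment for t in [0, recruit_end), sustained for [recruit_end,
    sustain_end], derecruitment for (sustain_end, duration].
    """
    t_ms = traj.times_s * 1000.0
    bounds = {
        "recruitment": (t_ms >= 0) & (t_ms < partition.recruit_end_ms),
        "sustained": (t_ms >= partition.recruit_end_ms) & (t_ms <= partition.sustain_end_ms),
        "derecruitment": t_ms > partition.sustain_end_ms,
    }
    rows = []
    for metric, vals in (("f_mean", traj.f_mean_hz), ("f_median", traj.f_median_hz)):
        for phase, mask in bounds.items():
            v = vals[mask]
            v = v[np.isfinite(v)]
            rows.append(
                {
                    "subject": burst.subject,
                    "group": burst.group,
                    "burst_id": burst.burst_id,
                    "phase": phase,
                    "source": source,
                    "metric": metric,
                    "value": float(np.mean(v)) if v.size else np.nan,
                }
            )
    return rows


def trajectory_features(
    segments: list[BurstSegment], config: RunConfig
) -> tuple[pd.DataFrame, dict[str, dict[str, list[SpectralTrajectory]]]]:
    """Per-burst STFT/CWT trajectories and their phase-averaged feature rows.

    Returns the tidy feature frame plus the raw per-burst trajectories keyed
    by source then group (for averaged-trajectory outputs).
    """
    partition = config.partition()
    wavelet = BumpWavelet(config.cwt_mu, config.cwt_sigma)
    rows: list[dict] = []
    trajs: dict[str, dict[str, list[SpectralTrajectory]]] = {}
    for seg in segments:
        if partition_phases(seg, partition) is None:
            continue  # too short to host all three phases
        per_source: dict[str, SpectralTrajectory] = {}
        ok = True
        for sc in config.stft_configs:
            try:
                tf = stft_spectrogram(seg, sc["window_ms"], sc["overlap_ms"], sc["nfft"])
            except ValueError:
                ok = False
                break
            per_source[sc["name"]] = spectral_trajectory(tf)
        if not ok:
            continue
        if config.cwt_enabled:
            tf = bump_cwt(seg, wavelet, config.cwt_fmin_hz, config.cwt_fmax_hz,
                          config.cwt_voices_per_octave)
            per_source["cwt"] = spectral_trajectory(tf)
        for source, traj in per_source.items():
            rows.extend(burst_phase_features(traj, seg, partition, source))
            trajs.setdefault(source, {}).setdefault(seg.group, []).append(traj)
    return pd.DataFrame(rows, columns=list(eio.FEATURE_COLUMNS)), trajs


def _group_mean_fmedian_by_phase(
    table: pd.DataFrame, source: str
) -> dict[str, dict[str, float]]:
    sel = table[(table["source"] == source) & (table["metric"] == "f_median")]
    out: dict[str, dict[str, float]] = {}
    for phase, sub in sel.groupby("phase"):
        out[str(phase)] = sub.groupby("group")["value"].mean().to_dict()
    return out


def consistency_report(table: pd.DataFrame, sources: list[str]) -> dict:
    """Rank ordering of group-mean F_median per phase, per source.

    The report exposes whether the STFT and CWT routes agree on the ordering
    of conditions (the cross-method concordance check).
    """
    report: dict = {"sources": {}}
    for source in sources:
        means = _group_mean_fmedian_by_phase(table, source)
        report["sources"][source] = {
            phase: [g for g, _ in sorted(vals.items(), key=lambda kv: -kv[1])]
            for phase, vals in means.items()
        }
    orders = [
        tuple(report["sources"][s].get("derecruitment", [])) for s in sources
        if s in report["sources"]
    ]
    report["derecruitment_orders_agree"] = len(set(orders)) <= 1
    return report


def dispersion_report(
    trajs: dict[str, dict[str, list[SpectralTrajectory]]]
) -> dict[str, dict[str, float]]:
    """Median across time of the group-averaged F_median SEM, per source/group.

    A between-burst dispersion summary: lower values mean the method's
    trajectory estimate varies less from burst to burst.  Reported (not
    asserted) so STFT/CWT smoothness can be compared across conditions.
    """
    out: dict[str, dict[str, float]] = {}
    for source, groups in trajs.items():
        out[source] = {}
        for group, lst in sorted(groups.items()):
            avg = average_trajectories(lst)
            sem = avg.f_median_sem[np.isfinite(avg.f_median_sem)]
            out[source][group] = float(np.median(sem)) if sem.size else float("nan")
    return out


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes annotations, per-group averaged trajectories, the tidy feature
    table, statistics tables, a cross-method consistency report and a
    manifest with the config hash and per-stage row counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "counts": {}}
    config_json = config.to_json()
    (out / "config.json").write_text(config_json)
    manifest["config_sha256"] = hashlib.sha256(config_json.encode()).hexdigest()

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    synth_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    memd_seed = int(seeds[1].generate_state(1)[0] % (2**31))

    # --- stage 1: synthesis -------------------------------------------------
    spec = synth.SessionSpec(
        subjects_per_group=config.subjects_per_group,
        bursts_per_subject=config.bursts_per_subject,
        fs=config.fs,
        session_length_s=config.session_length_s,
        seed=synth_seed,
        baseline_sd=config.baseline_sd,
    )
    recordings, annotations = synth.generate_session(spec)
    eio.write_annotations(annotations, out / "annotations_truth.csv")
    manifest["counts"]["recordings"] = len(recordings)
    manifest["counts"]["annotated_bursts"] = len(annotations)

    # --- stage 2: filtering + segmentation ---------------------------------
    filtered = [
        bandpass_notch(r, config.band_low_hz, config.band_high_hz, config.notch_hz)
        for r in recordings
    ]
    segments: list[BurstSegment] = []
    if config.segmentation == "detect":
        for rec in filtered:
            segments.extend(
                detect_bursts(
                    rec,
                    rms_window_ms=config.rms_window_ms,
                    k_threshold=config.k_threshold,
                    min_duration_ms=config.min_duration_ms,
                    merge_gap_ms=config.merge_gap_ms,
                )
            )
    elif config.segmentation == "annotations":
        by_subject = {a.subject: [] for a in annotations}
        for a in annotations:
            by_subject[a.subject].append(a)
        for rec in filtered:
            segments.extend(extract_segments(rec, by_subject.get(rec.channel_meta[0].subject, [])))
    else:
        raise ValueError(f"unknown segmentation mode {config.segmentation!r}")
    detected = [
        eio.BurstAnnotation(s.subject, s.group, s.burst_id, s.onset_s, s.offset_s)
        for s in segments
    ]
    eio.write_annotations(detected, out / "annotations_detected.csv")
    manifest["counts"]["detected_bursts"] = len(segments)

    # --- stage 3: STFT + CWT trajectories and phase features ----------------
    table, trajs = trajectory_features(segments, config)
    for source, groups in trajs.items():
        avg_rows = []
        for group, lst in sorted(groups.items()):
            avg = average_trajectories(lst)
            for i in range(avg.times_s.size):
                avg_rows.append(
                    {
                        "group": group,
                        "time_s": avg.times_s[i],
                        "f_mean_hz": avg.f_mean_hz[i],
                        "f_mean_sem": avg.f_mean_sem[i],
                        "f_median_hz": avg.f_median_hz[i],
                        "f_median_sem": avg.f_median_sem[i],
                        "n": int(avg.n_valid[i]),
                    }
                )
        pd.DataFrame(avg_rows).to_csv(
            out / f"trajectory_{source}.csv", index=False, float_format=eio.FLOAT_FMT
        )

    # --- stage 4: NA-MEMD + Hilbert features --------------------------------
    if config.memd_enabled:
        n_keep = int(round(config.memd_max_seconds * config.fs))
        n_keep = min(n_keep, min(r.n_samples for r in filtered))
        pooled = eio.Recording(
            samples=np.vstack([r.samples[0, :n_keep] for r in filtered]),
            fs=config.fs,
            channel_meta=[r.channel_meta[0] for r in filtered],
        )
        imfset = ememd.na_memd(
            pooled,
            n_noise_channels=config.n_noise_channels,
            noise_sd_ratio=config.noise_sd_ratio,
            n_directions=config.n_directions,
            max_modes=config.max_modes,
            seed=memd_seed,
        )
        series = ememd.hilbert_if_ie(imfset)
        ann_in = [a for a in annotations if a.offset_s <= config.memd_max_seconds]
        imf_table = ememd.segment_imfs(
            imfset, series, ann_in, config.partition(), config.modes_of_interest
        )
        freqs, spectra, ranges = ememd.imf_marginal_spectra(imfset)
        spec_df = pd.DataFrame(spectra.T, columns=[f"imf{m + 1}" for m in range(spectra.shape[0])])
        spec_df.insert(0, "freq_hz", freqs)
        spec_df.to_csv(out / "imf_marginal_spectra.csv", index=False, float_format=eio.FLOAT_FMT)
        (out / "imf_dominant_ranges.json").write_text(
            json.dumps({f"imf{m + 1}": r for m, r in enumerate(ranges)}, indent=1)
        )
        table = pd.concat([table, imf_table], ignore_index=True)
        manifest["counts"]["imf_modes"] = int(imfset.n_modes)
        manifest["counts"]["imf_feature_rows"] = len(imf_table)

    manifest["counts"]["feature_rows"] = len(table)
    if len(table):
        eio.write_feature_table(table, out / "features.csv")

    # --- stage 5: statistics -------------------------------------------------
    if config.stats_enabled and len(table):
        summary, pairwise = estats.run_stat_battery(
            table, alpha=config.alpha, correction=config.correction, unit=config.unit
        )
        summary.to_csv(out / "stats_summary.csv", index=False, float_format=eio.FLOAT_FMT)
        pairwise.to_csv(out / "stats_pairwise.csv", index=False, float_format=eio.FLOAT_FMT)
        manifest["counts"]["stats_tests"] = len(summary)

    sources = [c["name"] for c in config.stft_configs]
    if config.cwt_enabled:
        sources.append("cwt")
    report = consistency_report(table, sources)
    report["f_median_sem_by_source"] = dispersion_report(trajs)
    (out / "consistency.json").write_text(json.dumps(report, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
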