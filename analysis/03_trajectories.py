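#!/usr/bin/env python
"""Per-burst STFT (80 ms and 30 ms) and Bump-CWT trajectories.

Reads the filtered recordings and detected bursts, writes the tidy
phase-feature table (``results/features_trajectories.csv``), per-group
averaged F_median trajectories per method, and an SVG overview figure.
"""

from __future__ import annotations

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, ensure

from emgtf import io as eio
from emgtf.io import CONDITIONS
from emgtf.pipeline import trajectory_features
from emgtf.preprocess import bandpass_notch, extract_segments
from emgtf.spectrogram import average_trajectories


def main() -> None:
    ensure(RESULTS)
    annotations = eio.read_annotations(RESULTS / "annotations_detected.csv")
    segments = []
    for path in sorted(DATA.glob("*.wav")):
        rec = bandpass_notch(eio.read_recording(path))
        subj = rec.channel_meta[0].subject
        segments.extend(
            extract_segments(rec, [a for a in annotations if a.subject == subj])
        )
    table, trajs = trajectory_features(segments, CONFIG)
    eio.write_feature_table(table, RESULTS / "features_trajectories.csv")

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    rows = []
    for ax, source in zip(axes, ("stft80", "stft30", "cwt")):
        for group in CONDITIONS:
            avg = average_trajectories(trajs[source][group])
            ax.plot(avg.times_s * 1e3, avg.f_median_hz, label=group)
            for i in range(avg.times_s.size):
                rows.append({"source": source, "group": group,
                             "time_ms": avg.times_s[i] * 1e3,
                             "f_median_hz": avg.f_median_hz[i],
                             "f_median_sem": avg.f_median_sem[i],
                             "n": int(avg.n_valid[i])})
        ax.set_title(source)
        ax.set_xlabel("time from burst onset (ms)")
    axes[0].set_ylabel("F_median (Hz)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(RESULTS / "trajectories.svg")
    pd.DataFrame(rows).to_csv(RESULTS / "trajectories_group_mean.csv",
                              index=False, float_format=eio.FLOAT_FMT)
    print(f"{len(segments)} bursts -> {len(table)} feature rows; "
          f"figure results/trajectories.svg")


if __name__ == "__main__":
    main()
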