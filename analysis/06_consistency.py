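#!/usr/bin/env python
"""Cross-method consistency: rank orderings and dispersion per method.

Summarizes whether the STFT (80/30 ms) and CWT routes agree on the ordering
of conditions per contraction phase, and compares between-burst dispersion
(median SEM of the group-averaged F_median trajectory) across methods.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, ensure

from emgtf import io as eio
from emgtf.pipeline import consistency_report, dispersion_report, trajectory_features
from emgtf.preprocess import bandpass_notch, extract_segments


def main() -> None:
    ensure(RESULTS)
    table = eio.read_feature_table(RESULTS / "features_trajectories.csv")
    report = consistency_report(table, ["stft80", "stft30", "cwt"])

    annotations = eio.read_annotations(RESULTS / "annotations_detected.csv")
    segments = []
    for path in sorted(DATA.glob("*.wav")):
        rec = bandpass_notch(eio.read_recording(path))
        subj = rec.channel_meta[0].subject
        segments.extend(
            extract_segments(rec, [a for a in annotations if a.subject == subj])
        )
    _, trajs = trajectory_features(segments, CONFIG)
    report["f_median_sem_by_source"] = dispersion_report(trajs)

    (RESULTS / "consistency.json").write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
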