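#!/usr/bin/env python
"""Filter the benchmark recordings and detect contraction bursts.

Reads ``results/data/*.wav``, writes detected annotations and a small
detection-quality report (onset/offset errors vs ground truth).
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS, ensure

from emgtf import io as eio
from emgtf.preprocess import bandpass_notch, detect_bursts


def main() -> None:
    ensure(RESULTS)
    truth = eio.read_annotations(DATA / "annotations_truth.csv")
    detected = []
    onset_err, offset_err = [], []
    for path in sorted(DATA.glob("*.wav")):
        rec = eio.read_recording(path)
        segs = detect_bursts(bandpass_notch(rec))
        subj = rec.channel_meta[0].subject
        detected.extend(
            eio.BurstAnnotation(s.subject, s.group, s.burst_id, s.onset_s, s.offset_s)
            for s in segs
        )
        t = [a for a in truth if a.subject == subj]
        if len(segs) == len(t):
            onset_err.extend((s.onset_s - a.onset_s) * 1e3 for s, a in zip(segs, t))
            offset_err.extend((s.offset_s - a.offset_s) * 1e3 for s, a in zip(segs, t))
    eio.write_annotations(detected, RESULTS / "annotations_detected.csv")
    report = {
        "n_truth": len(truth),
        "n_detected": len(detected),
        "onset_err_ms_mean_abs": float(np.mean(np.abs(onset_err))),
        "onset_err_ms_max_abs": float(np.max(np.abs(onset_err))),
        "offset_err_ms_mean_abs": float(np.mean(np.abs(offset_err))),
    }
    (RESULTS / "detection_report.json").write_text(json.dumps(report, indent=1))
    print(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
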