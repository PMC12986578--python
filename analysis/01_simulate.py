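#!/usr/bin/env python
"""Generate the synthetic locomotor-EMG benchmark sessions.

Writes one WAV recording per synthetic subject plus the ground-truth burst
annotations to ``results/data/``.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, ensure

from emgtf import io as eio
from emgtf.synth import SessionSpec, generate_session


def main() -> None:
    out = ensure(DATA)
    spec = SessionSpec(
        subjects_per_group=CONFIG.subjects_per_group,
        bursts_per_subject=CONFIG.bursts_per_subject,
        fs=CONFIG.fs,
        session_length_s=CONFIG.session_length_s,
        seed=CONFIG.seed,
    )
    recordings, annotations = generate_session(spec)
    for rec in recordings:
        eio.write_recording(rec, out / f"{rec.channel_meta[0].subject}.wav")
    eio.write_annotations(annotations, out / "annotations_truth.csv")
    print(f"wrote {len(recordings)} recordings, {len(annotations)} bursts -> {out}")


if __name__ == "__main__":
    main()
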