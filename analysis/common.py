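"""Shared configuration for the numbered analysis drivers.

Every driver reads/writes under ``results/`` relative to the repository root
and uses one benchmark configuration, so the scripts can be run in order
(01 -> 06) or individually after their inputs exist.
"""

from __future__ import annotations

from pathlib import Path

from emgtf.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

#: the seeded default benchmark: 5 conditions x 2 subjects x 100 bursts
CONFIG = RunConfig(
    seed=20240917,
    subjects_per_group=2,
    bursts_per_subject=100,
    session_length_s=80.0,
    memd_max_seconds=10.0,
)


def ensure(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path
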