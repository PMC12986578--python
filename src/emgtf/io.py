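"""Plain-text I/O for recordings, burst annotations and tidy feature tables.

Signal containers are deliberately simple: a CSV file (``time_s`` column plus
one value column per channel) or a PCM-16 WAV file, each with a JSON sidecar
carrying ``fs_hz``, ``scale``, ``subject`` and ``group``.  Annotation and
feature tables are CSV with fixed column order and deterministic row order so
that repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: canonical ordering of the experimental conditions, mildest first
CONDITIONS = ("control", "week3", "week4", "week5", "week6")

#: fixed column order of the tidy per-burst feature table
FEATURE_COLUMNS = ("subject", "group", "burst_id", "phase", "source", "metric", "value")

ANNOTATION_COLUMNS = ("subject", "group", "burst_id", "onset_s", "offset_s")

#: float formatting used by every writer (9 significant digits)
FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """Raised when a signal container or table violates its documented schema."""


@dataclass
class ChannelMeta:
    """Per-channel metadata: which subject/condition a channel belongs to."""

    subject: str
    group: str
    is_noise_channel: bool = False


@dataclass
class Recording:
    """A continuous multichannel recording.

    ``samples`` has shape (n_channels, n_samples); all channels share the
    sampling rate ``fs`` (Hz) and are equal length.
    """

    samples: np.ndarray
    fs: float
    channel_meta: list[ChannelMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_meta and len(self.channel_meta) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_meta)} channel_meta entries for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class BurstAnnotation:
    """Ground-truth or detected burst interval, half-open [onset_s, offset_s)."""

    subject: str
    group: str
    burst_id: int
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise FormatError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write one recording to CSV (exact) or WAV (PCM-16) plus a JSON sidecar."""
    path = Path(path)
    meta0 = rec.channel_meta[0] if rec.channel_meta else ChannelMeta("unknown", "unknown")
    sidecar = {
        "fs_hz": rec.fs,
        "subject": meta0.subject,
        "group": meta0.group,
    }
    if path.suffix.lower() == ".wav":
        peak = float(np.max(np.abs(rec.samples))) or 1.0
        scale = peak / 32767.0
        pcm = np.round(rec.samples / scale).astype(np.int16)
        wavfile.write(path, int(rec.fs), pcm.T)  # wav expects (samples, channels)
        sidecar["scale"] = scale
    elif path.suffix.lower() == ".csv":
        t = np.arange(rec.n_samples) / rec.fs
        cols = {"time_s": t}
        for i in range(rec.n_channels):
            cols[f"value_{i}" if rec.n_channels > 1 else "value"] = rec.samples[i]
        pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
        sidecar["scale"] = 1.0
    else:
        raise FormatError(f"unsupported signal container suffix: {path.suffix}")
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording(path: str | Path) -> Recording:
    """Read a CSV or WAV signal container back into a :class:`Recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _read_sidecar(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        scale = float(sidecar.get("scale", 1.0))
        samples = np.atleast_2d(data.astype(float).T) * scale
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        value_cols = [c for c in df.columns if c != "time_s"]
        if not value_cols:
            raise FormatError(f"{path}: no value columns")
        if df[value_cols].isna().any().any():
            raise FormatError(f"{path}: ragged channels (missing samples)")
        samples = df[value_cols].to_numpy(dtype=float).T
        if "fs_hz" in sidecar:
            fs = float(sidecar["fs_hz"])
        elif "time_s" in df.columns and len(df) > 1:
            dt = np.diff(df["time_s"].to_numpy())
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise FormatError(f"{path}: non-uniform time axis")
            fs = 1.0 / dt[0]
        else:
            raise FormatError(f"{path}: sampling rate unavailable (no sidecar fs_hz)")
    else:
        raise FormatError(f"unsupported signal container suffix: {path.suffix}")
    subject = str(sidecar.get("subject", path.stem))
    group = str(sidecar.get("group", "unknown"))
    meta = [ChannelMeta(subject, group) for _ in range(samples.shape[0])]
    return Recording(samples=samples, fs=float(fs), channel_meta=meta)


def write_annotations(annotations: list[BurstAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject": a.subject,
                "group": a.group,
                "burst_id": a.burst_id,
                "onset_s": a.onset_s,
                "offset_s": a.offset_s,
            }
            for a in annotations
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    df = df.sort_values(["subject", "burst_id"]).reset_index(drop=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_annotations(path: str | Path) -> list[BurstAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    return [
        BurstAnnotation(
            subject=str(r.subject),
            group=str(r.group),
            burst_id=int(r.burst_id),
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
        )
        for r in df.itertuples()
    ]


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy feature-table schema; returns the column-ordered frame."""
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"feature table missing columns {sorted(missing)}")
    keys = ["subject", "burst_id", "phase", "source", "metric"]
    if table.duplicated(subset=keys).any():
        raise FormatError("feature table has duplicate (subject, burst, phase, source, metric) keys")
    return table.loc[:, list(FEATURE_COLUMNS)]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy feature table; rows sorted by all key columns, NaN -> ''."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    out = validate_feature_table(table)
    out = out.sort_values(list(FEATURE_COLUMNS[:-1]), kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False, float_format=FLOAT_FMT, na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str, "group": str})
    return validate_feature_table(df)
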