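"""Readers and writers for every on-disk artifact.

All tabular artifacts are CSV; audio is WAV; reports and run metadata are
JSON; configs are YAML.  Readers validate and reject malformed input
rather than coercing it; every writer produces files its paired reader
round-trips losslessly.

Time is expressed in seconds from performance start and motif slices are
half-open ``[start_s, end_s)`` so adjacent motifs never share frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "MotifRecord",
    "ValidationError",
    "SEGMENTS",
    "read_motif_table",
    "write_motif_table",
    "read_kinematics",
    "write_kinematics",
    "read_feature_series",
    "write_feature_series",
    "read_audio",
    "write_audio",
    "read_distance_table",
    "write_distance_table",
    "slice_motif",
]

SEGMENTS = ("head", "hand_L", "hand_R", "shoulder_L", "shoulder_R", "pelvis")

MOTIF_COLUMNS = ("motif_id", "performance_id", "performer_id", "start_s", "end_s")
KIN_COLUMNS = ("t", "segment", "px", "py", "pz", "vx", "vy", "vz", "ax", "ay", "az")

MIN_MOTIF_DURATION_S = 1.5


class ValidationError(ValueError):
    """Malformed on-disk input."""


@dataclass(frozen=True)
class MotifRecord:
    """One segmented vocal motif with timing and provenance."""

    motif_id: str
    performance_id: str
    performer_id: str
    start_s: float
    end_s: float
    raga_id: str | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _validate_motifs(records: list[MotifRecord]) -> None:
    seen: set[str] = set()
    for k, rec in enumerate(records):
        row = f"row {k} (motif {rec.motif_id!r})"
        if rec.motif_id in seen:
            raise ValidationError(f"{row}: duplicate motif_id")
        seen.add(rec.motif_id)
        if not rec.end_s > rec.start_s:
            raise ValidationError(f"{row}: end_s ({rec.end_s}) <= start_s ({rec.start_s})")
        if rec.duration_s < MIN_MOTIF_DURATION_S:
            raise ValidationError(
                f"{row}: duration {rec.duration_s:.3f} s below the "
                f"{MIN_MOTIF_DURATION_S} s segmentation floor"
            )
    by_perf: dict[str, list[MotifRecord]] = {}
    for rec in records:
        by_perf.setdefault(rec.performance_id, []).append(rec)
    for perf, recs in by_perf.items():
        recs = sorted(recs, key=lambda r: r.start_s)
        for prev, cur in zip(recs, recs[1:]):
            if cur.start_s < prev.end_s:
                raise ValidationError(
                    f"performance {perf!r}: motifs {prev.motif_id!r} and "
                    f"{cur.motif_id!r} overlap"
                )


def read_motif_table(path: str | Path) -> list[MotifRecord]:
    """Read and validate a motif segmentation table.

    Rejects missing columns, duplicate ids, nonpositive or sub-floor
    durations, and overlapping motifs within a performance, naming the
    offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in MOTIF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    for _, r in df.iterrows():
        records.append(
            MotifRecord(
                motif_id=str(r["motif_id"]),
                performance_id=str(r["performance_id"]),
                performer_id=str(r["performer_id"]),
                start_s=float(r["start_s"]),
                end_s=float(r["end_s"]),
                raga_id=str(r["raga_id"]) if "raga_id" in df.columns and pd.notna(r.get("raga_id")) else None,
            )
        )
    _validate_motifs(records)
    return records


def write_motif_table(records: list[MotifRecord], path: str | Path) -> None:
    rows = [
        {
            "motif_id": r.motif_id,
            "performance_id": r.performance_id,
            "performer_id": r.performer_id,
            "start_s": r.start_s,
            "end_s": r.end_s,
            **({"raga_id": r.raga_id} if r.raga_id is not None else {}),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def motif_frame(records: list[MotifRecord]) -> pd.DataFrame:
    """Motif records as a DataFrame (ordering preserved)."""
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in records],
            "performance_id": [r.performance_id for r in records],
            "performer_id": [r.performer_id for r in records],
            "start_s": [r.start_s for r in records],
            "end_s": [r.end_s for r in records],
        }
    )


def read_kinematics(path: str | Path, rate_hz: float = 60.0) -> dict[str, dict[str, np.ndarray]]:
    """Read a per-frame motion-tracking CSV for one performance.

    Returns ``{segment: {"t": (n,), "pos": (n,3), "vel": (n,3), "acc": (n,3)}}``
    with frames sorted by time.  Unknown segment labels and non-uniform
    frame grids (beyond one-sample jitter) are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in KIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    unknown = sorted(set(df["segment"]) - set(SEGMENTS))
    if unknown:
        raise ValidationError(
            f"{path}: unknown segment labels {unknown}; allowed: {list(SEGMENTS)}"
        )
    if not np.all(np.isfinite(df[[c for c in KIN_COLUMNS if c != "segment"]].to_numpy())):
        raise ValidationError(f"{path}: non-finite values")
    out: dict[str, dict[str, np.ndarray]] = {}
    for seg, g in df.groupby("segment"):
        g = g.sort_values("t", kind="mergesort")
        t = g["t"].to_numpy(float)
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValidationError(f"{path}: segment {seg!r} has duplicate time stamps")
            jitter = np.abs(dt - 1.0 / rate_hz)
            if np.any(jitter > 1.0 / rate_hz):
                warnings.warn(
                    f"{path}: segment {seg!r} has frame gaps larger than one "
                    f"sample at {rate_hz} Hz",
                    stacklevel=2,
                )
        out[str(seg)] = {
            "t": t,
            "pos": g[["px", "py", "pz"]].to_numpy(float),
            "vel": g[["vx", "vy", "vz"]].to_numpy(float),
            "acc": g[["ax", "ay", "az"]].to_numpy(float),
        }
    return out


def write_kinematics(frames: dict[str, dict[str, np.ndarray]], path: str | Path) -> None:
    parts = []
    for seg in sorted(frames):
        d = frames[seg]
        part = pd.DataFrame(
            {
                "t": d["t"],
                "segment": seg,
                "px": d["pos"][:, 0], "py": d["pos"][:, 1], "pz": d["pos"][:, 2],
                "vx": d["vel"][:, 0], "vy": d["vel"][:, 1], "vz": d["vel"][:, 2],
                "ax": d["acc"][:, 0], "ay": d["acc"][:, 1], "az": d["acc"][:, 2],
            }
        )
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_feature_series(path: str | Path, value_col: str = "value") -> tuple[np.ndarray, np.ndarray]:
    """Read a (t, value) series CSV; returns (t, value) arrays sorted by t."""
    df = pd.read_csv(path)
    for c in ("t", value_col):
        if c not in df.columns:
            raise ValidationError(f"{path}: missing column {c!r}")
    df = df.sort_values("t", kind="mergesort")
    return df["t"].to_numpy(float), df[value_col].to_numpy(float)


def write_feature_series(t: np.ndarray, value: np.ndarray, path: str | Path, value_col: str = "value") -> None:
    pd.DataFrame({"t": t, value_col: value}).to_csv(path, index=False)


def read_audio(path: str | Path) -> tuple[np.ndarray, int]:
    """Read WAV as mono float64 in [-1, 1]; multichannel input is averaged."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, int(sr)


def write_audio(waveform: np.ndarray, sample_rate: int, path: str | Path) -> None:
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))


def slice_motif(values: np.ndarray, rate_hz: float, record: MotifRecord, t0: float = 0.0) -> np.ndarray:
    """Half-open slice ``[start_s, end_s)`` of a uniform series at its native rate.

    ``values`` may be 1-D or (n, d); ``t0`` is the time of the first sample.
    """
    values = np.asarray(values)
    i0 = int(np.floor((record.start_s - t0) * rate_hz + 0.5))
    i1 = int(np.floor((record.end_s - t0) * rate_hz + 0.5))
    if i0 < 0 or i1 > values.shape[0]:
        raise ValidationError(
            f"motif {record.motif_id!r} [{record.start_s}, {record.end_s}) s lies "
            f"outside the series extent ({values.shape[0]} samples at {rate_hz} Hz "
            f"from t0={t0})"
        )
    return values[i0:i1]


def write_distance_table(table: pd.DataFrame, path: str | Path) -> None:
    from .dtw import FEATURE_COLUMNS, PAIR_COLUMNS

    cols = list(PAIR_COLUMNS) + list(FEATURE_COLUMNS)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"distance table missing columns {missing}")
    path = Path(path)
    if path.suffix == ".parquet":
        table[cols].to_parquet(path, index=False)
    else:
        table[cols].to_csv(path, index=False, float_format="%.12g")


def read_distance_table(path: str | Path) -> pd.DataFrame:
    from .dtw import FEATURE_COLUMNS, PAIR_COLUMNS

    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    cols = list(PAIR_COLUMNS) + list(FEATURE_COLUMNS)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: distance table missing columns {missing}")
    vals = df[list(FEATURE_COLUMNS)].to_numpy(float)
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValidationError(f"{path}: distances must be finite and >= 0")
    return df[cols]
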