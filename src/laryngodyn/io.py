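"""CSV interchange formats and run configuration.

Interchange dialects (all plain CSV, missing values as empty fields):

* fiducial frames — ``participant_id, frame_index, time_ms, lx, ly, lz,
  rx, ry, rz, ga_mm2, is_vocalizing`` (one row per participant x frame);
* participant records — ``participant_id, condition, age_years, sex,
  duration_months, updrs3``;
* measure summaries — one row per participant with the
  :class:`~laryngodyn.measures.MeasureSummary` fields.

The fiducial reader validates frame structure per participant (uniform frame
interval, strictly increasing frame indices, finite coordinates, no duplicate
frames) and rejects — with a logged reason — any participant whose frame
interval deviates from the expected 100 ms, unless overridden.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, CsvFormatError
from .measures import (
    DEFAULT_FRAME_INTERVAL_MS,
    FiducialFrame,
    MeasureSummary,
    PhonationSeries,
)
from .records import ParticipantRecord

logger = logging.getLogger(__name__)

FIDUCIAL_COLUMNS = [
    "participant_id", "frame_index", "time_ms",
    "lx", "ly", "lz", "rx", "ry", "rz", "ga_mm2", "is_vocalizing",
]
RECORD_COLUMNS = [
    "participant_id", "condition", "age_years", "sex",
    "duration_months", "updrs3",
]

_INTERVAL_TOL_MS = 1e-6


def write_fiducial_csv(series_list: Iterable[PhonationSeries], path) -> None:
    """Write phonation series in the tidy fiducial dialect."""
    rows = []
    for s in series_list:
        for f, m in zip(s.frames, s.vocalization_mask):
            left = f.left_marker
            right = f.right_marker
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "frame_index": f.frame_index,
                    "time_ms": f.time_ms,
                    "lx": left[0] if left is not None else np.nan,
                    "ly": left[1] if left is not None else np.nan,
                    "lz": left[2] if left is not None else np.nan,
                    "rx": right[0] if right is not None else np.nan,
                    "ry": right[1] if right is not None else np.nan,
                    "rz": right[2] if right is not None else np.nan,
                    "ga_mm2": f.ga if f.ga is not None else np.nan,
                    "is_vocalizing": int(m),
                }
            )
    df = pd.DataFrame(rows, columns=FIDUCIAL_COLUMNS)
    df.to_csv(path, index=False)


class FiducialReadResult(NamedTuple):
    series: list[PhonationSeries]
    rejected: dict[str, str]   # participant_id -> reason


def _row_floats(row: pd.Series, cols: list[str], line: int) -> list[float]:
    vals = []
    for c in cols:
        v = row[c]
        if pd.isna(v):
            vals.append(math.nan)
            continue
        try:
            vals.append(float(v))
        except (TypeError, ValueError):
            raise CsvFormatError(
                f"non-numeric value {v!r} in column {c!r}", line=line
            ) from None
    return vals


def read_fiducial_csv(
    path,
    expected_interval_ms: float = DEFAULT_FRAME_INTERVAL_MS,
    allow_interval_mismatch: bool = False,
) -> FiducialReadResult:
    """Read phonation series, validating structure row by row.

    Participants whose frame interval deviates from ``expected_interval_ms``
    are rejected (not raised) and reported in ``rejected`` — mirroring the
    exclusion of acquisitions reconstructed at a non-standard frame rate —
    unless ``allow_interval_mismatch`` is set. Structural defects (malformed
    values, duplicate frames, non-monotone indices) raise
    :class:`~laryngodyn.errors.CsvFormatError` with the offending line number.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in FIDUCIAL_COLUMNS if c not in df.columns]
    if missing:
        raise CsvFormatError(f"missing column(s) {missing} in {path}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1

    series_out: list[PhonationSeries] = []
    rejected: dict[str, str] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        frames: list[FiducialFrame] = []
        mask: list[bool] = []
        seen: set[int] = set()
        times: list[float] = []
        for _, row in grp.iterrows():
            line = int(row["_line"])
            idx_f, t = _row_floats(row, ["frame_index", "time_ms"], line)
            if math.isnan(idx_f) or idx_f != int(idx_f):
                raise CsvFormatError(
                    f"bad frame_index {row['frame_index']!r}", line=line
                )
            idx = int(idx_f)
            if idx in seen:
                raise CsvFormatError(
                    f"duplicate frame {idx} for participant {pid}", line=line
                )
            if seen and idx <= max(seen):
                raise CsvFormatError(
                    f"frame indices not increasing for participant {pid}",
                    line=line,
                )
            seen.add(idx)
            lx, ly, lz, rx, ry, rz = _row_floats(
                row, ["lx", "ly", "lz", "rx", "ry", "rz"], line
            )
            for c, v in zip(("lx", "ly", "lz", "rx", "ry", "rz"),
                            (lx, ly, lz, rx, ry, rz)):
                if math.isinf(v):
                    raise CsvFormatError(
                        f"non-finite coordinate in column {c!r}", line=line
                    )
            left = None if any(map(math.isnan, (lx, ly, lz))) else (lx, ly, lz)
            right = None if any(map(math.isnan, (rx, ry, rz))) else (rx, ry, rz)
            (ga,) = _row_floats(row, ["ga_mm2"], line)
            (voc,) = _row_floats(row, ["is_vocalizing"], line)
            try:
                frames.append(
                    FiducialFrame(
                        frame_index=idx, time_ms=t,
                        left_marker=left, right_marker=right,
                        ga=None if math.isnan(ga) else ga,
                    )
                )
            except ValueError as exc:
                raise CsvFormatError(str(exc), line=line) from None
            mask.append(bool(voc))
            times.append(t)

        diffs = np.diff(times) / np.diff(sorted(seen))
        if len(diffs) == 0:
            rejected[str(pid)] = "single frame"
            logger.warning("participant %s rejected: single frame", pid)
            continue
        interval = float(diffs[0])
        if np.any(np.abs(diffs - interval) > _INTERVAL_TOL_MS):
            rejected[str(pid)] = "non-uniform frame interval"
            logger.warning(
                "participant %s rejected: non-uniform frame interval", pid
            )
            continue
        if (
            not allow_interval_mismatch
            and abs(interval - expected_interval_ms) > _INTERVAL_TOL_MS
        ):
            reason = (
                f"frame interval {interval:g} ms != expected "
                f"{expected_interval_ms:g} ms"
            )
            rejected[str(pid)] = reason
            logger.warning("participant %s rejected: %s", pid, reason)
            continue
        series_out.append(
            PhonationSeries(
                participant_id=str(pid),
                frame_interval_ms=interval,
                frames=tuple(frames),
                vocalization_mask=np.array(mask, dtype=bool),
            )
        )
    return FiducialReadResult(series=series_out, rejected=rejected)


def write_records_csv(records: Iterable[ParticipantRecord], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "condition": r.condition,
            "age_years": r.age_years,
            "sex": r.sex,
            "duration_months": (
                r.duration_months if r.duration_months is not None else np.nan
            ),
            "updrs3": r.updrs3,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str, "sex": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise CsvFormatError(f"missing column(s) {missing} in {path}")
    out = []
    for i, row in df.iterrows():
        line = int(i) + 2
        dur = row["duration_months"]
        try:
            out.append(
                ParticipantRecord(
                    participant_id=str(row["participant_id"]),
                    condition=str(row["condition"]),
                    age_years=float(row["age_years"]),
                    sex=str(row["sex"]),
                    duration_months=None if pd.isna(dur) else float(dur),
                    updrs3=float(row["updrs3"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CsvFormatError(str(exc), line=line) from None
    return out


def write_summaries_csv(summaries: Iterable[MeasureSummary], path) -> None:
    from dataclasses import asdict

    df = pd.DataFrame([asdict(s) for s in summaries])
    df.to_csv(path, index=False)


def read_summaries_csv(path) -> list[MeasureSummary]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in row.index}
        for k in ("n_frames_ga", "n_frames_iad", "n_frames_iai",
                  "n_velocity_pairs"):
            kwargs[k] = int(kwargs[k])
        for k, v in list(kwargs.items()):
            if isinstance(v, (np.floating, np.integer)):
                kwargs[k] = v.item()
        out.append(MeasureSummary(**kwargs))
    return out


def write_frames_csv(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, index=False)


def read_frames_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    out_dir: str = "laryngodyn_out"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "measure", "analyze", "report")
    #: overrides applied to SyntheticCohortConfig fields
    cohort: dict = field(default_factory=dict)
    #: input directory holding fiducial.csv / records.csv when simulate is off
    input_dir: str | None = None
    trim_factor: float = 2.0
    #: frames additionally excluded just inside each trim boundary
    trim_guard_frames: int = 1
    velocity_variant: str = "displacement"
    expected_interval_ms: float = DEFAULT_FRAME_INTERVAL_MS
    allow_interval_mismatch: bool = False
    #: analysis switches, applied onto stats.AnalysisConfig fields
    analysis: dict = field(default_factory=dict)
    figures: bool = False
    log_level: str = "INFO"

    VALID_STAGES = ("simulate", "measure", "analyze", "report")

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in self.VALID_STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s) {bad}")
        if self.trim_factor <= 0:
            raise ConfigError("trim_factor must be positive")
        if self.trim_guard_frames < 0:
            raise ConfigError("trim_guard_frames must be >= 0")
        if self.velocity_variant not in ("displacement", "iad-delta"):
            raise ConfigError(
                f"unknown velocity_variant {self.velocity_variant!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_canonical_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
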