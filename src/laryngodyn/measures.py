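"""Per-frame and per-participant laryngeal kinematic measures.

Definitions
-----------
Given left/right fiducial markers placed at the most medial aspect of each
arytenoid cartilage on every reconstructed frame (100 ms apart by default):

* **IAD** — inter-arytenoid distance, the Euclidean distance between the two
  markers, mm.
* **GA** — glottic area, the segmented air area at the level of the vocal
  folds, mm^2 (measured per frame; may be missing on some frames).
* **IAI** — IAD-Area index, the dimensionless per-frame ratio GA / IAD. A
  disproportionately high GA at a given IAD indicates vocal-fold bowing.
* **av** — arytenoid velocity, the summed distance the left and right markers
  moved between successive frames, mm per frame interval, classified as
  adduction (IAD decreased), abduction (IAD increased) or stationary.
* **effective minimum / maximum** — the median of the five lowest / highest
  per-frame values across the vocalization period (the task is five short
  phonations), a robust stand-in for the raw extremum.

The pre- and post-vocalization periods, during which the glottis is wide open
and GA/IAD are strikingly higher, are excluded by an automatic trimming rule
(:func:`trim_to_vocalization`) before summarising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UnusableSeriesError
from .imaging import GlottisImage, segment_glottic_area  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

DEFAULT_FRAME_INTERVAL_MS = 100.0
#: |delta IAD| below this is classified as stationary (float safety).
STATIONARY_TOL_MM = 1e-6
#: Number of order statistics entering an effective extremum (five phonations).
EFFECTIVE_K = 5
DEFAULT_TRIM_FACTOR = 2.0

_TIME_TOL_MS = 1e-6


class Direction(str, Enum):
    """Direction of arytenoid movement over one frame interval."""

    ADDUCTION = "adduction"
    ABDUCTION = "abduction"
    STATIONARY = "stationary"


def _as_point(p, name: str) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite coordinates: {a}")
    return a


def compute_iad(left_marker, right_marker) -> float:
    """Inter-arytenoid distance: Euclidean distance between the markers, mm."""
    left = _as_point(left_marker, "left_marker")
    right = _as_point(right_marker, "right_marker")
    return float(np.linalg.norm(left - right))


def compute_iai(ga: float, iad: float) -> float:
    """IAD-Area index GA / IAD (dimensionless) for one frame.

    The mean IAI of a series is the mean of per-frame ratios, never the ratio
    of means. Undefined for non-positive IAD.
    """
    if not np.isfinite(ga) or ga < 0:
        raise ValueError(f"ga must be finite and >= 0, got {ga}")
    if not np.isfinite(iad) or iad <= 0:
        raise ValueError(f"iai undefined for iad={iad}")
    return float(ga) / float(iad)


@dataclass(frozen=True)
class FiducialFrame:
    """One reconstructed frame: marker pair plus optional glottic area.

    Either marker (or the GA) may be absent on a frame — e.g. not reliably
    placeable — in which case the measures that need it are simply not defined
    for that frame and per-measure frame counts diverge.
    """

    frame_index: int
    time_ms: float
    left_marker: np.ndarray | None
    right_marker: np.ndarray | None
    ga: float | None = None

    def __post_init__(self) -> None:
        for name in ("left_marker", "right_marker"):
            p = getattr(self, name)
            if p is not None:
                object.__setattr__(self, name, _as_point(p, name))
        if self.ga is not None:
            ga = float(self.ga)
            if not np.isfinite(ga) or ga < 0:
                raise ValueError(f"ga must be finite and >= 0, got {ga}")
            object.__setattr__(self, "ga", ga)

    @property
    def iad(self) -> float:
        """IAD of this frame, or NaN when a marker is missing."""
        if self.left_marker is None or self.right_marker is None:
            return float("nan")
        return compute_iad(self.left_marker, self.right_marker)

    @property
    def has_markers(self) -> bool:
        return self.left_marker is not None and self.right_marker is not None


@dataclass(frozen=True)
class PhonationSeries:
    """One participant's ordered frames with a vocalization mask.

    ``true_iad`` / ``true_ga`` optionally carry the noise-free per-frame values
    when the series came from the synthetic generator; they are never used by
    the analysis itself, only by oracle checks.
    """

    participant_id: str
    frame_interval_ms: float
    frames: tuple[FiducialFrame, ...]
    vocalization_mask: np.ndarray
    true_iad: np.ndarray | None = None
    true_ga: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        mask = np.asarray(self.vocalization_mask, dtype=bool)
        if mask.shape != (len(frames),):
            raise ValueError("vocalization_mask length must equal frame count")
        object.__setattr__(self, "vocalization_mask", mask)
        for f in frames:
            expected = f.frame_index * self.frame_interval_ms
            if abs(f.time_ms - expected) > _TIME_TOL_MS:
                raise ValueError(
                    f"frame {f.frame_index} time {f.time_ms} ms != "
                    f"index x interval ({expected} ms)"
                )
        idx = [f.frame_index for f in frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        for arr_name in ("true_iad", "true_ga"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(frames),):
                    raise ValueError(f"{arr_name} length must equal frame count")
                object.__setattr__(self, arr_name, arr)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ms(self) -> np.ndarray:
        return np.array([f.time_ms for f in self.frames])

    @property
    def iad(self) -> np.ndarray:
        """Per-frame IAD, NaN where a marker is missing."""
        return np.array([f.iad for f in self.frames])

    @property
    def ga(self) -> np.ndarray:
        """Per-frame GA, NaN where absent."""
        return np.array(
            [f.ga if f.ga is not None else np.nan for f in self.frames]
        )

    def with_mask(self, mask) -> "PhonationSeries":
        return replace(self, vocalization_mask=np.asarray(mask, dtype=bool))


def arytenoid_velocity(
    frame_a: FiducialFrame,
    frame_b: FiducialFrame,
    stationary_tol: float = STATIONARY_TOL_MM,
    variant: str = "displacement",
) -> tuple[float, Direction]:
    """Arytenoid velocity between two successive frames.

    ``variant="displacement"`` (primary definition) sums the distances moved
    by the left and right markers; ``variant="iad-delta"`` uses |delta IAD|
    instead. Direction is classified by the sign of the IAD change with a
    small stationary tolerance.
    """
    if frame_b.frame_index != frame_a.frame_index + 1:
        raise ValueError(
            f"frames must be successive, got indices "
            f"{frame_a.frame_index} and {frame_b.frame_index}"
        )
    if not (frame_a.has_markers and frame_b.has_markers):
        raise ValueError("both frames need both markers for a velocity")
    d_iad = frame_b.iad - frame_a.iad
    if variant == "displacement":
        av = float(
            np.linalg.norm(frame_b.left_marker - frame_a.left_marker)
            + np.linalg.norm(frame_b.right_marker - frame_a.right_marker)
        )
    elif variant == "iad-delta":
        av = abs(float(d_iad))
    else:
        raise ValueError(f"unknown velocity variant {variant!r}")
    if abs(d_iad) < stationary_tol:
        direction = Direction.STATIONARY
    elif d_iad < 0:
        direction = Direction.ADDUCTION
    else:
        direction = Direction.ABDUCTION
    return av, direction


def trim_to_vocalization(
    series: PhonationSeries,
    open_threshold_factor: float = DEFAULT_TRIM_FACTOR,
    guard_frames: int = 0,
) -> PhonationSeries:
    """Mark the open-glottis pre/post-vocalization periods as non-vocalizing.

    Automatic surrogate for visual trimming: every frame in the *leading* and
    *trailing* maximal runs whose GA exceeds ``open_threshold_factor`` x the
    series' median GA is marked non-vocalizing. Interior frames are never
    removed. Frames with missing GA terminate a run.

    ``guard_frames`` additionally excludes that many frames just inside each
    non-empty trimmed run: a frame straddling the vocalization onset or offset
    mixes open and phonatory configurations, and a human trimming visually
    would drop it. The default pipeline configuration uses a one-frame guard.
    """
    if open_threshold_factor <= 0:
        raise ValueError("open_threshold_factor must be positive")
    if guard_frames < 0:
        raise ValueError("guard_frames must be >= 0")
    ga = series.ga
    if np.all(np.isnan(ga)):
        raise UnusableSeriesError(
            f"{series.participant_id}: no GA values, cannot trim"
        )
    threshold = open_threshold_factor * float(np.nanmedian(ga))
    above = np.zeros(series.n_frames, dtype=bool)
    finite = ~np.isnan(ga)
    above[finite] = ga[finite] > threshold

    mask = np.ones(series.n_frames, dtype=bool)
    i = 0
    while i < series.n_frames and above[i]:
        mask[i] = False
        i += 1
    if i == series.n_frames:
        raise UnusableSeriesError(
            f"{series.participant_id}: every frame classified as "
            "pre/post-vocalization"
        )
    n_lead = i
    j = series.n_frames - 1
    while j >= 0 and above[j]:
        mask[j] = False
        j -= 1
    n_trail = series.n_frames - 1 - j
    if guard_frames:
        if n_lead:
            mask[n_lead:n_lead + guard_frames] = False
        if n_trail:
            start = max(series.n_frames - n_trail - guard_frames, 0)
            mask[start:series.n_frames - n_trail] = False
    if not mask.any():
        raise UnusableSeriesError(
            f"{series.participant_id}: guard band removed every frame"
        )
    n_trimmed = int((~mask).sum())
    if n_trimmed:
        logger.info(
            "%s: trimmed %d open-glottis frame(s) (threshold %.3g mm^2)",
            series.participant_id, n_trimmed, threshold,
        )
    return series.with_mask(mask)


def effective_extreme(
    values: Sequence[float] | np.ndarray, k: int = EFFECTIVE_K, mode: str = "min"
) -> float:
    """Median of the k smallest (``mode="min"``) or largest (``"max"``) values.

    With five phonations per acquisition, the default k=5 makes this a robust
    surrogate for the per-series extremum. If fewer than k finite values are
    available, all of them are used and a warning is issued.
    """
    if mode not in ("min", "max"):
        raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("effective_extreme needs at least one finite value")
    if v.size < k:
        warnings.warn(
            f"effective {mode}: only {v.size} value(s) available, need {k}; "
            "using all",
            stacklevel=2,
        )
        k = v.size
    v = np.sort(v)
    chosen = v[:k] if mode == "min" else v[-k:]
    return float(np.median(chosen))


@dataclass(frozen=True)
class MeasureSummary:
    """Per-participant summary of the laryngeal measures over vocalization.

    Velocities are mm per frame interval. A velocity field is NaN when no
    frame pair of the relevant direction exists.
    """

    participant_id: str
    mean_ga: float
    mean_iad: float
    mean_iai: float
    eff_min_ga: float
    eff_min_iad: float
    eff_max_iai: float
    mean_av: float
    eff_max_av: float
    eff_max_abv: float
    eff_max_adv: float
    n_frames_ga: int
    n_frames_iad: int
    n_frames_iai: int
    n_velocity_pairs: int

    #: summary fields compared between groups, in reporting order
    MEASURES = (
        "mean_ga", "mean_iad", "mean_iai",
        "eff_min_ga", "eff_min_iad", "eff_max_iai",
        "mean_av", "eff_max_av", "eff_max_abv", "eff_max_adv",
    )
    #: positional (non-velocity) measures entering correlations by default
    POSITIONAL_MEASURES = (
        "mean_ga", "mean_iad", "mean_iai",
        "eff_min_ga", "eff_min_iad", "eff_max_iai",
    )
    VELOCITY_MEASURES = ("mean_av", "eff_max_av", "eff_max_abv", "eff_max_adv")


def _velocity_pairs(
    series: PhonationSeries,
    stationary_tol: float,
    variant: str,
) -> list[tuple[float, Direction]]:
    """Velocities between consecutive vocalizing frames with markers."""
    out: list[tuple[float, Direction]] = []
    mask = series.vocalization_mask
    for a, b, ma, mb in zip(
        series.frames, series.frames[1:], mask, mask[1:]
    ):
        if not (ma and mb):
            continue
        if b.frame_index != a.frame_index + 1:
            continue  # gap in recording
        if not (a.has_markers and b.has_markers):
            continue
        out.append(arytenoid_velocity(a, b, stationary_tol, variant))
    return out


def summarize_participant(
    series: PhonationSeries,
    k: int = EFFECTIVE_K,
    stationary_tol: float = STATIONARY_TOL_MM,
    velocity_variant: str = "displacement",
) -> MeasureSummary:
    """Summarise a (trimmed) series into per-participant measures.

    Only vocalizing frames contribute. Per-measure frame counts are reported
    separately because GA, markers and hence IAI can each be missing on
    different frames.
    """
    mask = series.vocalization_mask
    if not mask.any():
        raise UnusableSeriesError(
            f"{series.participant_id}: no vocalizing frames"
        )
    voc = [f for f, m in zip(series.frames, mask) if m]

    iad_vals = np.array([f.iad for f in voc if f.has_markers])
    ga_vals = np.array([f.ga for f in voc if f.ga is not None])
    iai_vals = []
    for f in voc:
        if f.ga is None or not f.has_markers:
            continue
        iad = f.iad
        if iad <= 0:
            logger.warning(
                "%s frame %d: IAI undefined (iad=%g <= 0), frame excluded",
                series.participant_id, f.frame_index, iad,
            )
            continue
        iai_vals.append(compute_iai(f.ga, iad))
    iai_vals = np.array(iai_vals)

    vels = _velocity_pairs(series, stationary_tol, velocity_variant)
    av = np.array([v for v, _ in vels])
    abv = np.array([v for v, d in vels if d is Direction.ABDUCTION])
    adv = np.array([v for v, d in vels if d is Direction.ADDUCTION])

    def _eff(vals: np.ndarray, mode: str) -> float:
        if vals.size == 0:
            return float("nan")
        return effective_extreme(vals, k=k, mode=mode)

    return MeasureSummary(
        participant_id=series.participant_id,
        mean_ga=float(np.mean(ga_vals)) if ga_vals.size else float("nan"),
        mean_iad=float(np.mean(iad_vals)) if iad_vals.size else float("nan"),
        mean_iai=float(np.mean(iai_vals)) if iai_vals.size else float("nan"),
        eff_min_ga=_eff(ga_vals, "min"),
        eff_min_iad=_eff(iad_vals, "min"),
        eff_max_iai=_eff(iai_vals, "max"),
        mean_av=float(np.mean(av)) if av.size else float("nan"),
        eff_max_av=_eff(av, "max"),
        eff_max_abv=_eff(abv, "max"),
        eff_max_adv=_eff(adv, "max"),
        n_frames_ga=int(ga_vals.size),
        n_frames_iad=int(iad_vals.size),
        n_frames_iai=int(iai_vals.size),
        n_velocity_pairs=len(vels),
    )


def frames_long_table(
    series_list: Iterable[PhonationSeries], vocalizing_only: bool = True
) -> pd.DataFrame:
    """Tidy per-frame table (one row per participant x frame) for modelling.

    Columns: participant_id, frame_index, time_ms, iad, ga, iai — NaN where a
    measure is undefined on that frame.
    """
    rows = []
    for series in series_list:
        for f, m in zip(series.frames, series.vocalization_mask):
            if vocalizing_only and not m:
                continue
            iad = f.iad
            ga = f.ga if f.ga is not None else np.nan
            iai = (
                ga / iad
                if np.isfinite(ga) and np.isfinite(iad) and iad > 0
                else np.nan
            )
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "frame_index": f.frame_index,
                    "time_ms": f.time_ms,
                    "iad": iad,
                    "ga": ga,
                    "iai": iai,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "frame_index", "time_ms", "iad", "ga", "iai"],
    )
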