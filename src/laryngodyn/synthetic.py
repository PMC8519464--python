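"""Synthetic laryngeal-dynamics cohorts.

Generates per-participant phonation time series (fiducial marker pairs plus
per-frame glottic areas at a fixed frame interval) with the statistical
structure the downstream analysis assumes:

* five short phonations inside a <= 5 s acquisition, bracketed by open-glottis
  lead-in/lead-out periods;
* each phonation adducts the arytenoids along a raised-cosine gate
  (adduct - hold - abduct) from the open baseline IAD down to a phonatory
  minimum;
* *hyperadduction*: the whole IAD trace is shifted inward in proportion to
  disease duration (increased resting adductor tone), so the phonatory
  minimum — and every other frame — is reduced by
  ``hyperadduction_slope_per_month x duration``;
* *vocal-fold bowing*: glottic area is elevated above the baseline GA-IAD
  relation in proportion to disease duration, with the elevation scaled by the
  adduction gate (a closure deficit has no effect while the glottis is wide
  open);
* frame-level measurement noise: isotropic Gaussian jitter on each fiducial
  coordinate and additive Gaussian noise on GA, floored at physical ranges;
* participant covariates shaped like the study cohort (ages ~ N(70, 7.4),
  disease durations ~ truncated log-normal with median 83.5 months, UPDRS-III
  a noisy linear function of duration).

The noise-free per-frame IAD and GA are retained on each series
(``true_iad`` / ``true_ga``) so oracle tests can compare pipeline output to
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .imaging import GlottisImage, render_glottis_slice  # noqa: F401  (re-export)
from .measures import FiducialFrame, PhonationSeries
from .records import ParticipantRecord

#: fixed anatomical coordinates of the glottic plane (mm); markers move
#: mediolaterally (x) about the midline, y is antero-posterior, z cranio-caudal
_MARKER_Y_MM = 18.0
_MARKER_Z_MM = 64.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generator settings. Defaults are the study conditions.

    Lengths in mm, areas in mm^2, durations in ms unless suffixed otherwise.
    """

    n_pd: int = 30
    n_control: int = 19
    frame_interval: float = 100.0
    n_phonations: int = 5
    acquisition_window: float = 5000.0

    # kinematic baselines (control, noise-free)
    baseline_min_iad: float = 3.7      # phonatory minimum IAD, mm
    baseline_open_iad: float = 15.0    # resting open-glottis IAD, mm
    ga_per_iad_slope: float = 5.0      # mm^2 per mm of IAD

    # disease effects
    bowing_slope_per_month: float = 0.09         # mm^2 / month at full adduction
    hyperadduction_slope_per_month: float = 0.011  # mm / month, whole-trace shift

    # disease-duration distribution: truncated log-normal, months
    duration_median_months: float = 83.5
    duration_log_sigma: float = 0.77
    duration_range_months: tuple[float, float] = (6.0, 160.0)

    # UPDRS-III = intercept + slope x duration + N(0, sd), clipped to [0, 132]
    updrs_intercept: float = 5.0
    updrs_slope_per_month: float = 0.18
    updrs_noise_sd: float = 5.0

    # demographics
    age_mean_pd: float = 69.7
    age_mean_control: float = 70.8
    age_sd: float = 7.35
    female_fraction_pd: float = 9.0 / 29.0
    female_fraction_control: float = 8.0 / 19.0

    # noise / variability
    participant_iad_sd: float = 0.4    # between-participant baseline shift, mm
    marker_noise_sd: float = 0.15      # per-coordinate jitter, mm
    ga_noise_sd: float = 2.0           # additive GA noise, mm^2

    # phonation waveform timing, ms
    lead_in_ms: float = 300.0
    rise_ms: float = 100.0
    hold_ms: float = 500.0
    fall_ms: float = 100.0
    gap_ms: float = 100.0
    lead_out_ms: float = 300.0
    onset_jitter_sd_ms: float = 30.0
    #: adduction gate floor between phonations: speakers producing five quick
    #: phonations only partially abduct between them
    inter_phonation_gate: float = 0.55

    #: emit one extra control-like participant captured at 300 ms/frame, for
    #: testing reader-side interval validation
    include_slow_frame_participant: bool = False

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_control < 1:
            raise ConfigError("n_pd and n_control must be >= 1")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.n_phonations < 1:
            raise ConfigError("n_phonations must be >= 1")
        if not (self.baseline_open_iad > self.baseline_min_iad > 0):
            raise ConfigError(
                "need baseline_open_iad > baseline_min_iad > 0"
            )
        for name in ("participant_iad_sd", "marker_noise_sd", "ga_noise_sd",
                     "updrs_noise_sd", "onset_jitter_sd_ms"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.duration_range_months
        if not 0 < lo < hi:
            raise ConfigError("duration_range_months must satisfy 0 < lo < hi")
        if not 0 <= self.inter_phonation_gate < 1:
            raise ConfigError("inter_phonation_gate must be in [0, 1)")

    @property
    def cycle_ms(self) -> float:
        return self.rise_ms + self.hold_ms + self.fall_ms

    def nominal_task_span_ms(self) -> float:
        """Lead-in plus the nominal footprint of all phonation cycles."""
        n = self.n_phonations
        return self.lead_in_ms + n * self.cycle_ms + (n - 1) * self.gap_ms


def _adduction_gate(t_ms: np.ndarray, onsets: np.ndarray,
                    cfg: SyntheticCohortConfig) -> np.ndarray:
    """Raised-cosine adduction gate in [0, 1] at times ``t_ms``.

    0 = fully open glottis, 1 = maximal adduction (phonatory hold). Between
    phonations the gate only falls to ``inter_phonation_gate``: with five
    quick phonations the folds never fully abduct until the task is over.
    """
    g = np.zeros_like(t_ms, dtype=float)
    for onset in onsets:
        u = t_ms - onset
        rising = (u >= 0) & (u < cfg.rise_ms)
        g[rising] = 0.5 * (1 - np.cos(np.pi * u[rising] / cfg.rise_ms))
        holding = (u >= cfg.rise_ms) & (u < cfg.rise_ms + cfg.hold_ms)
        g[holding] = 1.0
        v = u - (cfg.rise_ms + cfg.hold_ms)
        falling = (v >= 0) & (v < cfg.fall_ms)
        g[falling] = 0.5 * (1 + np.cos(np.pi * v[falling] / cfg.fall_ms))
    # partial-abduction floor strictly inside the task period
    interior = (t_ms >= onsets[0] + cfg.rise_ms) & (
        t_ms <= onsets[-1] + cfg.rise_ms + cfg.hold_ms
    )
    g[interior] = np.maximum(g[interior], cfg.inter_phonation_gate)
    return g


def generate_phonation_trace(
    config: SyntheticCohortConfig,
    duration_months: float,
    rng: np.random.Generator,
    participant_id: str = "SYN00",
    frame_interval: float | None = None,
) -> PhonationSeries:
    """Generate one participant's phonation series.

    ``duration_months = 0`` encodes a control. The random stream is consumed
    in a fixed order (baseline shift, onset jitter, marker noise, GA noise),
    so a given seed yields a bit-identical series.
    """
    if duration_months < 0:
        raise ValueError("duration_months must be >= 0")
    interval = config.frame_interval if frame_interval is None else frame_interval
    if interval <= 0:
        raise ConfigError("frame interval must be positive")
    if config.nominal_task_span_ms() > config.acquisition_window:
        raise ConfigError(
            f"acquisition window {config.acquisition_window} ms too short for "
            f"{config.n_phonations} phonations "
            f"({config.nominal_task_span_ms():.0f} ms needed)"
        )

    baseline_shift = rng.normal(0.0, config.participant_iad_sd)
    jitter = rng.normal(0.0, config.onset_jitter_sd_ms, size=config.n_phonations)
    # clip jitter so phonations never overlap or spill out of the window
    jitter = np.clip(jitter, -config.gap_ms / 2 + 1e-9, config.gap_ms / 2 - 1e-9)
    onsets = (
        config.lead_in_ms
        + np.arange(config.n_phonations) * (config.cycle_ms + config.gap_ms)
        + jitter
    )
    # acquisition stops shortly after the task is complete (scans were
    # terminated early once the five phonations were done), capped at the
    # full acquisition window
    nominal_end = min(
        config.acquisition_window,
        config.nominal_task_span_ms() + config.lead_out_ms,
    )
    n_frames = int(np.floor(nominal_end / interval))
    t = np.arange(n_frames) * interval
    gate = _adduction_gate(t, onsets, config)

    hyper_shift = config.hyperadduction_slope_per_month * duration_months
    depth = config.baseline_open_iad - config.baseline_min_iad
    true_iad = (
        config.baseline_open_iad + baseline_shift - hyper_shift - gate * depth
    )
    true_iad = np.maximum(true_iad, 0.1)  # physical floor

    bowing = config.bowing_slope_per_month * duration_months * gate
    true_ga = np.maximum(config.ga_per_iad_slope * true_iad + bowing, 0.0)

    marker_noise = rng.normal(0.0, config.marker_noise_sd, size=(n_frames, 2, 3))
    ga_noise = rng.normal(0.0, config.ga_noise_sd, size=n_frames)
    ga = np.maximum(true_ga + ga_noise, 0.0)

    task_start = onsets[0]
    task_end = onsets[-1] + config.cycle_ms
    mask = (t >= task_start) & (t < task_end)

    frames = []
    for i in range(n_frames):
        half = true_iad[i] / 2.0
        left = np.array([-half, _MARKER_Y_MM, _MARKER_Z_MM]) + marker_noise[i, 0]
        right = np.array([half, _MARKER_Y_MM, _MARKER_Z_MM]) + marker_noise[i, 1]
        frames.append(
            FiducialFrame(
                frame_index=i,
                time_ms=float(t[i]),
                left_marker=left,
                right_marker=right,
                ga=float(ga[i]),
            )
        )
    return PhonationSeries(
        participant_id=participant_id,
        frame_interval_ms=interval,
        frames=tuple(frames),
        vocalization_mask=mask,
        true_iad=true_iad,
        true_ga=true_ga,
    )


def _draw_duration(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> float:
    """Truncated log-normal disease duration, months."""
    mu = np.log(cfg.duration_median_months)
    lo, hi = cfg.duration_range_months
    for _ in range(1000):
        d = float(rng.lognormal(mu, cfg.duration_log_sigma))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))  # pathological sigma: clamp


def generate_cohort(
    config: SyntheticCohortConfig,
) -> list[tuple[ParticipantRecord, PhonationSeries]]:
    """Generate the full synthetic cohort, reproducibly under the config seed.

    Returns PD participants first (``PD01``...), then controls (``C01``...).
    Each participant consumes an independent child stream of the seed, so the
    cohort is bit-identical for identical configs.
    """
    root = np.random.SeedSequence(config.rng_seed)
    n_extra = 1 if config.include_slow_frame_participant else 0
    children = root.spawn(config.n_pd + config.n_control + n_extra)
    out: list[tuple[ParticipantRecord, PhonationSeries]] = []

    for i in range(config.n_pd):
        rng = np.random.default_rng(children[i])
        duration = _draw_duration(config, rng)
        updrs = float(
            np.clip(
                round(
                    config.updrs_intercept
                    + config.updrs_slope_per_month * duration
                    + rng.normal(0.0, config.updrs_noise_sd)
                ),
                0, 132,
            )
        )
        age = float(np.clip(rng.normal(config.age_mean_pd, config.age_sd), 40, 95))
        sex = "F" if rng.random() < config.female_fraction_pd else "M"
        pid = f"PD{i + 1:02d}"
        record = ParticipantRecord(
            participant_id=pid, condition="PD", age_years=round(age, 1),
            sex=sex, duration_months=round(duration, 1), updrs3=updrs,
        )
        out.append((record, generate_phonation_trace(config, duration, rng, pid)))

    for i in range(config.n_control):
        rng = np.random.default_rng(children[config.n_pd + i])
        age = float(
            np.clip(rng.normal(config.age_mean_control, config.age_sd), 40, 95)
        )
        sex = "F" if rng.random() < config.female_fraction_control else "M"
        pid = f"C{i + 1:02d}"
        record = ParticipantRecord(
            participant_id=pid, condition="control", age_years=round(age, 1),
            sex=sex, duration_months=None, updrs3=0.0,
        )
        out.append((record, generate_phonation_trace(config, 0.0, rng, pid)))

    if config.include_slow_frame_participant:
        rng = np.random.default_rng(children[-1])
        age = float(
            np.clip(rng.normal(config.age_mean_control, config.age_sd), 40, 95)
        )
        pid = "SLOW01"
        record = ParticipantRecord(
            participant_id=pid, condition="control", age_years=round(age, 1),
            sex="M", duration_months=None, updrs3=0.0,
        )
        series = generate_phonation_trace(
            config, 0.0, rng, pid, frame_interval=3 * config.frame_interval
        )
        out.append((record, series))
    return out
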