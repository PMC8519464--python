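"""Shared fixtures: small synthetic cohorts and hand-built series."""

import numpy as np
import pytest
from hypothesis import settings

import laryngodyn as ld
from laryngodyn.measures import frames_long_table

settings.register_profile("laryngodyn", derandomize=True, deadline=None)
settings.load_profile("laryngodyn")


def make_series(ga_values, iad_values=None, participant_id="T01",
                interval=100.0, mask=None):
    """Build a series with given per-frame GA (and optional IAD) values.

    Markers are placed symmetrically on the x axis so the frame IAD equals
    the requested value exactly.
    """
    n = len(ga_values)
    if iad_values is None:
        iad_values = [4.0] * n
    frames = []
    for i, (ga, iad) in enumerate(zip(ga_values, iad_values)):
        half = iad / 2.0
        frames.append(
            ld.FiducialFrame(
                frame_index=i,
                time_ms=i * interval,
                left_marker=(-half, 0.0, 0.0),
                right_marker=(half, 0.0, 0.0),
                ga=ga,
            )
        )
    if mask is None:
        mask = np.ones(n, dtype=bool)
    return ld.PhonationSeries(
        participant_id=participant_id,
        frame_interval_ms=interval,
        frames=tuple(frames),
        vocalization_mask=np.asarray(mask, dtype=bool),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (8 PD / 6 control) for fast structural tests."""
    cfg = ld.SyntheticCohortConfig(n_pd=8, n_control=6, rng_seed=11)
    return cfg, ld.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort_analysis():
    """One full default-size cohort run end to end (shared, read-only)."""
    cfg = ld.SyntheticCohortConfig(rng_seed=7)
    cohort = ld.generate_cohort(cfg)
    records = [r for r, _ in cohort]
    trimmed = [ld.trim_to_vocalization(s) for _, s in cohort]
    summaries = [ld.summarize_participant(t) for t in trimmed]
    frames = frames_long_table(trimmed)
    report = ld.run_full_analysis(summaries, frames, records)
    return cfg, cohort, records, trimmed, summaries, frames, report
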