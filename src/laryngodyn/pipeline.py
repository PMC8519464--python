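"""End-to-end pipeline: simulate -> measure -> analyze -> report.

Each stage reads the previous stage's artifacts from ``out_dir`` (or
``input_dir`` when simulation is disabled) and writes its own, together with a
``provenance.json`` that records the canonical config, its hash, the seed and
per-stage counts — enough to rerun any stage bit-identically. No artifact
contains wall-clock time, so two runs from the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .errors import ConfigError, LaryngodynError, UnusableSeriesError
from .io import (
    RunConfig,
    ensure_dir,
    read_fiducial_csv,
    read_frames_csv,
    read_records_csv,
    read_summaries_csv,
    write_fiducial_csv,
    write_frames_csv,
    write_records_csv,
    write_summaries_csv,
)
from .measures import frames_long_table, summarize_participant, trim_to_vocalization
from .stats import AnalysisConfig, run_full_analysis
from .synthetic import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger(__name__)

FIDUCIAL_FILE = "fiducial.csv"
RECORDS_FILE = "records.csv"
SUMMARIES_FILE = "summaries.csv"
FRAMES_FILE = "frames.csv"
REPORT_JSON = "report.json"
REPORT_TEXT = "report.txt"
PROVENANCE_FILE = "provenance.json"


def config_hash(config: RunConfig) -> str:
    """Hash of the scientifically relevant configuration.

    File locations and logging verbosity do not change what is computed, so
    they are excluded: the same analysis run into two directories yields
    byte-identical artifacts.
    """
    payload = config.to_canonical_dict()
    for key in ("out_dir", "input_dir", "log_level"):
        payload.pop(key, None)
    canonical = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_provenance(out: Path, config: RunConfig, counts: dict) -> None:
    cfg = config.to_canonical_dict()
    for key in ("out_dir", "input_dir", "log_level"):
        cfg.pop(key, None)
    payload = {
        "package": "laryngodyn",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": cfg,
        "stage_counts": counts,
    }
    (out / PROVENANCE_FILE).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the stage-count summary.

    A stage failure raises after flagging partially written artifacts in the
    provenance block. Configuration problems (e.g. simulation disabled but no
    input directory) are detected before any stage runs.
    """
    logging.basicConfig(level=config.log_level)
    out = ensure_dir(config.out_dir)
    counts: dict = {}

    # pre-flight validation, before any stage touches disk
    if "simulate" not in config.stages:
        src = Path(config.input_dir) if config.input_dir else out
        if "measure" in config.stages:
            for name in (FIDUCIAL_FILE, RECORDS_FILE):
                if not (src / name).is_file():
                    raise ConfigError(
                        f"simulate disabled but input {src / name} is missing"
                    )

    try:
        if "simulate" in config.stages:
            cohort_cfg = SyntheticCohortConfig(
                rng_seed=config.seed, **config.cohort
            )
            cohort = generate_cohort(cohort_cfg)
            write_records_csv([r for r, _ in cohort], out / RECORDS_FILE)
            write_fiducial_csv([s for _, s in cohort], out / FIDUCIAL_FILE)
            counts["simulate"] = {
                "participants": len(cohort),
                "frames": int(sum(s.n_frames for _, s in cohort)),
            }
            logger.info("simulate: %s", counts["simulate"])

        if "measure" in config.stages:
            src = out if "simulate" in config.stages else (
                Path(config.input_dir) if config.input_dir else out
            )
            result = read_fiducial_csv(
                src / FIDUCIAL_FILE,
                expected_interval_ms=config.expected_interval_ms,
                allow_interval_mismatch=config.allow_interval_mismatch,
            )
            records = read_records_csv(src / RECORDS_FILE)
            summaries = []
            trimmed_series = []
            n_trimmed_frames = 0
            unusable: dict[str, str] = {}
            for series in result.series:
                try:
                    trimmed = trim_to_vocalization(
                        series, config.trim_factor,
                        guard_frames=config.trim_guard_frames,
                    )
                    summaries.append(
                        summarize_participant(
                            trimmed, velocity_variant=config.velocity_variant
                        )
                    )
                except UnusableSeriesError as exc:
                    unusable[series.participant_id] = str(exc)
                    logger.warning("measure: %s", exc)
                    continue
                trimmed_series.append(trimmed)
                n_trimmed_frames += int(
                    trimmed.n_frames - trimmed.vocalization_mask.sum()
                )
            frames = frames_long_table(trimmed_series, vocalizing_only=True)
            write_summaries_csv(summaries, out / SUMMARIES_FILE)
            write_frames_csv(frames, out / FRAMES_FILE)
            counts["measure"] = {
                "participants_in": len(result.series) + len(result.rejected),
                "participants_out": len(summaries),
                "rejected": result.rejected,
                "unusable": unusable,
                "frames_trimmed": n_trimmed_frames,
                "vocalizing_frames": int(len(frames)),
            }
            logger.info("measure: %s", counts["measure"])

        if "analyze" in config.stages:
            summaries = read_summaries_csv(out / SUMMARIES_FILE)
            frames = read_frames_csv(out / FRAMES_FILE)
            records = read_records_csv(
                (out if "simulate" in config.stages or not config.input_dir
                 else Path(config.input_dir)) / RECORDS_FILE
            )
            analysis_cfg = AnalysisConfig(**config.analysis)
            report = run_full_analysis(summaries, frames, records, analysis_cfg)
            payload = report.to_dict()
            payload["provenance"] = {
                "seed": config.seed,
                "config_hash": config_hash(config),
                "version": __version__,
            }
            (out / REPORT_JSON).write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"
            )
            counts["analyze"] = {
                "comparisons": len(report.comparisons),
                "correlations": len(report.correlations),
                "models": len(report.models),
                "errors": len(report.errors),
            }
            logger.info("analyze: %s", counts["analyze"])

        if "report" in config.stages:
            summaries = read_summaries_csv(out / SUMMARIES_FILE)
            frames = read_frames_csv(out / FRAMES_FILE)
            records = read_records_csv(
                (out if "simulate" in config.stages or not config.input_dir
                 else Path(config.input_dir)) / RECORDS_FILE
            )
            analysis_cfg = AnalysisConfig(**config.analysis)
            report = run_full_analysis(summaries, frames, records, analysis_cfg)
            (out / REPORT_TEXT).write_text(report.render_text())
            if config.figures:
                from .plots import save_figures

                save_figures(summaries, records, out)
            counts["report"] = {"written": REPORT_TEXT}
            logger.info("report: %s", counts["report"])
    except LaryngodynError:
        counts["failed"] = True
        _write_provenance(out, config, counts)
        raise

    _write_provenance(out, config, counts)
    return counts
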