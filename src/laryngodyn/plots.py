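"""Optional figure generation (boxplots and duration/severity scatter plots).

Requires matplotlib; imported lazily by the report stage so the core pipeline
has no plotting dependency.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .measures import MeasureSummary
from .records import ParticipantRecord
from .stats import _records_frame


def save_figures(
    summaries: Iterable[MeasureSummary],
    records: Iterable[ParticipantRecord],
    out_dir,
) -> list[Path]:
    """Write group boxplots and duration/UPDRS scatter plots as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    df = pd.DataFrame([asdict(s) for s in summaries]).merge(
        _records_frame(records), on="participant_id"
    )
    written = []

    fig, axes = plt.subplots(2, 5, figsize=(16, 7))
    for ax, measure in zip(axes.ravel(), MeasureSummary.MEASURES):
        groups = [
            df.loc[df.condition == "PD", measure].dropna(),
            df.loc[df.condition == "control", measure].dropna(),
        ]
        ax.boxplot(groups, tick_labels=["PD", "control"])
        ax.set_title(measure, fontsize=9)
    fig.suptitle("Laryngeal measures during vocalization, PD vs control")
    fig.tight_layout()
    path = out / "comparisons.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    pd_df = df[df.condition == "PD"]
    fig, axes = plt.subplots(2, 6, figsize=(18, 7))
    for row, predictor in enumerate(("duration", "updrs3")):
        for col, measure in enumerate(MeasureSummary.POSITIONAL_MEASURES):
            ax = axes[row, col]
            ax.scatter(pd_df[predictor], pd_df[measure], s=12)
            ax.set_xlabel(predictor, fontsize=8)
            ax.set_ylabel(measure, fontsize=8)
    fig.suptitle("Laryngeal measures vs disease duration and UPDRS-III")
    fig.tight_layout()
    path = out / "correlations.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
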