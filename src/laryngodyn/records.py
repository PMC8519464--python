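"""Participant-level clinical covariates.

A :class:`ParticipantRecord` carries the cross-sectional covariates used by the
group-comparison, correlation and mixed-model stages: condition (PD or
control), age, sex, disease duration in months and the UPDRS part-III motor
score. Controls carry no disease duration and a UPDRS-III of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

CONDITION_PD = "PD"
CONDITION_CONTROL = "control"

UPDRS3_MAX = 132.0


@dataclass(frozen=True)
class ParticipantRecord:
    """Clinical covariates for one participant.

    Parameters
    ----------
    participant_id:
        Unique identifier, shared with the participant's phonation series.
    condition:
        ``"PD"`` or ``"control"``.
    age_years:
        Age at imaging, years.
    sex:
        ``"F"`` or ``"M"``.
    duration_months:
        Disease duration in months; required for PD, ``None`` for controls.
    updrs3:
        UPDRS part-III motor score in [0, 132]; 0 for controls.
    """

    participant_id: str
    condition: str
    age_years: float
    sex: str
    duration_months: float | None = None
    updrs3: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in (CONDITION_PD, CONDITION_CONTROL):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.condition == CONDITION_PD:
            if self.duration_months is None or self.duration_months < 0:
                raise ValueError("PD participants need duration_months >= 0")
        elif self.duration_months is not None:
            raise ValueError("controls must not carry a disease duration")
        if not 0.0 <= self.updrs3 <= UPDRS3_MAX:
            raise ValueError(f"updrs3 {self.updrs3} outside [0, {UPDRS3_MAX}]")

    @property
    def is_pd(self) -> bool:
        return self.condition == CONDITION_PD
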