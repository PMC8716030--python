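"""Event-history data model for acute ocular severity progression.

The acute ocular surface involvement of SJS/TEN is graded 0-3 (none, mild,
severe, very severe) at two visits: the initial ophthalmological presentation
and the worst-condition follow-up visit.  For multi-state analysis the four
grades collapse to three states,

    state 0  no ocular involvement,
    state 1  mild (conjunctival hyperemia),
    state 2  severe or very severe (epithelial defect and/or pseudomembrane),

with the progressive transition graph 0->1, 0->2, 1->2 and state 2 absorbing.
Time runs clock-forward in days from disease onset (the day erythema
developed); a negative presentation day means the eye exam preceded the
erythema.

This module holds the patient-record data model, the eligibility filter, the
initial-vs-worst grade cross-tabulation, and the conversion of two-visit
records into transition-specific counting-process data (mstate-style long
format) with delayed entry for the 1->2 transition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeverityGrade",
    "PatientRecord",
    "TransitionStructure",
    "CovariateVector",
    "COVARIATE_NAMES",
    "grade_to_state",
    "apply_eligibility_filters",
    "build_transition_table",
    "to_counting_process",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

GRADE_LABELS = {0: "none", 1: "mild", 2: "severe", 3: "very severe"}
LABEL_GRADES = {v: k for k, v in GRADE_LABELS.items()}

#: Covariate order fixed to match the prognostic-factor table layout.
COVARIATE_NAMES = (
    "age_years",
    "sex_female",
    "diagnosis_ten",
    "drug_nsaids",
    "drug_cold_remedies",
    "drug_antibiotics",
    "drug_anticonvulsants",
    "drug_gout",
    "severity_subscore",
)


@dataclass(frozen=True)
class SeverityGrade:
    """Acute ocular severity grade, an integer 0-3 with a canonical label."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in GRADE_LABELS:
            raise ValueError(
                f"invalid acute ocular severity grade {self.value!r}; "
                "expected an integer in {0, 1, 2, 3}"
            )

    @property
    def label(self) -> str:
        return GRADE_LABELS[self.value]

    @classmethod
    def from_label(cls, label: str) -> "SeverityGrade":
        try:
            return cls(LABEL_GRADES[label])
        except KeyError:
            raise ValueError(f"unknown severity grade label {label!r}") from None


def grade_to_state(grade: SeverityGrade | int) -> int:
    """Collapse a 0-3 severity grade to a model state in {0, 1, 2}.

    Grades 2 (severe) and 3 (very severe) are handled as one category because
    both imply extensive ocular-surface inflammation; the model state is
    therefore min(grade, 2).
    """
    value = grade.value if isinstance(grade, SeverityGrade) else grade
    if value not in GRADE_LABELS:
        raise ValueError(
            f"invalid acute ocular severity grade {value!r}; "
            "expected an integer in {0, 1, 2, 3}"
        )
    return min(int(value), 2)


@dataclass(frozen=True)
class TransitionStructure:
    """The progressive three-state graph: 0->1, 0->2, 1->2; state 2 absorbing."""

    states: dict = field(
        default_factory=lambda: {0: "none", 1: "mild", 2: "severe/very severe"}
    )
    transitions: tuple = ((0, 1), (0, 2), (1, 2))
    absorbing: frozenset = frozenset({2})

    def __post_init__(self) -> None:
        for q, r in self.transitions:
            if q == r:
                raise ValueError("self-loop transitions are not allowed")
            if r == 0:
                raise ValueError("no transition may enter state 0")
        if len(self.transitions) != 3:
            raise ValueError("the progressive structure has exactly three transitions")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transitions_from(self, state: int) -> list:
        return [t for t in self.transitions if t[0] == state]


DEFAULT_STRUCTURE = TransitionStructure()


@dataclass
class PatientRecord:
    """One patient's covariates, visit grades/times, follow-up and outcomes.

    Day fields count days from disease onset (erythema); ``days_onset_to_initial``
    may be negative when the eye exam preceded the erythema.  Outcome fields
    (``sequelae``, ``visual_disturbance``, ``dry_eye``) may be jointly missing
    (``None``) for patients without chronic-stage data.
    """

    patient_id: str
    age_years: float
    sex: str  # "male" | "female"
    diagnosis: str  # "SJS" | "TEN"
    drug_nsaids: bool
    drug_cold_remedies: bool
    drug_antibiotics: bool
    drug_anticonvulsants: bool
    drug_gout: bool
    severity_subscore: float  # systemic severity index subscore, 0-11
    days_onset_to_initial: float
    days_initial_to_worst: float
    grade_initial: SeverityGrade
    grade_worst: SeverityGrade
    days_onset_to_last_followup: float
    died: bool
    sequelae: Optional[str] = None  # "none" | "present"
    visual_disturbance: Optional[str] = None  # "none" | "20/20-20/200" | "worse than 20/200"
    dry_eye: Optional[str] = None  # "none" | "mild" | "moderate" | "severe"

    def __post_init__(self) -> None:
        if isinstance(self.grade_initial, int):
            self.grade_initial = SeverityGrade(self.grade_initial)
        if isinstance(self.grade_worst, int):
            self.grade_worst = SeverityGrade(self.grade_worst)
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.diagnosis not in ("SJS", "TEN"):
            raise ValueError(f"diagnosis must be 'SJS' or 'TEN', got {self.diagnosis!r}")
        if self.days_initial_to_worst < 0:
            raise ValueError("days_initial_to_worst must be non-negative")
        if self.grade_worst.value < self.grade_initial.value:
            raise ValueError(
                f"patient {self.patient_id}: worst grade {self.grade_worst.value} "
                f"below initial grade {self.grade_initial.value} (severity cannot regress)"
            )
        if (
            self.days_onset_to_last_followup
            < self.days_onset_to_initial + self.days_initial_to_worst
        ):
            raise ValueError(
                f"patient {self.patient_id}: final follow-up precedes the "
                "worst-condition visit"
            )

    @property
    def state_initial(self) -> int:
        return grade_to_state(self.grade_initial)

    @property
    def state_worst(self) -> int:
        return grade_to_state(self.grade_worst)

    @property
    def day_worst(self) -> float:
        """Day of the worst-condition follow-up visit, from onset."""
        return self.days_onset_to_initial + self.days_initial_to_worst

    def covariates(self) -> np.ndarray:
        """The 9-component covariate vector in canonical order."""
        return np.array(
            [
                float(self.age_years),
                1.0 if self.sex == "female" else 0.0,
                1.0 if self.diagnosis == "TEN" else 0.0,
                float(self.drug_nsaids),
                float(self.drug_cold_remedies),
                float(self.drug_antibiotics),
                float(self.drug_anticonvulsants),
                float(self.drug_gout),
                float(self.severity_subscore),
            ]
        )


#: alias used in signatures: a 9-vector in COVARIATE_NAMES order
CovariateVector = np.ndarray


def apply_eligibility_filters(
    cohort: Sequence[PatientRecord], max_days: int = 30
) -> tuple[list[PatientRecord], list[dict]]:
    """Apply the 30-day timeliness filters.

    A patient is eligible when the elapsed time from disease onset to the
    initial eye exam is at most ``max_days`` AND the elapsed time from initial
    presentation to the worst-condition visit is at most ``max_days``; strictly
    longer intervals are excluded.  Negative onset-to-initial days (exam before
    erythema) pass this filter.

    Returns ``(eligible, exclusion_log)``; each log entry names the patient and
    the rule that fired.
    """
    if max_days < 0:
        raise ValueError("max_days must be non-negative")
    eligible: list[PatientRecord] = []
    log: list[dict] = []
    for rec in cohort:
        if rec.days_onset_to_initial > max_days:
            log.append(
                {
                    "patient_id": rec.patient_id,
                    "rule": "onset_to_initial",
                    "detail": f"days_onset_to_initial={rec.days_onset_to_initial} > {max_days}",
                }
            )
        elif rec.days_initial_to_worst > max_days:
            log.append(
                {
                    "patient_id": rec.patient_id,
                    "rule": "initial_to_worst",
                    "detail": f"days_initial_to_worst={rec.days_initial_to_worst} > {max_days}",
                }
            )
        else:
            eligible.append(rec)
    return eligible, log


def build_transition_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """4x4 cross-tabulation of initial grade (rows) by worst grade (columns).

    The lower triangle is structurally zero: acute ocular severity does not
    regress between the initial and worst-condition visits.
    """
    labels = [GRADE_LABELS[g] for g in range(4)]
    counts = np.zeros((4, 4), dtype=int)
    for rec in cohort:
        counts[rec.grade_initial.value, rec.grade_worst.value] += 1
    return pd.DataFrame(counts, index=pd.Index(labels, name="initial"), columns=pd.Index(labels, name="worst"))


_CP_COLUMNS = ["patient_id", "from_state", "to_state", "entry", "exit", "status"]


def to_counting_process(
    cohort: Sequence[PatientRecord],
    structure: TransitionStructure = DEFAULT_STRUCTURE,
    same_day_offset: float = 0.5,
) -> tuple[pd.DataFrame, list[dict]]:
    """Convert two-visit patient records to transition-specific at-risk intervals.

    Clock-forward convention: day 0 is disease onset and every interval is on
    the onset time scale.  Each patient still in state 0 contributes intervals
    ``(0, t]`` for both competing transitions 0->1 and 0->2, exactly one of
    which may end in an event; entering state 1 opens a delayed-entry interval
    for 1->2.  Non-progressors are censored at the final follow-up day.  An
    interval that would have zero length (event on day 0, or worst-condition
    visit on the presentation day) has its exit shifted by ``same_day_offset``.

    Patients whose eye exam preceded disease onset (negative presentation day)
    cannot be placed on the onset clock and are dropped with a log entry.

    Returns ``(rows, drop_log)`` where ``rows`` is a long-format DataFrame with
    columns patient_id, from_state, to_state, entry, exit, status (1 = event,
    0 = censored) plus the nine covariate columns.
    """
    out: list[dict] = []
    log: list[dict] = []
    for rec in cohort:
        if rec.days_onset_to_initial < 0:
            log.append(
                {
                    "patient_id": rec.patient_id,
                    "rule": "negative_onset_to_initial",
                    "detail": f"days_onset_to_initial={rec.days_onset_to_initial} < 0",
                }
            )
            continue
        covs = rec.covariates()
        if np.any(np.isnan(covs)):
            raise ValueError(
                f"patient {rec.patient_id}: missing covariate value; "
                "complete cases are required for multi-state analysis"
            )
        s_init, s_worst = rec.state_initial, rec.state_worst
        t_init = float(rec.days_onset_to_initial)
        t_worst = float(rec.day_worst)
        t_cens = float(rec.days_onset_to_last_followup)

        def _row(q, r, entry, exit_, status):
            if exit_ <= entry:
                exit_ = entry + same_day_offset
            d = {
                "patient_id": rec.patient_id,
                "from_state": q,
                "to_state": r,
                "entry": entry,
                "exit": exit_,
                "status": int(status),
            }
            d.update(dict(zip(COVARIATE_NAMES, covs)))
            out.append(d)
            return exit_

        if s_init == 0:
            if s_worst == 0:
                _row(0, 1, 0.0, t_cens, 0)
                _row(0, 2, 0.0, t_cens, 0)
            elif s_worst == 1:
                exit0 = _row(0, 1, 0.0, t_worst, 1)
                _row(0, 2, 0.0, exit0, 0)
                _row(1, 2, exit0, t_cens, 0)
            else:
                exit0 = _row(0, 2, 0.0, t_worst, 1)
                _row(0, 1, 0.0, exit0, 0)
        elif s_init == 1:
            exit0 = _row(0, 1, 0.0, t_init, 1)
            _row(0, 2, 0.0, exit0, 0)
            if s_worst == 2:
                _row(1, 2, exit0, t_worst, 1)
            else:
                _row(1, 2, exit0, t_cens, 0)
        else:  # presented already severe/very severe
            exit0 = _row(0, 2, 0.0, t_init, 1)
            _row(0, 1, 0.0, exit0, 0)

    rows = pd.DataFrame(out, columns=_CP_COLUMNS + list(COVARIATE_NAMES))
    return rows, log


# ---------------------------------------------------------------------------
# cohort (de)serialization


def _grade_cell(g: SeverityGrade) -> int:
    return g.value


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient with canonical column names; missing outcomes -> NA."""
    rows = []
    for rec in cohort:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "diagnosis": rec.diagnosis,
                "drug_nsaids": int(rec.drug_nsaids),
                "drug_cold_remedies": int(rec.drug_cold_remedies),
                "drug_antibiotics": int(rec.drug_antibiotics),
                "drug_anticonvulsants": int(rec.drug_anticonvulsants),
                "drug_gout": int(rec.drug_gout),
                "severity_subscore": rec.severity_subscore,
                "days_onset_to_initial": rec.days_onset_to_initial,
                "days_initial_to_worst": rec.days_initial_to_worst,
                "grade_initial": _grade_cell(rec.grade_initial),
                "grade_worst": _grade_cell(rec.grade_worst),
                "days_onset_to_last_followup": rec.days_onset_to_last_followup,
                "died": int(rec.died),
                "sequelae": rec.sequelae,
                "visual_disturbance": rec.visual_disturbance,
                "dry_eye": rec.dry_eye,
            }
        )
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    cohort = []
    for _, r in frame.iterrows():
        def _opt(col):
            v = r[col]
            return None if pd.isna(v) or v == "" else str(v)

        cohort.append(
            PatientRecord(
                patient_id=str(r["patient_id"]),
                age_years=_maybe_int(r["age_years"]),
                sex=str(r["sex"]),
                diagnosis=str(r["diagnosis"]),
                drug_nsaids=bool(int(r["drug_nsaids"])),
                drug_cold_remedies=bool(int(r["drug_cold_remedies"])),
                drug_antibiotics=bool(int(r["drug_antibiotics"])),
                drug_anticonvulsants=bool(int(r["drug_anticonvulsants"])),
                drug_gout=bool(int(r["drug_gout"])),
                severity_subscore=_maybe_int(r["severity_subscore"]),
                days_onset_to_initial=_maybe_int(r["days_onset_to_initial"]),
                days_initial_to_worst=_maybe_int(r["days_initial_to_worst"]),
                grade_initial=SeverityGrade(int(r["grade_initial"])),
                grade_worst=SeverityGrade(int(r["grade_worst"])),
                days_onset_to_last_followup=_maybe_int(r["days_onset_to_last_followup"]),
                died=bool(int(r["died"])),
                sequelae=_opt("sequelae"),
                visual_disturbance=_opt("visual_disturbance"),
                dry_eye=_opt("dry_eye"),
            )
        )
    return cohort


def _maybe_int(v):
    f = float(v)
    return int(f) if float(f).is_integer() else f


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    return frame_to_cohort(frame)
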