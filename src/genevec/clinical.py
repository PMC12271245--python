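"""Clinical course labels: response, onset of improvement, severity, inclusion.

Labels are derived from repeated clinical scale scores.  Depressive (F3)
subjects are rated on the 17-item Hamilton scale (HAM-D17); schizophrenic
(F2) subjects on the PANSS positive subscale (PANSS-P) for response and the
PANSS general-psychopathology subscale (PANSS-G) for baseline severity and
inclusion.

*Response* is a sustained 50% (HAM-D17) or 40% (PANSS-P) reduction of the
baseline score; *onset of improvement* a sustained 20% reduction; subjects
reaching onset within the first 14 days are *early improvers*.  "Sustained"
means no later deterioration beyond 15% of the achieved baseline-score
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalTrajectory",
    "OutcomeLabels",
    "RESPONSE_THRESHOLD",
    "ONSET_THRESHOLD",
    "EARLY_WINDOW_DAYS",
    "INCLUSION_BASELINE",
    "locf_fill",
    "baseline_severity",
    "inclusion_filter",
    "sustained_reduction_day",
    "classify_response",
    "classify_onset",
    "label_cohort",
]

#: sustained fractional baseline reduction defining response, per diagnosis
RESPONSE_THRESHOLD = {"F2": 0.40, "F3": 0.50}
#: sustained reduction defining onset of improvement (both diagnoses)
ONSET_THRESHOLD = 0.20
#: onset at or before this day => early improver
EARLY_WINDOW_DAYS = 14
#: minimum baseline on the severity scale required at study entry
INCLUSION_BASELINE = {"F2": 21.0, "F3": 15.0}  # PANSS-G / HAM-D17
#: scale carrying the response criterion, per diagnosis
RESPONSE_SCALE = {"F2": "PANSS-P", "F3": "HAM-D17"}
#: scale carrying severity/inclusion, per diagnosis
SEVERITY_SCALE = {"F2": "PANSS-G", "F3": "HAM-D17"}
MIN_EARLY_VISITS = 3


@dataclass
class ClinicalTrajectory:
    """One subject's repeated scores on one scale.

    ``visits`` is an ordered list of (day, score); day 0 is baseline.
    """

    subject_id: str
    diagnosis: str  # 'F2' | 'F3'
    scale: str  # 'HAM-D17' | 'PANSS-P' | 'PANSS-G'
    visits: list[tuple[int, float]] = field(default_factory=list)
    igm_level: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("F2", "F3"):
            raise ValueError(f"diagnosis must be F2 or F3, got {self.diagnosis!r}")
        days = [d for d, _ in self.visits]
        if days and days[0] != 0:
            raise ValueError("first visit must be day 0 (baseline)")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("visit days must be strictly increasing")
        if any(s < 0 for _, s in self.visits):
            raise ValueError("scores must be non-negative")

    @property
    def baseline(self) -> float:
        if not self.visits:
            raise ValueError("empty trajectory")
        return self.visits[0][1]

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.visits]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.visits]


@dataclass
class OutcomeLabels:
    """Per-subject outcome labels as a DataFrame indexed by subject_id.

    Columns: diagnosis, included, severity, responder, onset_day (NaN = never),
    early_improver, non_improver, igm_elevated.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "diagnosis", "included", "severity", "responder",
            "onset_day", "early_improver", "non_improver",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")

    @property
    def subjects(self) -> list[str]:
        return list(self.table.index)

    def subjects_where(self, column: str, value=True) -> list[str]:
        return list(self.table.index[self.table[column] == value])


def locf_fill(traj: ClinicalTrajectory, schedule: list[int]) -> ClinicalTrajectory:
    """Fill missing scheduled assessments by last observation carried forward.

    Scheduled days earlier than the first observation are not extrapolated.
    """
    if not traj.visits:
        raise ValueError("trajectory has no baseline")
    observed = dict(traj.visits)
    days = sorted(set(traj.days) | set(schedule))
    out = []
    last = None
    for d in days:
        if d in observed:
            last = observed[d]
            out.append((d, last))
        elif last is not None:
            out.append((d, last))
        # else: scheduled day before baseline — skip, no extrapolation
    return replace(traj, visits=out)


def baseline_severity(score: float, diagnosis: str) -> str:
    """Severity band from the baseline severity-scale score.

    F3 (HAM-D17): <20 mild, 20-24 moderate, >24 severe.
    F2 (PANSS-G): <30 mild, 30-40 moderate, >40 severe.
    Boundaries are inclusive into "moderate".
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    lo, hi = (20.0, 24.0) if diagnosis == "F3" else (30.0, 40.0)
    if score < lo:
        return "mild"
    if score <= hi:
        return "moderate"
    return "severe"


def inclusion_filter(
    traj: ClinicalTrajectory, severity_baseline: float | None = None
) -> bool:
    """Study inclusion: baseline above the entry threshold and >= 3 assessments
    within the first two weeks.

    For F2 subjects the entry threshold applies to PANSS-G; pass that baseline
    via ``severity_baseline`` when ``traj`` is the PANSS-P trajectory.
    """
    if not traj.visits:
        return False
    base = traj.baseline if severity_baseline is None else severity_baseline
    if base < INCLUSION_BASELINE[traj.diagnosis]:
        return False
    early_visits = sum(1 for d, _ in traj.visits if d <= EARLY_WINDOW_DAYS)
    return early_visits >= MIN_EARLY_VISITS


def sustained_reduction_day(
    traj: ClinicalTrajectory,
    threshold_fraction: float,
    sustain_tolerance: float = 0.15,
    anchor: str = "first",
) -> int | None:
    """Earliest visit day with a sustained fractional baseline-score reduction.

    A visit at day t qualifies when the reduction r(t) = (baseline - score) /
    baseline reaches ``threshold_fraction`` and no later visit deteriorates
    beyond ``sustain_tolerance`` of the achieved reduction.  With
    ``anchor='first'`` (default) "achieved" is the reduction at the first
    qualifying visit; ``anchor='max'`` anchors to the running maximum
    reduction from the qualifying visit onwards.
    """
    if anchor not in ("first", "max"):
        raise ValueError("anchor must be 'first' or 'max'")
    if not traj.visits:
        return None
    base = traj.baseline
    if base <= 0:
        raise ValueError("baseline score must be positive")
    days = traj.days
    red = [base - s for s in traj.scores]  # absolute reduction
    thr = threshold_fraction * base
    for i, (d, r) in enumerate(zip(days, red)):
        if r < thr:
            continue
        later = red[i + 1:]
        if anchor == "first":
            floor = (1.0 - sustain_tolerance) * r
            if all(u >= floor for u in later):
                return d
        else:
            run_max, ok = r, True
            for u in later:
                if u < (1.0 - sustain_tolerance) * run_max:
                    ok = False
                    break
                run_max = max(run_max, u)
            if ok:
                return d
    return None


def _check_scale(traj: ClinicalTrajectory) -> None:
    want = RESPONSE_SCALE[traj.diagnosis]
    if traj.scale != want:
        raise ValueError(
            f"diagnosis {traj.diagnosis} requires scale {want}, got {traj.scale}"
        )


def classify_response(traj: ClinicalTrajectory, **kw) -> bool:
    """Responder: sustained 40% (F2, PANSS-P) / 50% (F3, HAM-D17) reduction."""
    _check_scale(traj)
    return sustained_reduction_day(traj, RESPONSE_THRESHOLD[traj.diagnosis], **kw) is not None


def classify_onset(traj: ClinicalTrajectory, **kw) -> tuple[int | None, bool]:
    """Onset of improvement (sustained 20% reduction) and early-improver flag."""
    _check_scale(traj)
    day = sustained_reduction_day(traj, ONSET_THRESHOLD, **kw)
    return day, day is not None and day <= EARLY_WINDOW_DAYS


def label_cohort(
    trajectories: list[ClinicalTrajectory],
    severity_baselines: dict[str, float] | None = None,
    igm_elevated: dict[str, bool] | None = None,
) -> OutcomeLabels:
    """Derive all outcome labels for a cohort of response-scale trajectories.

    ``severity_baselines`` maps F2 subject ids to their PANSS-G baselines (for
    F3 the HAM-D17 baseline doubles as the severity score).
    """
    severity_baselines = severity_baselines or {}
    igm_elevated = igm_elevated or {}
    rows = {}
    for traj in trajectories:
        sid = traj.subject_id
        sev_base = severity_baselines.get(sid, traj.baseline if traj.visits else 0.0)
        onset, early = classify_onset(traj)
        included = inclusion_filter(traj, severity_baseline=sev_base)
        # response/onset criteria are only evaluated among included subjects
        responder = classify_response(traj) and included
        early = early and included
        rows[sid] = {
            "diagnosis": traj.diagnosis,
            "included": included,
            "severity": baseline_severity(sev_base, traj.diagnosis),
            "responder": responder,
            "onset_day": float(onset) if onset is not None else np.nan,
            "early_improver": early,
            "non_improver": onset is None,
            "igm_elevated": bool(igm_elevated.get(sid, False)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return OutcomeLabels(table)
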