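"""Trial-level quality control and participant x session aggregation.

The exclusion cascade runs in a fixed order: (1) drop trials whose peak or
undershoot could not be determined, (2) drop trials with a gaze amplitude
below 40 deg, (3) within the survivors, drop trials whose oscillation ratio
lies more than two sample standard deviations from the session mean (single
pass).  Early/late-flagged trials are retained — flagging exists to minimize
data loss while keeping the decisions auditable.  The session mean of the
retained ratios is the value entered into the statistical analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import SESSIONS

__all__ = ["TrialRecord", "QCReport", "SessionSummary", "apply_exclusions",
           "summarize", "cohort_table"]

logger = logging.getLogger(__name__)

MIN_GAZE_AMPLITUDE_DEG = 40.0
OUTLIER_SD_LIMIT = 2.0


@dataclass
class TrialRecord:
    """Per-trial inputs to the exclusion cascade."""

    trial_index: int
    ratio_pct: float
    amplitude_deg: float
    determinate: bool = True
    extended_early: bool = False
    extended_late: bool = False


@dataclass
class QCReport:
    """Outcome of the exclusion cascade for one participant-session."""

    n_input: int
    n_early: int
    n_late: int
    n_indeterminate: int
    n_small_amplitude: int
    n_outlier: int
    retained_indices: list[int] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)

    def __post_init__(self) -> None:
        total = (
            self.n_retained + self.n_indeterminate + self.n_small_amplitude
            + self.n_outlier
        )
        if total != self.n_input:
            raise ValueError("QC counts do not add up to the number of input trials")


@dataclass
class SessionSummary:
    """Mean retained oscillation ratio for one participant-session."""

    participant_id: str
    group: str
    session: str
    mean_ratio_pct: float
    n_trials_retained: int


def apply_exclusions(trials: list[TrialRecord]) -> QCReport:
    """Run the three-stage exclusion cascade over one session's trials.

    The +/-2 SD outlier screen uses the mean and sample standard deviation
    (n-1 denominator) of the ratios surviving the first two filters, applied
    in a single pass; the boundary is non-strict (exactly 2 SD is kept).
    Raises if no trial survives.
    """
    if not trials:
        raise ValueError("no trials supplied")
    n_early = sum(t.extended_early for t in trials)
    n_late = sum(t.extended_late for t in trials)

    determinate = [t for t in trials if t.determinate]
    n_indet = len(trials) - len(determinate)

    large = [t for t in determinate if t.amplitude_deg >= MIN_GAZE_AMPLITUDE_DEG]
    n_small = len(determinate) - len(large)

    if not large:
        raise ValueError("no trials survive QC; session unusable")
    ratios = np.array([t.ratio_pct for t in large])
    if len(ratios) > 1:
        mean, sd = ratios.mean(), ratios.std(ddof=1)
    else:
        mean, sd = ratios[0], 0.0
    keep = np.abs(ratios - mean) <= OUTLIER_SD_LIMIT * sd
    n_outlier = int((~keep).sum())
    retained = [t.trial_index for t, k in zip(large, keep) if k]
    if not retained:
        raise ValueError("no trials survive QC; session unusable")

    for t, k in zip(large, keep):
        if not k:
            logger.info(
                "trial %d excluded as ratio outlier (%.2f vs mean %.2f, sd %.2f)",
                t.trial_index, t.ratio_pct, mean, sd,
            )
    return QCReport(
        n_input=len(trials),
        n_early=n_early,
        n_late=n_late,
        n_indeterminate=n_indet,
        n_small_amplitude=n_small,
        n_outlier=n_outlier,
        retained_indices=retained,
    )


def summarize(
    trials: list[TrialRecord],
    report: QCReport,
    participant_id: str,
    group: str,
    session: str,
) -> SessionSummary:
    """Mean oscillation ratio over the QC-retained trials."""
    retained = set(report.retained_indices)
    ratios = [t.ratio_pct for t in trials if t.trial_index in retained]
    if not ratios:
        raise ValueError("no retained trials to summarize")
    return SessionSummary(
        participant_id=participant_id,
        group=group,
        session=session,
        mean_ratio_pct=float(np.mean(ratios)),
        n_trials_retained=len(ratios),
    )


def cohort_table(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Long-format participant x session table, validated complete.

    Every participant must contribute exactly the three sessions; duplicates
    or gaps raise an error naming the participant.
    """
    if not summaries:
        raise ValueError("no session summaries supplied")
    df = pd.DataFrame(
        {
            "participant_id": s.participant_id,
            "group": s.group,
            "session": s.session,
            "mean_ratio_pct": s.mean_ratio_pct,
            "n_trials_retained": s.n_trials_retained,
        }
        for s in summaries
    )
    for pid, sub in df.groupby("participant_id"):
        sessions = list(sub["session"])
        if len(sessions) != len(set(sessions)):
            raise ValueError(f"duplicate session rows for participant {pid}")
        if set(sessions) != set(SESSIONS):
            missing = set(SESSIONS) - set(sessions)
            raise ValueError(
                f"participant {pid} is missing session(s): {sorted(missing)}"
            )
    return df.reset_index(drop=True)
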