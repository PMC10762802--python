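"""End-to-end convenience wrappers: recording -> session summary -> cohort table."""

from __future__ import annotations

import pandas as pd

from .events import detect_events, gaze_amplitude, oscillation_ratio
from .signal_processing import DEFAULT_ONSET_THRESHOLD_DPS, segment_trials
from .synthetic_data import ParticipantData, RecordingSession
from .trial_qc import (QCReport, SessionSummary, TrialRecord, apply_exclusions,
                       cohort_table, summarize)

__all__ = ["process_session", "process_cohort"]


def process_session(
    recording: RecordingSession,
    participant_id: str,
    group: str,
    session: str,
    onset_threshold_dps: float = DEFAULT_ONSET_THRESHOLD_DPS,
    cutoff_hz: float = 20.0,
) -> tuple[SessionSummary, QCReport, pd.DataFrame]:
    """Filter, segment, detect events, QC and summarize one session.

    Returns the session summary, the QC report and a per-trial table of
    landmarks, ratios and flags.
    """
    segments = segment_trials(
        recording, onset_threshold_dps=onset_threshold_dps, cutoff_hz=cutoff_hz
    )
    records: list[TrialRecord] = []
    rows = []
    for seg in segments:
        ev = detect_events(seg)
        ratio = oscillation_ratio(ev)
        amplitude = gaze_amplitude(seg)
        records.append(
            TrialRecord(
                trial_index=seg.trial_index,
                ratio_pct=ratio.ratio_pct,
                amplitude_deg=amplitude,
                determinate=ratio.determinate,
                extended_early=seg.extended_early,
                extended_late=seg.extended_late,
            )
        )
        rows.append(
            {
                "trial_index": seg.trial_index,
                "target_amplitude_deg": seg.target_amplitude_deg,
                "ratio_pct": ratio.ratio_pct,
                "gaze_amplitude_deg": amplitude,
                "determinate": ratio.determinate,
                "extended_early": seg.extended_early,
                "extended_late": seg.extended_late,
                "t_peak_s": ev.t_peak_s,
                "v_peak_dps": ev.v_peak_dps,
                "t_zc1_s": ev.t_zc1_s,
                "t_min_s": ev.t_min_s,
                "v_min_dps": ev.v_min_dps,
                "t_zc2_s": ev.t_zc2_s,
            }
        )
    report = apply_exclusions(records)
    summary = summarize(records, report, participant_id, group, session)
    return summary, report, pd.DataFrame(rows)


def process_cohort(
    participants: list[ParticipantData],
    onset_threshold_dps: float = DEFAULT_ONSET_THRESHOLD_DPS,
    cutoff_hz: float = 20.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], QCReport]]:
    """Run :func:`process_session` over a cohort; returns the cohort table."""
    summaries = []
    reports: dict[tuple[str, str], QCReport] = {}
    for p in participants:
        for session, rec in p.sessions.items():
            summary, report, _ = process_session(
                rec, p.participant_id, p.group, session,
                onset_threshold_dps=onset_threshold_dps, cutoff_hz=cutoff_hz,
            )
            summaries.append(summary)
            reports[(p.participant_id, session)] = report
    return cohort_table(summaries), reports
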