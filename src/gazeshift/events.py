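"""Kinematic landmark detection and the head-oscillation ratio.

For each trial the head-velocity trace is rectified by the protocol's
movement direction and four landmarks are located: the first positive peak,
the first subsequent downward zero crossing, the absolute minimum of the
first undershoot, and the second (upward) zero crossing.  The primary
outcome is the head-oscillation ratio — the undershoot magnitude expressed
as a percentage of peak head velocity, so larger values mean larger terminal
head oscillations regardless of movement vigor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_processing import TrialSegment

__all__ = ["EventSet", "OscillationRatio", "detect_events", "oscillation_ratio",
           "gaze_amplitude"]

#: Span (s) of the terminal plateau used to read off the gaze endpoint.
PLATEAU_SPAN_S = 0.1


@dataclass
class EventSet:
    """Detected landmarks of one gaze shift, in rectified coordinates."""

    trial_index: int
    determinate: bool
    t_peak_s: float = np.nan
    v_peak_dps: float = np.nan
    t_zc1_s: float = np.nan
    t_min_s: float = np.nan
    v_min_dps: float = np.nan
    t_zc2_s: float = np.nan


@dataclass
class OscillationRatio:
    """Undershoot relative to peak head velocity, in percent."""

    trial_index: int
    determinate: bool
    ratio_pct: float = np.nan


def _interp_zero(t0: float, t1: float, v0: float, v1: float) -> float:
    """Zero-crossing time by linear interpolation; ties go to the earlier sample."""
    if v0 == 0.0:
        return t0
    return t0 + (t1 - t0) * v0 / (v0 - v1)


def detect_events(segment: TrialSegment) -> EventSet:
    """Locate peak, zero crossings and undershoot minimum of one trial.

    The velocity trace is rectified by the protocol's direction sign, so a
    correctly directed shift always shows a positive peak.  If no positive
    peak or no subsequent downward zero crossing exists the event set is
    indeterminate (the trial is excluded downstream).  If velocity never
    crosses back above zero after the undershoot, the window end stands in
    for the second zero crossing.
    """
    v = segment.direction_sign * np.asarray(segment.head_vel_dps, dtype=float)
    if v.size == 0:
        raise ValueError("empty trial segment")
    if v.size < 10:
        raise ValueError("trial segment has fewer than 10 samples")
    t = segment.window[0] + np.arange(v.size) / segment.sample_rate_hz

    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    if v_peak <= 0:
        return EventSet(segment.trial_index, determinate=False)

    # first downward zero crossing after the peak
    after = v[i_peak:]
    neg = np.nonzero(after < 0)[0]
    if neg.size == 0:
        return EventSet(segment.trial_index, determinate=False)
    j = i_peak + int(neg[0])  # first strictly negative sample after peak
    t_zc1 = _interp_zero(t[j - 1], t[j], v[j - 1], v[j])

    # undershoot: minimum between zc1 and the next upward crossing (or end)
    up = np.nonzero(v[j:] >= 0)[0]
    if up.size:
        k = j + int(up[0])  # first non-negative sample after the undershoot
        i_min = j + int(np.argmin(v[j:k]))
        t_zc2 = _interp_zero(t[k - 1], t[k], v[k - 1], v[k])
    else:
        i_min = j + int(np.argmin(v[j:]))
        t_zc2 = float(t[-1])

    return EventSet(
        trial_index=segment.trial_index,
        determinate=True,
        t_peak_s=float(t[i_peak]),
        v_peak_dps=v_peak,
        t_zc1_s=float(t_zc1),
        t_min_s=float(t[i_min]),
        v_min_dps=float(v[i_min]),
        t_zc2_s=float(t_zc2),
    )


def oscillation_ratio(events: EventSet) -> OscillationRatio:
    """Head-oscillation ratio: 100 * |undershoot| / peak velocity."""
    if not events.determinate:
        return OscillationRatio(events.trial_index, determinate=False)
    if events.v_peak_dps == 0:
        raise ValueError("determinate event set with zero peak velocity")
    return OscillationRatio(
        trial_index=events.trial_index,
        determinate=True,
        ratio_pct=100.0 * abs(events.v_min_dps) / abs(events.v_peak_dps),
    )


def gaze_amplitude(segment: TrialSegment) -> float:
    """Gaze displacement (deg) over the (possibly extended) trial window.

    Gaze is head position plus eye-in-head position; the amplitude is the
    absolute difference between the mean gaze over the final 100 ms plateau
    and the gaze at window start.
    """
    g = np.asarray(segment.head_pos_deg, dtype=float) + np.asarray(
        segment.eye_pos_deg, dtype=float
    )
    n_plateau = int(round(PLATEAU_SPAN_S * segment.sample_rate_hz))
    if g.size <= n_plateau:
        raise ValueError("trial window shorter than the endpoint plateau span")
    return float(abs(g[-n_plateau:].mean() - g[0]))
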