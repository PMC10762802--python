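"""Filtering, head-position derivation and trial segmentation.

Raw channels are smoothed with a zero-phase Gaussian low-pass (the -3 dB
point is the cutoff frequency), head position is recovered by trapezoidal
integration of head velocity referenced to the initial 10-s central-light
posture, and the continuous recording is cut into per-shift trial windows
bounded by target and control light onsets.  Trials in which the participant
moved before the target flashed, or only after the control light, get their
window extended to the neighbouring light events and are flagged rather than
discarded — a programmatic stand-in for the study's manual review, with every
decision left auditable in the flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .protocol import LARGE_SHIFT_AMPLITUDES, LEDProtocol
from .synthetic_data import RecordingSession

__all__ = [
    "TrialSegment",
    "gaussian_sigma_s",
    "gaussian_lowpass",
    "integrate_velocity",
    "segment_trials",
]

logger = logging.getLogger(__name__)

#: Gaze-speed threshold (deg/s) used to classify early/late movement onsets.
DEFAULT_ONSET_THRESHOLD_DPS = 20.0



@dataclass
class TrialSegment:
    """One gaze shift's trace window cut from a session recording."""

    trial_index: int
    target_amplitude_deg: float
    window: tuple[float, float]  # [start_s, end_s] on the session clock
    head_vel_dps: np.ndarray
    head_pos_deg: np.ndarray
    eye_pos_deg: np.ndarray
    sample_rate_hz: float
    direction_sign: int  # +1 counterclockwise, -1 clockwise
    extended_early: bool = False
    extended_late: bool = False

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("trial window start must precede its end")
        if self.direction_sign not in (-1, 1):
            raise ValueError("direction_sign must be +1 or -1")


def gaussian_sigma_s(cutoff_hz: float) -> float:
    """Kernel sigma (seconds) putting the Gaussian's -3 dB point at cutoff_hz."""
    return float(np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz))


def gaussian_lowpass(
    signal: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 20.0
) -> np.ndarray:
    """Zero-phase Gaussian low-pass filter.

    The kernel sigma is sqrt(ln 2)/(2*pi*cutoff), so the amplitude response
    exp(-2*pi^2*sigma^2*f^2) equals 1/sqrt(2) at the cutoff.  The kernel is
    truncated at +/-4 sigma and normalized (unit DC gain); edges are padded
    by reflection.  Output length equals input length.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if cutoff_hz >= sample_rate_hz / 2.0:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    sigma_samples = gaussian_sigma_s(cutoff_hz) * sample_rate_hz
    return gaussian_filter1d(x, sigma_samples, mode="reflect", truncate=4.0)


def integrate_velocity(
    head_vel: np.ndarray,
    sample_rate_hz: float,
    reference_window: tuple[float, float],
) -> np.ndarray:
    """Head position (deg) from trapezoidal integration of head velocity.

    The mean position over ``reference_window`` (the initial 10-s central
    light, when the head rests at 0 deg) is subtracted so the reference
    posture maps to zero.
    """
    v = np.asarray(head_vel, dtype=float)
    dt = 1.0 / sample_rate_hz
    start, end = reference_window
    duration = (len(v) - 1) * dt
    if start < 0 or end > duration + dt / 2 or start >= end:
        raise ValueError("reference window lies outside the recording")
    pos = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0) * dt])
    i0 = int(np.ceil(start * sample_rate_hz))
    i1 = int(np.floor(end * sample_rate_hz)) + 1
    return pos - pos[i0:i1].mean()


def _first_crossing(speed: np.ndarray, threshold: float) -> bool:
    return bool(np.any(speed > threshold))


def segment_trials(
    recording: RecordingSession,
    protocol: LEDProtocol | None = None,
    onset_threshold_dps: float = DEFAULT_ONSET_THRESHOLD_DPS,
    cutoff_hz: float | None = 20.0,
) -> list[TrialSegment]:
    """Cut a session recording into per-shift trial windows.

    Only the large (75/80 deg) shifts are emitted.  The nominal window runs
    from target onset to control onset.  If gaze speed (head velocity plus
    the eye-position derivative) exceeds ``onset_threshold_dps`` between the
    prior control light going off and target onset, the window is extended
    back to the prior control light (``extended_early``); if the movement is still ongoing at control
    onset — or only begins after it — the window is extended to the next
    target onset (``extended_late``).  With ``cutoff_hz`` set, channels are
    Gaussian-low-pass filtered before segmentation.
    """
    protocol = protocol or recording.protocol
    if protocol is None:
        raise ValueError("no protocol supplied with the recording")
    fs = recording.sample_rate_hz
    n = len(recording.time_s)
    duration = (n - 1) / fs
    if protocol.duration_s > duration + 1.0 / fs:
        raise ValueError("protocol extends beyond the recording")

    head_vel = recording.head_vel_dps
    eye_pos = recording.eye_pos_deg
    if cutoff_hz is not None:
        head_vel = gaussian_lowpass(head_vel, fs, cutoff_hz)
        eye_pos = gaussian_lowpass(eye_pos, fs, cutoff_hz)

    targets = protocol.targets
    controls = protocol.controls
    reference = targets[0]
    head_pos = integrate_velocity(
        head_vel, fs, (reference.onset_s, reference.onset_s + reference.duration_s)
    )
    eye_vel = np.gradient(eye_pos) * fs
    gaze_speed = np.abs(head_vel + eye_vel)

    def idx(t: float) -> int:
        return int(np.clip(round(t * fs), 0, n - 1))

    segments: list[TrialSegment] = []
    for k in range(1, len(targets)):
        delta = targets[k].position_deg - targets[k - 1].position_deg
        if abs(delta) not in LARGE_SHIFT_AMPLITUDES:
            continue
        t_start = targets[k].onset_s
        t_end = controls[k].onset_s
        extended_early = extended_late = False

        prev_off = controls[k - 1].onset_s + controls[k - 1].duration_s
        lookback = gaze_speed[idx(prev_off): idx(t_start) + 1]
        if _first_crossing(lookback, onset_threshold_dps):
            t_start = controls[k - 1].onset_s
            extended_early = True

        t_next = targets[k + 1].onset_s if k + 1 < len(targets) else duration
        moving_at_control = gaze_speed[idx(t_end)] > onset_threshold_dps
        nominal = gaze_speed[idx(targets[k].onset_s): idx(t_end) + 1]
        tail = gaze_speed[idx(t_end): idx(t_next) + 1]
        missed_movement = (
            not _first_crossing(nominal, onset_threshold_dps)
            and _first_crossing(tail, onset_threshold_dps)
        )
        if moving_at_control or missed_movement:
            t_end = t_next
            extended_late = True

        if extended_early or extended_late:
            logger.info(
                "trial %d window extended (%s%s) to [%.2f, %.2f] s",
                k - 1,
                "early" if extended_early else "",
                "late" if extended_late else "",
                t_start,
                t_end,
            )
        i0, i1 = idx(t_start), idx(t_end) + 1
        segments.append(
            TrialSegment(
                trial_index=k - 1,
                target_amplitude_deg=float(abs(delta)),
                window=(t_start, t_end),
                head_vel_dps=head_vel[i0:i1].copy(),
                head_pos_deg=head_pos[i0:i1].copy(),
                eye_pos_deg=eye_pos[i0:i1].copy(),
                sample_rate_hz=fs,
                direction_sign=1 if delta > 0 else -1,
                extended_early=extended_early,
                extended_late=extended_late,
            )
        )
    return segments
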