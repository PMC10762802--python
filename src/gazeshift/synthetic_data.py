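"""Forward simulation of eye-head gaze-shift recordings.

The generator emulates the experiment's 220-Hz two-channel recordings: a head
angular-velocity channel (inertial sensors) and a horizontal eye-in-head
position channel (video-oculography).  Each gaze shift is modelled as a
minimum-jerk head-velocity bell plus, when the controller's internal estimate
of the head moment of inertia disagrees with the actual plant, a damped
terminal oscillation whose first undershoot is a fixed fraction of peak head
velocity.  The eye channel is constructed so that gaze (head displacement +
eye-in-head displacement) lands on the target, i.e. the vestibulo-ocular
counter-rotation is implicit.

Mismatch model
--------------
The injected head-oscillation ratio (percent of peak velocity) is

    ratio_pct = ratio_gain_pct * |inertia_factor + goggles_inertia
                                  - internal_inertia|

a linear map from the inertia prediction error; it is zero when the internal
model is correct.  Trial-by-trial learning moves ``internal_inertia`` toward
the actual inertia by a fractional step ``learning_rate``.  Donning the
weighted helmet multiplies the head moment of inertia 3.1-fold without
warning; removing it is visible, so helmet-attributed learning is discarded
between sessions while adaptation to the measurement goggles carries over.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .protocol import LEDProtocol, build_standard_protocol

__all__ = [
    "SAMPLE_RATE_HZ",
    "SESSIONS",
    "PlantParams",
    "BehaviorParams",
    "TrialTruth",
    "RecordingSession",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "simulate_ratio_table",
    "participant_stream",
    "write_recording",
    "read_recording",
]

SAMPLE_RATE_HZ = 220
SESSIONS = ("unweighted1", "weighted", "unweighted2")

#: Helmet multiplier of the head moment of inertia in the weighted session.
WEIGHTED_INERTIA_FACTOR = 3.1


@dataclass
class PlantParams:
    """Head-plant and controller parameters for one simulated session.

    ``inertia_factor`` is the actual head moment of inertia relative to the
    natural head (1.0 natural, 3.1 with the weighted helmet);
    ``internal_inertia`` is the controller's current belief about it.
    ``goggles_inertia`` is a lumped effective mismatch present from the first
    trial of a naive participant (measurement-goggle mass plus any baseline
    miscalibration of the internal model).  Defaults are calibrated so the
    injected session-mean ratios approximate the observed ~2.2 / 6.9 / 1.5 %
    pattern across unweighted-weighted-unweighted sessions.
    """

    inertia_factor: float = 1.0
    internal_inertia: float = 1.0
    learning_rate: float = 0.0073
    osc_freq_hz: float = 2.5
    osc_decay_s: float = 0.15
    noise_sd_dps: float = 1.0
    goggles_inertia: float = 0.85
    ratio_gain_pct: float = 3.1  # percent ratio per unit inertia mismatch
    head_fraction: float = 0.9  # head share of the gaze amplitude
    peak_vel_scale_hz: float = 4.3  # peak head velocity per deg of head excursion
    trial_jitter_sd: float = 0.25  # lognormal sigma on the injected ratio
    eye_noise_sd_deg: float = 0.05
    osc_window_s: float = 0.8

    def __post_init__(self) -> None:
        if self.inertia_factor < 1:
            raise ValueError("inertia_factor must be >= 1")
        if not 0 <= self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.osc_freq_hz <= 0:
            raise ValueError("osc_freq_hz must be positive")
        if self.noise_sd_dps < 0:
            raise ValueError("noise_sd_dps must be non-negative")

    @property
    def mismatch(self) -> float:
        """Signed inertia prediction error of the controller."""
        return self.inertia_factor + self.goggles_inertia - self.internal_inertia


@dataclass
class BehaviorParams:
    """Rates and timing of anticipatory / delayed gaze shifts."""

    early_rate: float = 0.0
    late_rate: float = 0.0
    reaction_mean_s: float = 0.18
    reaction_sd_s: float = 0.03
    early_advance_s: tuple[float, float] = (0.15, 0.6)
    late_delay_s: tuple[float, float] = (0.05, 0.3)

    def __post_init__(self) -> None:
        if self.early_rate + self.late_rate > 1:
            raise ValueError("early_rate + late_rate must not exceed 1")


@dataclass
class TrialTruth:
    """Noiseless injected ground truth for one simulated gaze shift."""

    trial_index: int
    amplitude_deg: float
    true_ratio_pct: float
    peak_vel_dps: float
    head_contribution_deg: float
    eye_contribution_deg: float
    onset_offset_s: float = 0.0


@dataclass
class RecordingSession:
    """Continuous two-channel 220-Hz recording of one experimental session."""

    sample_rate_hz: float
    time_s: np.ndarray
    head_vel_dps: np.ndarray
    eye_pos_deg: np.ndarray
    protocol: LEDProtocol | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.head_vel_dps) == len(self.eye_pos_deg)):
            raise ValueError("recording channels must have equal length")


def _minimum_jerk_velocity(amplitude: float, duration: float, t: np.ndarray) -> np.ndarray:
    """Bell-shaped velocity of a minimum-jerk point-to-point movement."""
    s = np.clip(t / duration, 0.0, 1.0)
    return 30.0 * amplitude / duration * s**2 * (1.0 - s) ** 2


def _minimum_jerk_position(amplitude: float, duration: float, t: np.ndarray) -> np.ndarray:
    s = np.clip(t / duration, 0.0, 1.0)
    return amplitude * (10 * s**3 - 15 * s**4 + 6 * s**5)


def simulate_trial(
    params: PlantParams,
    target_amplitude: float,
    rng: np.random.Generator,
    sample_rate_hz: float = SAMPLE_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray, TrialTruth]:
    """Simulate one gaze shift in the positive direction.

    Returns the head-velocity trace (deg/s), the eye-in-head position trace
    (deg) and the noiseless injected :class:`TrialTruth`.  The head velocity
    is a minimum-jerk bell followed, for a non-zero inertia mismatch, by a
    damped sinusoidal oscillation whose first negative peak equals
    ``ratio/100`` of the sampled peak velocity.  Gaze (head displacement plus
    eye-in-head displacement) lands exactly on the target amplitude.
    """
    if target_amplitude <= 0:
        raise ValueError("target_amplitude must be positive")
    fs = float(sample_rate_hz)
    head_amp = params.head_fraction * target_amplitude
    move_dur = 1.875 / params.peak_vel_scale_hz  # peak = 1.875*H/T = scale*H
    n_move = int(round(move_dur * fs))

    ratio = params.ratio_gain_pct * abs(params.mismatch)
    if ratio > 0 and params.trial_jitter_sd > 0:
        sd = params.trial_jitter_sd
        ratio *= float(np.exp(rng.normal(-0.5 * sd**2, sd)))

    n_osc = int(round(params.osc_window_s * fs)) if ratio > 0 else 0
    n = n_move + n_osc
    t = np.arange(n) / fs

    head_vel = np.zeros(n)
    head_vel[:n_move] = _minimum_jerk_velocity(head_amp, move_dur, t[:n_move])
    v_peak = float(head_vel.max())

    if ratio > 0:
        t_osc = np.arange(n_osc) / fs
        unit = np.exp(-t_osc / params.osc_decay_s) * np.sin(
            2 * np.pi * params.osc_freq_hz * t_osc
        )
        # scale so the sampled first undershoot is exactly -ratio/100 * v_peak
        head_vel[n_move:] = -(ratio / 100.0) * v_peak / unit.max() * unit

    head_pos = np.concatenate(
        [[0.0], np.cumsum((head_vel[1:] + head_vel[:-1]) / 2.0) / fs]
    )
    gaze_dur = 0.75 * move_dur
    gaze_pos = _minimum_jerk_position(target_amplitude, gaze_dur, t)
    eye_pos = gaze_pos - head_pos

    head_contribution = float(head_pos[-1])
    truth = TrialTruth(
        trial_index=0,
        amplitude_deg=float(target_amplitude),
        true_ratio_pct=float(ratio),
        peak_vel_dps=v_peak,
        head_contribution_deg=head_contribution,
        eye_contribution_deg=float(target_amplitude - head_contribution),
    )

    if params.noise_sd_dps > 0:
        head_vel = head_vel + rng.normal(0.0, params.noise_sd_dps, n)
    if params.eye_noise_sd_deg > 0:
        eye_pos = eye_pos + rng.normal(0.0, params.eye_noise_sd_deg, n)
    return head_vel, eye_pos, truth


def simulate_session(
    params: PlantParams,
    protocol: LEDProtocol,
    behavior: BehaviorParams | None = None,
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> tuple[RecordingSession, list[TrialTruth]]:
    """Assemble a full session recording on the protocol timeline.

    One movement trial is inserted per non-zero target-to-target shift,
    aligned to the target onset plus a reaction time (or shifted before
    target onset / after control onset for early / late movers, drawn with
    the configured rates).  Between shifts the channels hold their
    steady-state values plus measurement noise.  ``params.internal_inertia``
    is updated in place after every movement, so the caller can carry the
    adapted internal model into the next session.
    """
    behavior = behavior or BehaviorParams()
    rng = rng if rng is not None else np.random.default_rng(0)
    fs = float(SAMPLE_RATE_HZ)
    n = int(np.ceil((protocol.duration_s + 1.5) * fs))
    time_s = np.arange(n) / fs
    head_vel = np.zeros(n)
    eye_pos = np.zeros(n)

    targets = protocol.targets
    controls = protocol.controls
    noisefree = replace(params, noise_sd_dps=0.0, eye_noise_sd_deg=0.0)

    eye_state = 0.0
    fill_from = 0
    prev = None  # (i0, i1, sign, eye_trace, eye_state_before)
    truths: list[TrialTruth] = []
    for k in range(1, len(targets)):
        delta = targets[k].position_deg - targets[k - 1].position_deg
        if delta == 0:
            continue
        sign = 1.0 if delta > 0 else -1.0
        amplitude = abs(delta)

        u = rng.uniform()
        target_onset = targets[k].onset_s
        if u < behavior.early_rate:
            advance = rng.uniform(*behavior.early_advance_s)
            floor = controls[k - 1].onset_s + 0.05
            t_on = max(target_onset - advance, floor)
        elif u < behavior.early_rate + behavior.late_rate:
            t_on = controls[k].onset_s + rng.uniform(*behavior.late_delay_s)
        else:
            t_on = target_onset + max(0.08, rng.normal(behavior.reaction_mean_s,
                                                       behavior.reaction_sd_s))
        next_onset = targets[k + 1].onset_s if k + 1 < len(targets) else np.inf
        if not controls[k - 1].onset_s < t_on < next_onset:
            raise ValueError(
                f"overlapping trials at shift {k - 1}: onset offset exceeds the ITI"
            )

        noisefree.internal_inertia = params.internal_inertia
        trial_vel, trial_eye, truth = simulate_trial(noisefree, amplitude, rng)
        truth.trial_index = k - 1
        truth.onset_offset_s = t_on - target_onset

        i0 = int(round(t_on * fs))
        i1 = i0 + len(trial_vel)
        if i1 > n:
            raise ValueError(f"trial {k - 1} extends past the end of the recording")
        if prev is not None and i0 < prev[1]:
            # the new movement begins while the previous oscillation tail is
            # still ringing: the head cannot do both, so the old tail stops
            p0, p1, psign, peye, pstate = prev
            head_vel[i0:p1] = 0.0
            eye_state = pstate + psign * peye[i0 - p0]
        eye_pos[fill_from:i0] = eye_state
        head_vel[i0:i1] += sign * trial_vel
        eye_pos[i0:i1] = eye_state + sign * trial_eye
        prev = (i0, i1, sign, trial_eye, eye_state)
        eye_state += sign * trial_eye[-1]
        fill_from = i1
        truths.append(truth)

        actual = params.inertia_factor + params.goggles_inertia
        params.internal_inertia += params.learning_rate * (
            actual - params.internal_inertia
        )

    eye_pos[fill_from:] = eye_state
    if params.noise_sd_dps > 0:
        head_vel = head_vel + rng.normal(0.0, params.noise_sd_dps, n)
    if params.eye_noise_sd_deg > 0:
        eye_pos = eye_pos + rng.normal(0.0, params.eye_noise_sd_deg, n)

    session = RecordingSession(
        sample_rate_hz=fs,
        time_s=time_s,
        head_vel_dps=head_vel,
        eye_pos_deg=eye_pos,
        protocol=protocol,
        meta=dict(meta or {}),
    )
    return session, truths


#: Early/late mover rates observed per group (fraction of trials).
DEFAULT_BEHAVIOR = {
    "patient": BehaviorParams(early_rate=0.013, late_rate=0.044),
    "control": BehaviorParams(early_rate=0.003, late_rate=0.051),
}


@dataclass
class ParticipantData:
    """One simulated participant: three session recordings plus ground truth."""

    participant_id: str
    group: str
    sessions: dict[str, RecordingSession]
    truths: pd.DataFrame


def simulate_cohort(
    group_params: dict[str, PlantParams] | None = None,
    n_per_group: int = 15,
    seed: int = 0,
    behavior_by_group: dict[str, BehaviorParams] | None = None,
    participant_sd: float = 0.35,
) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Simulate a two-group cohort over the three-session protocol.

    Every participant runs unweighted1 (natural inertia), weighted (3.1-fold
    inertia) and unweighted2 (natural inertia again).  The internal model
    adapted during unweighted1 carries over; helmet-attributed learning is
    discarded when the helmet visibly comes off.  ``participant_sd`` is the
    lognormal sigma of a per-participant multiplier on the ratio gain
    (between-participant variability in oscillation magnitude).

    Returns the participant list and a long-format truth table with one row
    per simulated movement trial.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    group_params = group_params or {"patient": PlantParams(), "control": PlantParams()}
    behavior_by_group = behavior_by_group or DEFAULT_BEHAVIOR
    root = np.random.SeedSequence(seed)

    participants: list[ParticipantData] = []
    rows: list[dict] = []
    for group in sorted(group_params):
        base = group_params[group]
        behavior = behavior_by_group.get(group, BehaviorParams())
        for j in range(n_per_group):
            pid = f"{group[:3]}{j + 1:02d}"
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            gain = base.ratio_gain_pct
            if participant_sd > 0:
                gain *= float(
                    np.exp(rng.normal(-0.5 * participant_sd**2, participant_sd))
                )

            sessions: dict[str, RecordingSession] = {}
            belief = 1.0  # naive internal model at experiment start
            belief_after_s1 = belief
            for session_label in SESSIONS:
                factor = (
                    WEIGHTED_INERTIA_FACTOR if session_label == "weighted" else 1.0
                )
                start_belief = belief_after_s1 if session_label == "unweighted2" else belief
                sp = replace(
                    base,
                    inertia_factor=factor,
                    internal_inertia=start_belief,
                    ratio_gain_pct=gain,
                )
                proto = build_standard_protocol(
                    seed=int(rng.integers(0, 2**31 - 1))
                )
                meta = {
                    "participant_id": pid,
                    "group": group,
                    "session": session_label,
                }
                rec, truths = simulate_session(sp, proto, behavior, rng, meta)
                sessions[session_label] = rec
                belief = sp.internal_inertia
                if session_label == "unweighted1":
                    belief_after_s1 = belief
                for tr in truths:
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "session": session_label,
                            "trial_index": tr.trial_index,
                            "amplitude_deg": tr.amplitude_deg,
                            "true_ratio_pct": tr.true_ratio_pct,
                            "peak_vel_dps": tr.peak_vel_dps,
                            "head_contribution_deg": tr.head_contribution_deg,
                            "eye_contribution_deg": tr.eye_contribution_deg,
                            "onset_offset_s": tr.onset_offset_s,
                        }
                    )
            participants.append(
                ParticipantData(pid, group, sessions, pd.DataFrame(
                    [r for r in rows if r["participant_id"] == pid]
                ))
            )
    truth_table = pd.DataFrame(rows)
    return participants, truth_table


# ---------------------------------------------------------------------------
# Summary-level generator for the statistics layer
# ---------------------------------------------------------------------------

#: Session-mean oscillation ratios (percent) used as the default injected
#: pattern: strong weighted-session effect, mild unweighted1 -> unweighted2
#: learning, no group difference.
DEFAULT_SESSION_MEANS = (2.2, 6.9, 1.5)


def simulate_ratio_table(
    n_per_group: int = 15,
    seed: int = 0,
    session_means: tuple[float, float, float] = DEFAULT_SESSION_MEANS,
    participant_sd: float = 0.4,
    residual_sd: float = 0.2,
    group_effect: float = 0.0,
) -> pd.DataFrame:
    """Draw a participant x session table of mean oscillation ratios.

    The model is multiplicative: a lognormal participant factor (sigma
    ``participant_sd``) scales all three session means of that participant,
    and lognormal residual noise (sigma ``residual_sd``) perturbs each cell.
    ``group_effect`` is the fractional elevation of patients' means (0 = no
    group difference).  Returns a long-format cohort table compatible with
    the Bayesian model-comparison layer.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("control", "patient"):
        mult = 1.0 + group_effect if group == "patient" else 1.0
        for j in range(n_per_group):
            pid = f"{group[:3]}{j + 1:02d}"
            f_p = np.exp(rng.normal(-0.5 * participant_sd**2, participant_sd))
            for session, mean in zip(SESSIONS, session_means):
                value = (
                    mean
                    * mult
                    * f_p
                    * np.exp(rng.normal(-0.5 * residual_sd**2, residual_sd))
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "session": session,
                        "mean_ratio_pct": float(value),
                        "n_trials_retained": 43,
                    }
                )
    return pd.DataFrame(rows)


def participant_stream(
    seed: int = 0,
    session_means: tuple[float, float, float] = DEFAULT_SESSION_MEANS,
    participant_sd: float = 0.4,
    residual_sd: float = 0.2,
    group_effect: float = 0.0,
) -> Iterator[dict]:
    """Infinite arrival stream of participants for the sequential design.

    Yields dicts with ``participant_id``, ``group`` and per-session mean
    ratios, alternating control/patient so both groups fill evenly.
    """
    rng = np.random.default_rng(seed)
    counter = {"control": 0, "patient": 0}
    while True:
        for group in ("control", "patient"):
            counter[group] += 1
            mult = 1.0 + group_effect if group == "patient" else 1.0
            f_p = np.exp(rng.normal(-0.5 * participant_sd**2, participant_sd))
            means = {
                session: float(
                    m * mult * f_p * np.exp(rng.normal(-0.5 * residual_sd**2, residual_sd))
                )
                for session, m in zip(SESSIONS, session_means)
            }
            yield {
                "participant_id": f"{group[:3]}{counter[group]:02d}",
                "group": group,
                "means": means,
            }


# ---------------------------------------------------------------------------
# Plain-text recording I/O
# ---------------------------------------------------------------------------

def write_recording(session: RecordingSession, path) -> None:
    """Write a recording as delimited text with a metadata header."""
    with open(path, "w") as fh:
        for key, value in session.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(f"# sample_rate_hz: {session.sample_rate_hz:g}\n")
        fh.write("time_s\thead_vel_dps\teye_pos_deg\n")
        for t, v, e in zip(session.time_s, session.head_vel_dps, session.eye_pos_deg):
            fh.write(f"{t:.6f}\t{v:.6f}\t{e:.6f}\n")


def read_recording(path, protocol: LEDProtocol | None = None) -> RecordingSession:
    """Read a recording written by :func:`write_recording`."""
    meta: dict = {}
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), sep="\t")
    fs = float(meta.pop("sample_rate_hz", SAMPLE_RATE_HZ))
    return RecordingSession(
        sample_rate_hz=fs,
        time_s=df["time_s"].to_numpy(),
        head_vel_dps=df["head_vel_dps"].to_numpy(),
        eye_pos_deg=df["eye_pos_deg"].to_numpy(),
        protocol=protocol,
        meta=meta,
    )
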