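"""LED stimulus protocol for the eye-head gaze-shift experiment.

The protocol is a fixed sequence of horizontal LED targets (center = 0 deg,
negative = clockwise).  Each target flash is followed, after a randomized
lights-off inter-trial interval (ITI), by a *control* flash at the same
position that lets the participant correct a misdirected gaze shift; a second
randomized ITI precedes the next target.  The very first central light serves
as the head-posture reference and stays on for 10 s.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEDEvent",
    "LEDProtocol",
    "STANDARD_TARGET_POSITIONS",
    "build_standard_protocol",
    "shift_amplitudes",
    "count_large_shifts",
]

#: Horizontal target positions (deg) in presentation order.  The first 0 deg
#: entry is the continuously lit reference light; every later entry flashes
#: briefly and is echoed by a control light at the same position.
STANDARD_TARGET_POSITIONS: tuple[int, ...] = (
    0, 0, -40, 40, -40, 40, -35, 40, -40, 40, -35, 40, -40, 35, 0,
    -40, 40, -40, 35, -40, 40, -40, 35, -40, 40, -35, 40, -35, 40,
    -40, 35, -40, 35, -35, 40, -35, 35, -40, 40, -35, 35, -40, 40,
    -35, 35, -40, 40, -40, 40, -35, 40, -40, 0,
)

#: Amplitudes (deg) analysed as "large" gaze shifts.
LARGE_SHIFT_AMPLITUDES = (75, 80)

# Timing constants (seconds).
REFERENCE_DURATION_S = 10.0
FLASH_DURATION_S = 0.1
TARGET_TO_CONTROL_ITI_S = (1.6, 2.4)
CONTROL_TO_TARGET_ITI_S = (0.8, 1.2)


@dataclass(frozen=True)
class LEDEvent:
    """One light event on the session timeline."""

    position_deg: int
    onset_s: float
    duration_s: float
    kind: str  # "target", "control" or "reference"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("LED event duration must be positive")
        if self.kind not in ("target", "control", "reference"):
            raise ValueError(f"unknown LED event kind {self.kind!r}")


@dataclass(frozen=True)
class LEDProtocol:
    """Ordered LED events plus the seed used to draw the ITIs."""

    events: tuple[LEDEvent, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("LED event onsets must be strictly increasing")

    @property
    def targets(self) -> tuple[LEDEvent, ...]:
        """Target events, the reference light included."""
        return tuple(e for e in self.events if e.kind in ("target", "reference"))

    @property
    def controls(self) -> tuple[LEDEvent, ...]:
        return tuple(e for e in self.events if e.kind == "control")

    @property
    def duration_s(self) -> float:
        last = self.events[-1]
        return last.onset_s + last.duration_s

    # -- plain-text serialization ------------------------------------------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# seed: {self.seed}\n")
        buf.write("# kind\tposition_deg\tonset_s\tduration_s\n")
        for e in self.events:
            buf.write(f"{e.kind}\t{e.position_deg}\t{e.onset_s:.6f}\t{e.duration_s:.6f}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LEDProtocol":
        seed = 0
        events = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("seed:"):
                    seed = int(body.split(":", 1)[1])
                continue
            kind, pos, onset, dur = line.split("\t")
            events.append(LEDEvent(int(pos), float(onset), float(dur), kind))
        return cls(events=tuple(events), seed=seed)


def build_standard_protocol(seed: int = 0) -> LEDProtocol:
    """Build the standard 53-target protocol with seeded random ITIs.

    Target positions are fixed; only the two lights-off intervals are random,
    drawn uniformly from 1.6-2.4 s (target -> control) and 0.8-1.2 s
    (control -> next target).
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    events: list[LEDEvent] = []
    t = 0.0
    for i, pos in enumerate(STANDARD_TARGET_POSITIONS):
        if i == 0:
            events.append(LEDEvent(pos, t, REFERENCE_DURATION_S, "reference"))
            t += REFERENCE_DURATION_S
        else:
            events.append(LEDEvent(pos, t, FLASH_DURATION_S, "target"))
            t += FLASH_DURATION_S
        t += rng.uniform(*TARGET_TO_CONTROL_ITI_S)
        events.append(LEDEvent(pos, t, FLASH_DURATION_S, "control"))
        t += FLASH_DURATION_S
        t += rng.uniform(*CONTROL_TO_TARGET_ITI_S)
    return LEDProtocol(events=tuple(events), seed=seed)


def shift_amplitudes(protocol: LEDProtocol) -> list[int]:
    """Absolute position change (deg) between consecutive target lights."""
    targets = protocol.targets
    if len(targets) < 2:
        raise ValueError("protocol has fewer than 2 target events; no gaze shifts")
    return [abs(b.position_deg - a.position_deg) for a, b in zip(targets, targets[1:])]


def count_large_shifts(amplitudes: list[int]) -> int:
    """Number of shifts with the analysed 75 or 80 deg target amplitude."""
    return sum(1 for a in amplitudes if a in LARGE_SHIFT_AMPLITUDES)
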