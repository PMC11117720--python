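"""Dual-threshold ON/OFF movement classification and event segmentation.

Per decision window the flexor and extensor envelope amplitudes (AVF, AVE)
are compared against per-user thresholds (TVF, TVE):

* both strictly exceeded  → co-contraction,
* only AVF > TVF          → flexion,
* only AVE > TVE          → extension,
* neither                 → rest.

"Exceeds" is a strict inequality, so amplitudes sitting exactly on a
threshold do not trigger detection.  Maximal runs of identical non-rest
labels form movement events — the unit counted in per-trial statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .signal_conditioning import EnvelopeTrace

__all__ = [
    "Movement",
    "Thresholds",
    "MovementEvent",
    "classify_window",
    "classify_trace",
    "segment_events",
    "calibrate_thresholds",
    "split_calibration_envelope",
    "CalibrationError",
    "TYPICAL_USER_THRESHOLDS",
]


class Movement(str, Enum):
    REST = "rest"
    FLEXION = "flexion"
    EXTENSION = "extension"
    COCONTRACTION = "cocontraction"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Thresholds:
    """Per-user detection thresholds in µV (flexion TVF, extension TVE)."""

    tvf: float
    tve: float

    def __post_init__(self) -> None:
        for name, v in (("tvf", self.tvf), ("tve", self.tve)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")


#: Eight representative per-user calibrations (µV), spanning the 20–100 µV
#: range typical of envelope-threshold myocontrol.  Flexion thresholds tend
#: to sit below extension thresholds.
TYPICAL_USER_THRESHOLDS: dict[int, Thresholds] = {
    1: Thresholds(20, 30),
    2: Thresholds(40, 50),
    3: Thresholds(40, 60),
    4: Thresholds(70, 60),
    5: Thresholds(60, 100),
    6: Thresholds(30, 60),
    7: Thresholds(20, 30),
    8: Thresholds(30, 50),
}


@dataclass(frozen=True)
class MovementEvent:
    """One contiguous run of a detected movement."""

    kind: Movement
    onset_s: float
    n_windows: int


def classify_window(avf: float, ave: float, thr: Thresholds) -> Movement:
    """Label one decision window from its envelope amplitudes."""
    if avf < 0 or ave < 0:
        raise ValueError(f"envelope amplitudes must be nonnegative, got ({avf}, {ave})")
    f = avf > thr.tvf
    e = ave > thr.tve
    if f and e:
        return Movement.COCONTRACTION
    if f:
        return Movement.FLEXION
    if e:
        return Movement.EXTENSION
    return Movement.REST


def classify_trace(env: EnvelopeTrace, thr: Thresholds) -> list[Movement]:
    """Apply :func:`classify_window` independently to every window."""
    if len(env) == 0:
        raise ValueError("empty envelope trace")
    return [classify_window(f, e, thr) for f, e in zip(env.avf, env.ave)]


def segment_events(
    labels: Sequence[Movement], times: Sequence[float] | None = None
) -> list[MovementEvent]:
    """Run-length encode labels into movement events; rest runs are dropped."""
    if len(labels) == 0:
        raise ValueError("empty label sequence")
    if times is None:
        times = np.arange(len(labels), dtype=float)
    events: list[MovementEvent] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            if labels[start] != Movement.REST:
                events.append(MovementEvent(labels[start], float(times[start]), i - start))
            start = i
    return events


class CalibrationError(ValueError):
    """Raised when calibration traces cannot separate activity from rest."""


def split_calibration_envelope(
    env: EnvelopeTrace, segment_s: float = 3.0, guard_s: float = 0.2
) -> tuple[EnvelopeTrace, EnvelopeTrace, EnvelopeTrace]:
    """Split a rest/flexion/rest/extension/rest calibration recording.

    Returns the (rest, flexion, extension) envelope segments, each trimmed
    by ``guard_s`` at both ends so that activation ramps at segment
    boundaries contaminate neither the rest reference nor the active
    statistics.  Segment layout matches
    :func:`myokitchen.emg_synthesis.make_calibration_script`.
    """
    if len(env) < 2:
        raise ValueError("calibration envelope too short to split")
    hop = float(np.median(np.diff(env.time)))
    per_seg = int(round(segment_s / hop))
    guard = int(round(guard_s / hop))
    if per_seg - 2 * guard < 1:
        raise ValueError("guard_s leaves no windows inside a segment")
    if len(env) < 4 * per_seg:
        raise ValueError("envelope shorter than the five-segment calibration layout")

    def seg(i: int) -> EnvelopeTrace:
        lo = i * per_seg + guard
        hi = min((i + 1) * per_seg, len(env)) - guard
        return EnvelopeTrace(env.time[lo:hi], env.avf[lo:hi], env.ave[lo:hi], env.window_s)

    return seg(0), seg(1), seg(3)


def calibrate_thresholds(
    rest_env: EnvelopeTrace,
    flexion_env: EnvelopeTrace,
    extension_env: EnvelopeTrace,
    fraction: float = 0.3,
) -> Thresholds:
    """Derive per-user thresholds from rest and sustained-contraction traces.

    Each threshold is anchored just above the channel's rest ceiling:
    ``T = rest_max + fraction * (median_active - rest_max)``, computed on
    the flexor channel of the flexion trace and the extensor channel of
    the extension trace.  The median is robust to ramp-up/ramp-down
    windows at the edges of the contraction.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    for env in (rest_env, flexion_env, extension_env):
        if len(env) == 0:
            raise ValueError("empty calibration trace")

    def one(rest_amp: np.ndarray, active_amp: np.ndarray, channel: str) -> float:
        rest_max = float(np.max(rest_amp))
        active = float(np.median(active_amp))
        if active <= rest_max:
            raise CalibrationError(
                f"{channel} calibration uninformative: active median {active:.2f} µV "
                f"does not exceed rest maximum {rest_max:.2f} µV"
            )
        return rest_max + fraction * (active - rest_max)

    return Thresholds(
        tvf=one(rest_env.avf, flexion_env.avf, "flexor"),
        tve=one(rest_env.ave, extension_env.ave, "extensor"),
    )
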