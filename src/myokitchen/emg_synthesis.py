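"""Synthetic two-channel surface EMG generation.

Raw surface EMG recorded over antagonist wrist muscles (flexor channel over
Flexor Carpi Radialis, extensor channel over Brachioradialis) is emulated as
zero-mean band-limited Gaussian noise whose instantaneous amplitude is
modulated by the user's intended gesture.  Four gestures are modelled:

* ``flexion``       — drives the flexor channel,
* ``extension``     — drives the extensor channel,
* ``cocontraction`` — drives both channels simultaneously,
* ``rest``          — baseline noise only.

The modulation is calibrated so that the *linear envelope* (mean absolute
value after smoothing, see :mod:`myokitchen.signal_conditioning`) of a
sustained gesture converges to the scripted intensity: for a Gaussian
carrier of RMS sigma the expected rectified mean is ``sigma * sqrt(2/pi)``,
so the carrier RMS is set to ``intensity * sqrt(pi/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

__all__ = [
    "GESTURES",
    "GestureEntry",
    "GestureScript",
    "SynthParams",
    "EmgTrace",
    "synthesize_trace",
    "make_calibration_script",
    "ENVELOPE_OF_RMS",
    "RMS_PER_ENVELOPE",
]

GESTURES = ("rest", "flexion", "extension", "cocontraction")

#: E|X| / sigma for zero-mean Gaussian X (folded-normal mean).
ENVELOPE_OF_RMS = math.sqrt(2.0 / math.pi)
#: Carrier RMS needed per µV of target envelope amplitude.
RMS_PER_ENVELOPE = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class GestureEntry:
    """One scripted gesture: what, for how long, how hard."""

    gesture: str
    duration_s: float
    intensity_uV: float = 0.0

    def __post_init__(self) -> None:
        if self.gesture not in GESTURES:
            raise ValueError(f"unknown gesture {self.gesture!r}; expected one of {GESTURES}")
        if not self.duration_s > 0:
            raise ValueError(f"gesture duration must be positive, got {self.duration_s}")
        if self.gesture != "rest" and self.intensity_uV < 0:
            raise ValueError(f"intensity must be nonnegative, got {self.intensity_uV}")


@dataclass(frozen=True)
class GestureScript:
    """Ordered sequence of intended gestures (an intent trace).

    Intensity is the target linear-envelope amplitude in µV; it is ignored
    for ``rest`` entries, where only baseline noise is produced.
    """

    entries: tuple[GestureEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValueError("gesture script is empty")

    @property
    def total_duration_s(self) -> float:
        return float(sum(e.duration_s for e in self.entries))

    def gesture_windows(self, hop_s: float = 0.1) -> int:
        """Total non-rest effort expressed in decision windows of ``hop_s``."""
        return int(sum(round(e.duration_s / hop_s) for e in self.entries if e.gesture != "rest"))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "gesture": [e.gesture for e in self.entries],
                "duration_s": [e.duration_s for e in self.entries],
                "intensity_uV": [e.intensity_uV for e in self.entries],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GestureScript":
        df = pd.read_csv(path)
        return cls(
            tuple(
                GestureEntry(str(r.gesture), float(r.duration_s), float(r.intensity_uV))
                for r in df.itertuples()
            )
        )

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence]) -> "GestureScript":
        """Build from ``(gesture, duration[, intensity])`` tuples."""
        entries = []
        for p in pairs:
            entries.append(GestureEntry(p[0], float(p[1]), float(p[2]) if len(p) > 2 else 0.0))
        return cls(tuple(entries))


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    Parameters
    ----------
    sampling_rate:
        Acquisition rate in Hz.  1500 Hz matches typical wireless surface
        EMG hardware.
    baseline_noise:
        RMS of the always-present baseline noise in µV.
    band:
        Passband of the carrier noise in Hz; surface EMG power lives
        roughly between 20 and 450 Hz.
    rise_time:
        Duration in seconds of the linear activation ramp between gesture
        intensities (physiological onset; avoids discontinuities).
    crosstalk:
        Fraction of each channel leaked into the other (0 disables).
    max_intensity:
        Largest representable envelope amplitude in µV; a 16-bit front end
        saturates far below millivolt-scale inputs.
    """

    sampling_rate: float = 1500.0
    baseline_noise: float = 3.0
    band: tuple[float, float] = (20.0, 450.0)
    rise_time: float = 0.1
    seed: int = 0
    crosstalk: float = 0.0
    max_intensity: float = 5000.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"invalid carrier band {self.band}")
        if self.sampling_rate <= 2 * hi:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the upper band edge {hi} Hz"
            )
        if self.baseline_noise < 0:
            raise ValueError("baseline_noise must be nonnegative")
        if self.rise_time < 0:
            raise ValueError("rise_time must be nonnegative")


@dataclass
class EmgTrace:
    """Uniformly sampled two-channel raw EMG in µV."""

    time: np.ndarray
    flexor: np.ndarray
    extensor: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flexor = np.asarray(self.flexor, dtype=float)
        self.extensor = np.asarray(self.extensor, dtype=float)
        n = self.time.size
        if self.flexor.size != n or self.extensor.size != n:
            raise ValueError("channel lengths differ from time axis")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ValueError("time axis must increase uniformly at 1/sampling_rate")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "flexor_uV": self.flexor, "extensor_uV": self.extensor}
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, sampling_rate: float | None = None) -> "EmgTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if sampling_rate is None:
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["flexor_uV"].to_numpy(), df["extensor_uV"].to_numpy(), sampling_rate)


def _activation_profiles(script: GestureScript, params: SynthParams, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample target envelope amplitude for (flexor, extensor)."""
    fs = params.sampling_rate
    flex = np.zeros(n)
    ext = np.zeros(n)
    t0 = 0.0
    for e in script.entries:
        i0 = int(round(t0 * fs))
        i1 = min(n, int(round((t0 + e.duration_s) * fs)))
        if e.gesture in ("flexion", "cocontraction"):
            flex[i0:i1] = e.intensity_uV
        if e.gesture in ("extension", "cocontraction"):
            ext[i0:i1] = e.intensity_uV
        t0 += e.duration_s
    ramp = max(1, int(round(params.rise_time * fs)))
    if ramp > 1:
        # boxcar smoothing of the piecewise-constant target = linear ramps
        flex = uniform_filter1d(flex, size=ramp, mode="nearest")
        ext = uniform_filter1d(ext, size=ramp, mode="nearest")
    return flex, ext


def _unit_rms_carrier(rng: np.random.Generator, n: int, params: SynthParams) -> np.ndarray:
    sos = signal.butter(4, params.band, btype="bandpass", fs=params.sampling_rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def synthesize_trace(script: GestureScript, params: SynthParams | None = None) -> EmgTrace:
    """Generate a raw two-channel EMG trace realizing a gesture script.

    Each channel is a single band-limited unit-RMS Gaussian carrier whose
    instantaneous amplitude is ``sqrt(baseline_rms**2 + (a(t)*sqrt(pi/2))**2)``
    with ``a(t)`` the ramped per-sample envelope target, so baseline noise
    and activation add in power.  Deterministic for a fixed seed.
    """
    params = params or SynthParams()
    for e in script.entries:
        if e.gesture != "rest" and e.intensity_uV > params.max_intensity:
            raise ValueError(
                f"intensity {e.intensity_uV} µV exceeds the representable maximum "
                f"{params.max_intensity} µV"
            )
    fs = params.sampling_rate
    n = int(round(script.total_duration_s * fs))
    if n == 0:
        raise ValueError("script duration rounds to zero samples")
    flex_a, ext_a = _activation_profiles(script, params, n)
    rng = np.random.default_rng(params.seed)
    cf = _unit_rms_carrier(rng, n, params)
    ce = _unit_rms_carrier(rng, n, params)
    sigma_f = np.hypot(params.baseline_noise, flex_a * RMS_PER_ENVELOPE)
    sigma_e = np.hypot(params.baseline_noise, ext_a * RMS_PER_ENVELOPE)
    flexor = sigma_f * cf
    extensor = sigma_e * ce
    if params.crosstalk:
        flexor, extensor = (
            flexor + params.crosstalk * extensor,
            extensor + params.crosstalk * flexor,
        )
    time = np.arange(n) / fs
    return EmgTrace(time, flexor, extensor, fs)


def make_calibration_script(mvc_intensity: float, segment_s: float = 3.0) -> GestureScript:
    """Fixed calibration sequence: rest, flexion, rest, extension, rest.

    ``mvc_intensity`` is the envelope amplitude (µV) of the user's maximal
    voluntary contraction; both active segments are held at that level.
    """
    if not mvc_intensity > 0:
        raise ValueError(f"mvc_intensity must be positive, got {mvc_intensity}")
    if not segment_s > 0:
        raise ValueError(f"segment_s must be positive, got {segment_s}")
    return GestureScript(
        (
            GestureEntry("rest", segment_s),
            GestureEntry("flexion", segment_s, mvc_intensity),
            GestureEntry("rest", segment_s),
            GestureEntry("extension", segment_s, mvc_intensity),
            GestureEntry("rest", segment_s),
        )
    )
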