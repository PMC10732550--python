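"""Stimulation protocol: trial timing for intermittent RF exposure.

A session is a sequence of non-overlapping trials; each trial is one RF-ON
epoch immediately followed by one RF-OFF epoch. All times are in seconds and
epochs are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["StimulusProtocol", "make_protocol", "am_phase", "am_envelope"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial timing and RF parameters for one stimulation session.

    Parameters
    ----------
    trial_start_times
        Start of each trial's ON epoch, seconds, strictly increasing.
    on_duration, off_duration
        Length of the RF-ON and RF-OFF epoch of every trial, seconds.
    radiated_power
        Power fed to the antenna, watts (0 for sham).
    am_frequency
        Sinusoidal amplitude-modulation frequency of the carrier envelope,
        Hz, or ``None`` for unmodulated RF.
    session_length
        Total recording span, seconds; must cover every trial.
    """

    trial_start_times: np.ndarray
    on_duration: float
    off_duration: float
    radiated_power: float
    am_frequency: float | None = None
    session_length: float = field(default=0.0)

    def __post_init__(self) -> None:
        starts = np.asarray(self.trial_start_times, dtype=float)
        object.__setattr__(self, "trial_start_times", starts)
        if starts.ndim != 1 or starts.size < 1:
            raise ValueError("protocol needs at least one trial")
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("epoch durations must be positive")
        period = self.on_duration + self.off_duration
        if np.any(np.diff(starts) < period - 1e-12):
            raise ValueError("trials overlap or are out of order")
        if self.session_length <= 0:
            object.__setattr__(self, "session_length", float(starts[-1] + period))
        if self.session_length < starts[-1] + period - 1e-9:
            raise ValueError("session_length does not cover the last trial")
        if self.am_frequency is not None and self.am_frequency <= 0:
            raise ValueError("am_frequency must be positive")

    @property
    def n_trials(self) -> int:
        return int(self.trial_start_times.size)

    def on_windows(self) -> np.ndarray:
        """(n_trials, 2) array of ON epoch [start, end) bounds."""
        s = self.trial_start_times
        return np.column_stack([s, s + self.on_duration])

    def off_windows(self) -> np.ndarray:
        """(n_trials, 2) array of OFF epoch [start, end) bounds."""
        s = self.trial_start_times + self.on_duration
        return np.column_stack([s, s + self.off_duration])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "trial_start_times": self.trial_start_times.tolist(),
            "on_duration": self.on_duration,
            "off_duration": self.off_duration,
            "radiated_power": self.radiated_power,
            "am_frequency": self.am_frequency,
            "session_length": self.session_length,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusProtocol":
        d = json.loads(Path(path).read_text())
        return cls(
            trial_start_times=np.asarray(d["trial_start_times"], dtype=float),
            on_duration=float(d["on_duration"]),
            off_duration=float(d["off_duration"]),
            radiated_power=float(d["radiated_power"]),
            am_frequency=None if d.get("am_frequency") is None else float(d["am_frequency"]),
            session_length=float(d["session_length"]),
        )


def make_protocol(
    n_trials: int,
    on_s: float,
    off_s: float,
    power_w: float,
    am_hz: float | None = None,
) -> StimulusProtocol:
    """Build a back-to-back intermittent protocol starting at t = 0.

    Trial ``k`` starts at ``k * (on_s + off_s)``; the session length is
    ``n_trials * (on_s + off_s)``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if on_s <= 0 or off_s <= 0:
        raise ValueError("epoch durations must be positive")
    period = on_s + off_s
    starts = np.arange(n_trials, dtype=float) * period
    return StimulusProtocol(
        trial_start_times=starts,
        on_duration=float(on_s),
        off_duration=float(off_s),
        radiated_power=float(power_w),
        am_frequency=None if am_hz is None else float(am_hz),
        session_length=float(n_trials * period),
    )


def am_phase(t_rel_onset: np.ndarray, am_hz: float) -> np.ndarray:
    """Envelope phase (radians in [0, 2pi)) at times relative to ON onset.

    Convention: the envelope is ``(1 + cos(phi)) / 2`` with ``phi = 0`` at the
    envelope peak; the envelope starts at its minimum at each ON onset, so
    ``phi = 2*pi*f*t - pi`` wrapped into [0, 2pi).
    """
    phi = 2.0 * np.pi * am_hz * np.asarray(t_rel_onset, dtype=float) - np.pi
    return np.mod(phi, 2.0 * np.pi)


def am_envelope(t_rel_onset: np.ndarray, am_hz: float) -> np.ndarray:
    """Amplitude-modulation envelope in [0, 1]; 0 at ON onset, 1 at phase 0."""
    return 0.5 * (1.0 + np.cos(am_phase(t_rel_onset, am_hz)))
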