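"""Core event-train containers.

A :class:`SpikeTrain` is the ordered sequence of action-potential times of a
single neuron over a known recording duration; a :class:`StimulusTrain` is the
sequence of electrical pulse onsets delivered during the recording, together
with the protocol parameters (pulse frequency, width, intensity).  All times
are seconds from the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["SpikeTrain", "StimulusTrain"]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron.

    Parameters
    ----------
    times : array-like of float
        Strictly increasing spike times in seconds, all within
        ``[0, duration_s]``.
    duration_s : float
        Length of the recording in seconds. Must be positive.
    neuron_id : str
        Label carried through analyses and output tables.
    """

    times: np.ndarray
    duration_s: float
    neuron_id: str = "neuron"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be positive, got {self.duration_s}")
        if times.ndim != 1:
            raise ValidationError("spike times must be one-dimensional")
        if times.size:
            diffs = np.diff(times)
            if np.any(diffs <= 0):
                bad = int(np.argmax(diffs <= 0)) + 1
                raise ValidationError(
                    f"spike times must be strictly increasing; violation at index {bad}",
                    row=bad,
                    column="time_s",
                )
            if times[0] < 0 or times[-1] > self.duration_s:
                raise ValidationError(
                    "spike times must lie within [0, duration_s]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        """Mean firing rate in spikes per second."""
        return self.n_spikes / self.duration_s

    @property
    def rate_per_10s(self) -> float:
        """Mean firing rate in spikes per 10 s, the unit used for slow DA cells."""
        return 10.0 * self.rate_hz

    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.times)

    def segment(self, t0: float, t1: float, neuron_id: str | None = None) -> "SpikeTrain":
        """Extract the half-open window ``[t0, t1)`` as a new train.

        Times are re-referenced to ``t0`` and the new duration is ``t1 - t0``.
        """
        if not (0 <= t0 < t1 <= self.duration_s + 1e-9):
            raise ValidationError(f"segment [{t0}, {t1}) outside recording [0, {self.duration_s}]")
        mask = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(
            times=self.times[mask] - t0,
            duration_s=t1 - t0,
            neuron_id=neuron_id or self.neuron_id,
        )

    def shifted(self, offset_s: float) -> "SpikeTrain":
        """Rigidly translate the train (and its duration window) by ``offset_s``."""
        return SpikeTrain(
            times=self.times + offset_s,
            duration_s=self.duration_s + offset_s,
            neuron_id=self.neuron_id,
        )


@dataclass(frozen=True)
class StimulusTrain:
    """Electrical stimulation pulse onsets plus protocol parameters.

    Defaults mirror the single-pulse protocol used for cortical afferent
    mapping: 50 pulses at 0.5 Hz, 0.5 ms pulse width, 0.5 or 1.0 mA.
    """

    pulse_times_s: np.ndarray
    frequency_hz: float = 0.5
    pulse_duration_ms: float = 0.5
    intensity_ma: float = 1.0

    def __post_init__(self):
        times = np.asarray(self.pulse_times_s, dtype=float)
        object.__setattr__(self, "pulse_times_s", times)
        if times.ndim != 1 or times.size == 0:
            raise ValidationError("pulse_times_s must be a non-empty 1-D array")
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0)) + 1
            raise ValidationError(
                "pulse times must be strictly increasing", row=bad, column="time_s"
            )

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times_s.size)

    @property
    def inter_pulse_interval_s(self) -> float:
        return 1.0 / self.frequency_hz

    def shifted(self, offset_s: float) -> "StimulusTrain":
        return StimulusTrain(
            pulse_times_s=self.pulse_times_s + offset_s,
            frequency_hz=self.frequency_hz,
            pulse_duration_ms=self.pulse_duration_ms,
            intensity_ma=self.intensity_ma,
        )

    @classmethod
    def regular(
        cls,
        n_pulses: int = 50,
        frequency_hz: float = 0.5,
        start_s: float = 0.0,
        pulse_duration_ms: float = 0.5,
        intensity_ma: float = 1.0,
    ) -> "StimulusTrain":
        """Evenly spaced protocol: ``n_pulses`` starting at ``start_s``."""
        times = start_s + np.arange(n_pulses) / frequency_hz
        return cls(
            pulse_times_s=times,
            frequency_hz=frequency_hz,
            pulse_duration_ms=pulse_duration_ms,
            intensity_ma=intensity_ma,
        )
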