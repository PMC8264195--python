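"""Burst detection and firing-pattern statistics for single-unit spike trains.

Midbrain dopamine (DA) neurons fire in a mixture of single spikes and
multi-spike bursts.  The classical extracellular criterion (Grace & Bunney)
opens a burst at the first of two consecutive spikes closer than 80 ms and
terminates it at the first interspike interval (ISI) longer than 160 ms.
The headline statistic is the percentage of spikes occurring in bursts
(%SIB): spikes inside detected bursts divided by all spikes, times 100.

This module also implements the electrophysiological qualification of
putative DA neurons from scalar waveform features: wide biphasic/triphasic
action potentials (> 2.5 ms), a long spike-onset-to-trough interval
(> 1.1 ms), and a slow spontaneous firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpikeTrain
from .errors import InvalidParameterError

__all__ = [
    "Burst",
    "BurstDetectorConfig",
    "BurstSummary",
    "WaveformFeatures",
    "DaQualificationConfig",
    "detect_bursts",
    "summarize_bursting",
    "qualify_da_neuron",
]


@dataclass(frozen=True)
class BurstDetectorConfig:
    """Thresholds of the two-ISI burst criterion (milliseconds).

    ``onset_isi_ms``: an ISI strictly below this opens a burst (default 80).
    ``termination_isi_ms``: an ISI strictly above this closes an open burst
    (default 160).  ISIs in between continue an open burst but never open one.
    """

    onset_isi_ms: float = 80.0
    termination_isi_ms: float = 160.0

    def __post_init__(self):
        if not (0 < self.onset_isi_ms <= self.termination_isi_ms):
            raise InvalidParameterError(
                "require termination_isi_ms >= onset_isi_ms > 0, got "
                f"{self.onset_isi_ms}/{self.termination_isi_ms}"
            )


@dataclass(frozen=True)
class Burst:
    """One detected burst: spikes ``start_index .. start_index+n_spikes-1``."""

    start_index: int
    n_spikes: int
    start_time_s: float
    end_time_s: float

    def __post_init__(self):
        if self.n_spikes < 2:
            raise InvalidParameterError("a burst has at least 2 spikes")


@dataclass(frozen=True)
class BurstSummary:
    """Firing-pattern statistics of one train.

    ``pct_sib`` is the percent of spikes in bursts; ``firing_rate_per_10s``
    uses the spikes-per-10-s convention common for slow DA cells.
    ``mean_spikes_per_burst`` is ``nan`` (and ``no_bursts`` True) when no
    burst was detected; ``empty_train`` flags a train without spikes.
    """

    firing_rate_per_10s: float
    firing_rate_hz: float
    pct_sib: float
    mean_spikes_per_burst: float
    n_bursts: int
    n_spikes: int
    n_spikes_in_bursts: int
    empty_train: bool = False

    @property
    def no_bursts(self) -> bool:
        return self.n_bursts == 0


def detect_bursts(train: SpikeTrain, config: BurstDetectorConfig | None = None) -> list[Burst]:
    """Detect bursts with the two-threshold ISI criterion.

    A burst opens at the first of two spikes with ISI < ``onset_isi_ms``
    while no burst is open, absorbs subsequent spikes until an ISI
    > ``termination_isi_ms`` occurs (the second spike of that ISI is outside
    the burst), and a burst still open at the end of the train closes at the
    last spike.  Boundaries are strict: an ISI exactly at the onset threshold
    does not open a burst and one exactly at the termination threshold does
    not close it.

    Returns bursts in temporal order; they never overlap.
    """
    config = config or BurstDetectorConfig()
    times = train.times
    n = times.size
    if n < 2:
        return []
    isi_ms = np.diff(times) * 1000.0
    onset = config.onset_isi_ms
    term = config.termination_isi_ms

    bursts: list[Burst] = []
    i = 0
    while i < n - 1:
        if isi_ms[i] < onset:
            j = i + 1
            while j < n - 1 and isi_ms[j] <= term:
                j += 1
            bursts.append(
                Burst(
                    start_index=i,
                    n_spikes=j - i + 1,
                    start_time_s=float(times[i]),
                    end_time_s=float(times[j]),
                )
            )
            i = j + 1
        else:
            i += 1
    return bursts


def summarize_bursting(train: SpikeTrain, bursts: list[Burst]) -> BurstSummary:
    """Aggregate burst statistics for one train.

    ``pct_sib = 100 * (sum of burst sizes) / (total spikes)``; an empty train
    reports 0 with the ``empty_train`` flag set rather than raising.
    """
    total = train.n_spikes
    in_bursts = sum(b.n_spikes for b in bursts)
    n_bursts = len(bursts)
    return BurstSummary(
        firing_rate_per_10s=train.rate_per_10s,
        firing_rate_hz=train.rate_hz,
        pct_sib=100.0 * in_bursts / total if total else 0.0,
        mean_spikes_per_burst=in_bursts / n_bursts if n_bursts else float("nan"),
        n_bursts=n_bursts,
        n_spikes=total,
        n_spikes_in_bursts=in_bursts,
        empty_train=total == 0,
    )


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar waveform features of one recorded unit."""

    ap_duration_ms: float
    onset_to_trough_ms: float
    waveform_class: str  # "biphasic" | "triphasic" | "other"
    spontaneous_rate_sps: float

    def __post_init__(self):
        if self.ap_duration_ms <= 0 or self.onset_to_trough_ms <= 0:
            raise InvalidParameterError("waveform durations must be positive")


@dataclass(frozen=True)
class DaQualificationConfig:
    """Thresholds for putative-DA-neuron qualification.

    All waveform comparisons are strict (a 2.5 ms spike does not qualify).
    The published rate criterion text is internally inconsistent ("slow"
    firing printed with a greater-than sign); the default here is the
    standard slow criterion, rate strictly below ``rate_threshold_sps``,
    with the direction configurable.
    """

    min_ap_duration_ms: float = 2.5
    min_onset_to_trough_ms: float = 1.1
    rate_threshold_sps: float = 10.0
    rate_direction: str = "below"  # "below" (slow cells) or "above"
    allowed_classes: tuple[str, ...] = ("biphasic", "triphasic")


def qualify_da_neuron(
    features: WaveformFeatures, config: DaQualificationConfig | None = None
) -> tuple[bool, dict[str, bool]]:
    """Apply the four DA-neuron criteria; returns (qualifies, per-criterion report)."""
    config = config or DaQualificationConfig()
    if config.rate_direction not in ("below", "above"):
        raise InvalidParameterError(f"rate_direction must be 'below' or 'above', got {config.rate_direction!r}")
    if config.rate_direction == "below":
        rate_ok = features.spontaneous_rate_sps < config.rate_threshold_sps
    else:
        rate_ok = features.spontaneous_rate_sps > config.rate_threshold_sps
    report = {
        "waveform_class": features.waveform_class in config.allowed_classes,
        "ap_duration": features.ap_duration_ms > config.min_ap_duration_ms,
        "onset_to_trough": features.onset_to_trough_ms > config.min_onset_to_trough_ms,
        "firing_rate": rate_ok,
    }
    return all(report.values()), report
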