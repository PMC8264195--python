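"""Peri-stimulus time histograms and evoked-response classification.

During afferent-mapping experiments, single pulses are delivered to the
ventromedial prefrontal cortex while a ventral tegmental area unit is
recorded; the cumulative PSTH across all pulses (5 ms bins, 500 ms of
baseline before each pulse) is the basis for classifying the unit's evoked
response into one of four archetypes: short-latency excitation,
long-latency excitation, inhibition, or no response.

Epoch rules
-----------
Baseline mean and sample SD are computed across the 100 pre-stimulus bins.
An excitation epoch starts at the first post-stimulus bin that leads a
sustained threshold crossing: the 5-bin window starting there has mean count
above ``baseline mean + 2 SD`` and its first two bins each exceed that
threshold individually (the leading-edge anchor keeps the reported onset at
the front of the elevated activity instead of up to four bins early when a
sliding window first overlaps it).  The epoch ends at the first later bin
whose 5-bin running mean has returned within 2 SD of baseline.

An inhibition epoch is the earliest stretch of at least 15 consecutive bins
whose mean count per bin is at least 35% below the baseline mean and whose
first and last bins are themselves below that threshold (the edge anchor
stops the epoch from absorbing leading or trailing baseline bins).

Both detectors only start epochs within a configurable onset-latency window
(default 150 ms) — evoked responses are stimulus-locked, and an unrestricted
search across all post-stimulus bins inflates the false-detection rate of
the 35%/15-bin inhibition rule on flat PSTHs.

Response magnitude (Rmag) is the excess (excitation) or deficit (inhibition)
of counts in the epoch relative to the baseline expectation, optionally
normalized by the baseline mean count per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bursting import BurstDetectorConfig, detect_bursts, summarize_bursting
from .core import SpikeTrain, StimulusTrain
from .errors import DegenerateDataError, InvalidParameterError, ValidationError
from . import stats as _stats

__all__ = [
    "PsthConfig",
    "PSTH",
    "BaselineStats",
    "ResponseEpoch",
    "ResponseClass",
    "EpochDetectionConfig",
    "ClassificationConfig",
    "RESPONSE_LABELS",
    "build_psth",
    "baseline_stats",
    "detect_excitation",
    "detect_inhibition",
    "compute_rmag",
    "classify_response",
    "classify_train",
    "sib_stimulation_contrast",
]

RESPONSE_LABELS = (
    "short_latency_excitation",
    "long_latency_excitation",
    "inhibition",
    "no_response",
)


@dataclass(frozen=True)
class PsthConfig:
    """PSTH geometry: 5 ms bins, 500 ms pre- and post-stimulus windows."""

    bin_width_ms: float = 5.0
    pre_window_ms: float = 500.0
    post_window_ms: float = 500.0

    def __post_init__(self):
        for name in ("bin_width_ms", "pre_window_ms", "post_window_ms"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("pre_window_ms", "post_window_ms"):
            ratio = getattr(self, name) / self.bin_width_ms
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidParameterError(f"{name} must be a multiple of bin_width_ms")


@dataclass(frozen=True)
class PSTH:
    """Cumulative counts per bin across trials.

    ``counts`` covers the whole peri-stimulus window; the first
    ``n_baseline_bins`` entries are the pre-stimulus (baseline) bins, the
    remainder the post-stimulus bins.  Bins are half-open ``[t, t + width)``
    relative to pulse onset.
    """

    counts: np.ndarray
    n_baseline_bins: int
    bin_width_ms: float
    n_trials: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if np.any(counts < 0):
            raise ValidationError("PSTH counts must be non-negative")

    @property
    def baseline_counts(self) -> np.ndarray:
        return self.counts[: self.n_baseline_bins]

    @property
    def post_counts(self) -> np.ndarray:
        return self.counts[self.n_baseline_bins :]

    @property
    def n_post_bins(self) -> int:
        return self.counts.size - self.n_baseline_bins


@dataclass(frozen=True)
class BaselineStats:
    """Mean and sample SD (ddof=1) of counts across the baseline bins."""

    mean_per_bin: float
    sd_per_bin: float

    @property
    def degenerate(self) -> bool:
        return self.sd_per_bin == 0 or self.mean_per_bin == 0


@dataclass(frozen=True)
class ResponseEpoch:
    """A detected excitation or inhibition epoch, bins half-open [onset, offset)."""

    kind: str  # "excitation" | "inhibition"
    onset_bin: int
    offset_bin: int
    onset_latency_ms: float
    rmag_raw: float = float("nan")
    rmag_norm: float = float("nan")

    def __post_init__(self):
        if self.offset_bin <= self.onset_bin:
            raise InvalidParameterError("epoch offset must exceed onset")

    @property
    def n_bins(self) -> int:
        return self.offset_bin - self.onset_bin


@dataclass(frozen=True)
class ResponseClass:
    """4-way label plus every epoch retained for reporting."""

    label: str
    epochs: tuple[ResponseEpoch, ...] = ()


@dataclass(frozen=True)
class EpochDetectionConfig:
    """Thresholds of the epoch detectors.

    ``sd_multiplier`` — excitation threshold above baseline, in baseline SDs.
    ``excitation_window_bins`` — length of the sustained-crossing window.
    ``excitation_anchor_bins`` — leading bins that must each exceed threshold.
    ``inhibition_depth`` — fractional suppression below baseline (0.35 = 35%).
    ``inhibition_min_bins`` — minimum inhibition epoch length.
    ``max_onset_ms`` — epochs must start within this post-pulse latency.
    ``allow_degenerate_baseline`` — permit sd = 0 baselines (threshold
    collapses to the mean) instead of raising.
    """

    sd_multiplier: float = 2.0
    excitation_window_bins: int = 5
    excitation_anchor_bins: int = 2
    inhibition_depth: float = 0.35
    inhibition_min_bins: int = 15
    max_onset_ms: float = 150.0
    allow_degenerate_baseline: bool = False


@dataclass(frozen=True)
class ClassificationConfig:
    """Latency boundary separating short- from long-latency excitation."""

    short_latency_max_ms: float = 20.0


def build_psth(
    train: SpikeTrain, stim: StimulusTrain, config: PsthConfig | None = None
) -> PSTH:
    """Cumulative PSTH of ``train`` around every pulse of ``stim``.

    Every pulse window must lie within the recording and windows must not
    overlap (a configuration error otherwise).
    """
    config = config or PsthConfig()
    pre = config.pre_window_ms / 1000.0
    post = config.post_window_ms / 1000.0
    width = config.bin_width_ms / 1000.0
    pulses = stim.pulse_times_s
    if pulses.size > 1 and np.any(np.diff(pulses) < pre + post - 1e-12):
        raise InvalidParameterError(
            "trial windows overlap: inter-pulse interval shorter than pre + post windows"
        )
    if pulses[0] - pre < -1e-12 or pulses[-1] + post > train.duration_s + 1e-12:
        raise InvalidParameterError("pulse windows extend outside the recording")

    n_pre = round(config.pre_window_ms / config.bin_width_ms)
    n_post = round(config.post_window_ms / config.bin_width_ms)
    edges = (np.arange(n_pre + n_post + 1) - n_pre) * width
    counts = np.zeros(n_pre + n_post, dtype=int)
    for pulse in pulses:
        # np.histogram closes the last bin; an extra guard bin keeps every
        # analysis bin half-open [t, t + width).
        hist, _ = np.histogram(train.times - pulse, bins=np.append(edges, edges[-1] + width))
        counts += hist[:-1]
    return PSTH(
        counts=counts,
        n_baseline_bins=n_pre,
        bin_width_ms=config.bin_width_ms,
        n_trials=stim.n_pulses,
    )


def baseline_stats(psth: PSTH) -> BaselineStats:
    """Mean and sample SD of the cumulative counts across baseline bins."""
    base = psth.baseline_counts
    if base.size < 2:
        raise DegenerateDataError("need at least 2 baseline bins")
    return BaselineStats(
        mean_per_bin=float(np.mean(base)),
        sd_per_bin=float(np.std(base, ddof=1)),
    )


def _excitation_threshold(baseline: BaselineStats, config: EpochDetectionConfig) -> float:
    if baseline.sd_per_bin == 0 and not config.allow_degenerate_baseline:
        raise DegenerateDataError(
            "baseline SD is zero; set allow_degenerate_baseline to proceed"
        )
    return baseline.mean_per_bin + config.sd_multiplier * baseline.sd_per_bin


def detect_excitation(
    psth: PSTH,
    baseline: BaselineStats,
    config: EpochDetectionConfig | None = None,
) -> ResponseEpoch | None:
    """Find the earliest excitation epoch, or ``None``.

    Onset: first post-stimulus bin leading a sustained crossing (window mean
    and the first ``excitation_anchor_bins`` bins all above
    ``mean + sd_multiplier * SD``), searched up to ``max_onset_ms``.
    Offset (exclusive): first later bin whose running window mean is back
    within threshold; the epoch runs to the end of the analysis window if
    activity never returns.
    """
    config = config or EpochDetectionConfig()
    thr = _excitation_threshold(baseline, config)
    p = psth.post_counts.astype(float)
    w = config.excitation_window_bins
    n = p.size
    if n < w:
        return None
    max_onset_bin = int(config.max_onset_ms / psth.bin_width_ms)
    window_means = np.convolve(p, np.ones(w) / w, mode="valid")  # index b -> mean p[b:b+w]

    onset = None
    for b in range(min(n - w, max_onset_bin) + 1):
        if b > n - w:
            break
        anchor = p[b : b + config.excitation_anchor_bins]
        if np.all(anchor > thr) and window_means[b] > thr:
            onset = b
            break
    if onset is None:
        return None

    offset = n
    for c in range(onset + 1, n):
        mean_c = window_means[c] if c <= n - w else float(np.mean(p[c:]))
        if mean_c <= thr:
            offset = c
            break
    return ResponseEpoch(
        kind="excitation",
        onset_bin=onset,
        offset_bin=offset,
        onset_latency_ms=onset * psth.bin_width_ms,
    )


def detect_inhibition(
    psth: PSTH,
    baseline: BaselineStats,
    config: EpochDetectionConfig | None = None,
) -> ResponseEpoch | None:
    """Find the earliest inhibition epoch, or ``None``.

    The epoch is the earliest, then longest, stretch of at least
    ``inhibition_min_bins`` consecutive post-stimulus bins whose mean count
    is at least ``inhibition_depth`` below the baseline mean, with the first
    and last bins themselves below that suppression threshold; onsets are
    searched up to ``max_onset_ms``.
    """
    config = config or EpochDetectionConfig()
    if baseline.mean_per_bin == 0:
        raise DegenerateDataError("baseline mean is zero; inhibition depth undefined")
    thr = (1.0 - config.inhibition_depth) * baseline.mean_per_bin
    p = psth.post_counts.astype(float)
    n = p.size
    min_bins = config.inhibition_min_bins
    max_onset_bin = int(config.max_onset_ms / psth.bin_width_ms)

    csum = np.concatenate([[0.0], np.cumsum(p)])
    for s in range(min(n - min_bins, max_onset_bin) + 1):
        if p[s] > thr:
            continue
        best_e = -1
        for e in range(s + min_bins - 1, n):
            if p[e] > thr:
                continue
            if (csum[e + 1] - csum[s]) / (e + 1 - s) <= thr:
                best_e = e
        if best_e >= 0:
            return ResponseEpoch(
                kind="inhibition",
                onset_bin=s,
                offset_bin=best_e + 1,
                onset_latency_ms=s * psth.bin_width_ms,
            )
    return None


def compute_rmag(
    psth: PSTH, epoch: ResponseEpoch, baseline: BaselineStats
) -> tuple[float, float]:
    """Response magnitude of a detected epoch.

    ``rmag_raw`` = observed epoch counts minus the baseline expectation
    (negative for inhibition); ``rmag_norm`` divides by the baseline mean
    count per bin and is ``nan`` (flagged undefined) for a silent baseline.
    """
    counts = psth.post_counts[epoch.onset_bin : epoch.offset_bin]
    raw = float(np.sum(counts) - baseline.mean_per_bin * epoch.n_bins)
    if baseline.mean_per_bin == 0:
        return raw, float("nan")
    return raw, raw / baseline.mean_per_bin


def _with_rmag(psth: PSTH, epoch: ResponseEpoch, baseline: BaselineStats) -> ResponseEpoch:
    raw, norm = compute_rmag(psth, epoch, baseline)
    return ResponseEpoch(
        kind=epoch.kind,
        onset_bin=epoch.onset_bin,
        offset_bin=epoch.offset_bin,
        onset_latency_ms=epoch.onset_latency_ms,
        rmag_raw=raw,
        rmag_norm=norm,
    )


def classify_response(
    excitation: ResponseEpoch | None,
    inhibition: ResponseEpoch | None,
    config: ClassificationConfig | None = None,
) -> ResponseClass:
    """4-way label from the detected epochs.

    No epoch: ``no_response``.  Excitation is split at the short/long
    latency boundary.  When both kinds are present the label follows the
    epoch with the earliest onset (tie goes to excitation); every epoch is
    retained on the result.
    """
    config = config or ClassificationConfig()
    epochs = tuple(e for e in (excitation, inhibition) if e is not None)
    if not epochs:
        return ResponseClass(label="no_response")
    if excitation is not None and (
        inhibition is None or excitation.onset_bin <= inhibition.onset_bin
    ):
        if excitation.onset_latency_ms <= config.short_latency_max_ms:
            label = "short_latency_excitation"
        else:
            label = "long_latency_excitation"
    else:
        label = "inhibition"
    return ResponseClass(label=label, epochs=epochs)


def classify_train(
    train: SpikeTrain,
    stim: StimulusTrain,
    psth_config: PsthConfig | None = None,
    detection_config: EpochDetectionConfig | None = None,
    classification_config: ClassificationConfig | None = None,
) -> tuple[ResponseClass, PSTH, BaselineStats]:
    """Full per-neuron pipeline: PSTH -> baseline -> epochs -> label."""
    psth = build_psth(train, stim, psth_config)
    base = baseline_stats(psth)
    det = detection_config or EpochDetectionConfig()
    if base.mean_per_bin == 0:
        # A silent baseline supports no epoch statistics at all.
        return ResponseClass(label="no_response"), psth, base
    exc = detect_excitation(psth, base, det)
    inh = detect_inhibition(psth, base, det)
    if exc is not None:
        exc = _with_rmag(psth, exc, base)
    if inh is not None:
        inh = _with_rmag(psth, inh, base)
    return classify_response(exc, inh, classification_config), psth, base


def sib_stimulation_contrast(
    neurons: list[tuple[SpikeTrain, StimulusTrain]],
    burst_config: BurstDetectorConfig | None = None,
    baseline_min_s: float = 300.0,
) -> tuple[pd.DataFrame, "_stats.TestResult | None"]:
    """%SIB before vs during stimulation, with a paired t-test across neurons.

    The baseline segment is the recording before the first pulse (required
    to be at least ``baseline_min_s``, matching the minimum 5 min of
    spontaneous activity recorded per cell); the stimulation segment spans
    the pulse train plus one inter-pulse interval after the last pulse.
    The paired test is only computed with at least two neurons.
    """
    rows = []
    for train, stim in neurons:
        first = float(stim.pulse_times_s[0])
        if first < baseline_min_s:
            raise ValidationError(
                f"neuron {train.neuron_id!r}: only {first:.1f} s of baseline before the "
                f"first pulse; need >= {baseline_min_s:.0f} s"
            )
        stim_end = min(
            float(stim.pulse_times_s[-1]) + stim.inter_pulse_interval_s, train.duration_s
        )
        base_seg = train.segment(0.0, first)
        stim_seg = train.segment(first, stim_end)
        base_sum = summarize_bursting(base_seg, detect_bursts(base_seg, burst_config))
        stim_sum = summarize_bursting(stim_seg, detect_bursts(stim_seg, burst_config))
        rows.append(
            {
                "neuron_id": train.neuron_id,
                "baseline_pct_sib": base_sum.pct_sib,
                "stimulation_pct_sib": stim_sum.pct_sib,
                "baseline_rate_per_10s": base_sum.firing_rate_per_10s,
                "stimulation_rate_per_10s": stim_sum.firing_rate_per_10s,
            }
        )
    table = pd.DataFrame(rows)
    test = None
    if len(table) >= 2:
        test = _stats.paired_t(
            table["baseline_pct_sib"].to_numpy(), table["stimulation_pct_sib"].to_numpy()
        )
    return table, test
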