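"""Synthetic spike trains, evoked responses, trajectories, and group tables.

Every analysis stage in this package is testable without recordings because
each generator has a known ground truth:

* **Burst trains** come from an alternating renewal process: each event is,
  with probability ``q``, a burst (length 2 + geometric, mean
  ``burst_len_mean``) of spikes separated by 50-70 ms, otherwise a single
  spike; events are separated by gaps of at least 200 ms.  Because every
  within-burst interval is below the 80 ms burst-onset threshold and every
  gap is above the 160 ms termination threshold, the detector recovers the
  generated bursts exactly, and the generative percent of spikes in bursts
  has the closed form ``100 * q*E[L] / (q*E[L] + (1-q))``.
* **Evoked neurons** superimpose stimulus-locked rate modulation on a
  baseline burst train: excitation adds Poisson spikes at
  ``(gain - 1) * baseline rate`` inside the response epoch after each pulse;
  inhibition thins baseline spikes inside the epoch.  Four archetypes mirror
  the response taxonomy (short-/long-latency excitation, inhibition, no
  response).
* **Trajectories** are discrete-time biased random walks reflected at the
  arena walls; the drift toward (or away from) the target zone is scaled by
  ``center_bias``, so expected zone occupancy is monotone in the bias.
* **Group tables** draw per-subject metric values from per-group normal
  distributions (4 groups x n = 8 by default).

All generators take explicit integer seeds and never touch global random
state; identical seed + parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import ArenaGeometry, Trajectory, ELEVATED_PLUS_MAZE, OPEN_FIELD
from .core import SpikeTrain, StimulusTrain
from .errors import InvalidParameterError

__all__ = [
    "BurstTrainParams",
    "EvokedResponseParams",
    "TrajectoryParams",
    "GroupTableParams",
    "ARCHETYPES",
    "simulate_burst_train",
    "simulate_evoked_neuron",
    "simulate_population",
    "simulate_waveform_features",
    "simulate_trajectory",
    "simulate_group_table",
    "simulate_sib_experiment",
    "strong_baseline_params",
]

ARCHETYPES = (
    "short_latency_excitation",
    "long_latency_excitation",
    "inhibition",
    "no_response",
)

_MS = 1e-3


@dataclass(frozen=True)
class BurstTrainParams:
    """Parameters of the burst-renewal spike-train generator.

    ``event_rate_hz`` is the rate of *events* (bursts or single spikes);
    the expected spike rate is ``event_rate_hz * (q*E[L] + (1-q))``.
    ``intra_burst_isi_ms`` must stay below the 80 ms burst-onset threshold
    and ``inter_event_gap_ms`` above the 160 ms termination threshold so
    that generated bursts are unambiguous to the detector.
    """

    duration_s: float
    event_rate_hz: float
    burst_prob_q: float
    burst_len_mean: float = 3.0
    intra_burst_isi_ms: tuple[float, float] = (50.0, 70.0)
    inter_event_gap_ms: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.event_rate_hz <= 0:
            raise InvalidParameterError("duration_s and event_rate_hz must be positive")
        if not (0.0 <= self.burst_prob_q <= 1.0):
            raise InvalidParameterError("burst_prob_q must be in [0, 1]")
        if self.burst_len_mean < 2.0:
            raise InvalidParameterError("burst_len_mean must be >= 2 (a burst has >= 2 spikes)")
        lo, hi = self.intra_burst_isi_ms
        if not (0 < lo <= hi):
            raise InvalidParameterError("intra_burst_isi_ms must be an increasing positive range")
        if hi >= 80.0:
            raise InvalidParameterError(
                "intra-burst ISIs must stay below the 80 ms burst-onset threshold"
            )
        if self.inter_event_gap_ms <= 160.0:
            raise InvalidParameterError(
                "inter-event gap must exceed the 160 ms burst-termination threshold"
            )
        if self.mean_gap_excess_s <= 0:
            raise InvalidParameterError(
                "event_rate_hz too high for the requested burst structure: the mean "
                "inter-event gap would fall below its minimum"
            )

    # -- closed-form ground truth ------------------------------------------
    @property
    def expected_spikes_per_event(self) -> float:
        q, m = self.burst_prob_q, self.burst_len_mean
        return q * m + (1.0 - q)

    @property
    def generative_pct_sib(self) -> float:
        """Expected percent of spikes in bursts, in percent."""
        q, m = self.burst_prob_q, self.burst_len_mean
        return 100.0 * q * m / self.expected_spikes_per_event

    @property
    def expected_spike_rate_hz(self) -> float:
        return self.event_rate_hz * self.expected_spikes_per_event

    @property
    def mean_intra_isi_s(self) -> float:
        lo, hi = self.intra_burst_isi_ms
        return (lo + hi) / 2.0 * _MS

    @property
    def mean_gap_excess_s(self) -> float:
        """Mean of the exponential part of the inter-event gap."""
        span = self.burst_prob_q * (self.burst_len_mean - 1.0) * self.mean_intra_isi_s
        return 1.0 / self.event_rate_hz - span - self.inter_event_gap_ms * _MS

    @classmethod
    def from_firing_targets(
        cls,
        pct_sib: float,
        spikes_per_burst: float,
        rate_per_10s: float,
        duration_s: float = 300.0,
        seed: int = 0,
        **kwargs,
    ) -> "BurstTrainParams":
        """Solve (q, event rate) so the generative %SIB, mean burst length and
        spike rate equal the given targets (%, spikes, spikes per 10 s)."""
        sib = pct_sib / 100.0
        if not (0 < sib < 1):
            raise InvalidParameterError("pct_sib must be strictly between 0 and 100")
        m = spikes_per_burst
        q = sib / (m * (1.0 - sib) + sib)
        rate_hz = rate_per_10s / 10.0
        event_rate = rate_hz / (q * m + (1.0 - q))
        return cls(
            duration_s=duration_s,
            event_rate_hz=event_rate,
            burst_prob_q=q,
            burst_len_mean=m,
            seed=seed,
            **kwargs,
        )


def _draw_burst_length(rng: np.random.Generator, mean: float) -> int:
    if mean <= 2.0:
        return 2
    return 1 + int(rng.geometric(1.0 / (mean - 1.0)))


def simulate_burst_train(params: BurstTrainParams, neuron_id: str = "sim") -> SpikeTrain:
    """Draw one spike train from the burst-renewal process."""
    rng = np.random.default_rng(params.seed)
    lo, hi = (v * _MS for v in params.intra_burst_isi_ms)
    min_gap = params.inter_event_gap_ms * _MS
    scale = params.mean_gap_excess_s

    times: list[float] = []
    t = min_gap + rng.exponential(scale)
    while t < params.duration_s:
        n_spikes = (
            _draw_burst_length(rng, params.burst_len_mean)
            if rng.random() < params.burst_prob_q
            else 1
        )
        times.append(t)
        for _ in range(n_spikes - 1):
            t += rng.uniform(lo, hi)
            if t >= params.duration_s:
                break
            times.append(t)
        t = times[-1] + min_gap + rng.exponential(scale)
    return SpikeTrain(np.asarray(times), duration_s=params.duration_s, neuron_id=neuron_id)


@dataclass(frozen=True)
class EvokedResponseParams:
    """Stimulus-locked modulation of a baseline train.

    ``archetype`` fixes the qualitative response; the quantitative fields
    give the epoch position (``onset_latency_ms``), its length
    (``epoch_duration_ms``), and its strength (``excitation_gain`` as a
    multiplicative rate increase, ``inhibition_fraction`` as the fraction of
    baseline spikes removed; at least 0.35 for a detectable inhibition).
    """

    archetype: str
    baseline: BurstTrainParams
    onset_latency_ms: float = 5.0
    epoch_duration_ms: float = 75.0
    excitation_gain: float = 5.0
    inhibition_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise InvalidParameterError(f"unknown archetype {self.archetype!r}")
        if self.onset_latency_ms < 0 or self.epoch_duration_ms <= 0:
            raise InvalidParameterError("epoch position must be non-negative, duration positive")
        if self.archetype == "no_response":
            if self.excitation_gain != 1.0 or self.inhibition_fraction != 0.0:
                raise InvalidParameterError(
                    "no_response requires excitation_gain = 1 and inhibition_fraction = 0"
                )
        if self.archetype in ("short_latency_excitation", "long_latency_excitation"):
            if self.excitation_gain <= 1.0:
                raise InvalidParameterError("excitation requires excitation_gain > 1")
        if self.archetype == "inhibition" and not (0.0 < self.inhibition_fraction <= 1.0):
            raise InvalidParameterError("inhibition_fraction must be in (0, 1]")


def simulate_evoked_neuron(
    params: EvokedResponseParams, stim: StimulusTrain, neuron_id: str = "sim"
) -> SpikeTrain:
    """Baseline train plus per-pulse response epochs.

    Outside the epochs the baseline process is untouched.  The epoch must
    fit inside the inter-pulse interval.
    """
    ipi_ms = stim.inter_pulse_interval_s / _MS
    if params.onset_latency_ms + params.epoch_duration_ms > ipi_ms:
        raise InvalidParameterError(
            "response epoch extends past the inter-pulse interval "
            f"({params.onset_latency_ms} + {params.epoch_duration_ms} > {ipi_ms} ms)"
        )
    duration = float(stim.pulse_times_s[-1]) + stim.inter_pulse_interval_s
    base_params = replace(
        params.baseline, duration_s=max(params.baseline.duration_s, duration), seed=params.seed
    )
    base = simulate_burst_train(base_params, neuron_id=neuron_id)
    rng = np.random.default_rng((params.seed, 0x5EED))

    onset = params.onset_latency_ms * _MS
    dur = params.epoch_duration_ms * _MS
    starts = stim.pulse_times_s + onset
    times = base.times

    if params.archetype == "inhibition" and params.inhibition_fraction > 0:
        keep = np.ones(times.size, dtype=bool)
        for s in starts:
            in_epoch = (times >= s) & (times < s + dur)
            drop = in_epoch & (rng.random(times.size) < params.inhibition_fraction)
            keep &= ~drop
        times = times[keep]
    elif params.archetype in ("short_latency_excitation", "long_latency_excitation"):
        extra_rate = (params.excitation_gain - 1.0) * params.baseline.expected_spike_rate_hz
        extras = []
        for s in starts:
            n = rng.poisson(extra_rate * dur)
            if n:
                extras.append(rng.uniform(s, s + dur, size=n))
        if extras:
            times = np.concatenate([times, *extras])
    times = np.unique(times)
    times = times[(times >= 0) & (times <= base_params.duration_s)]
    return SpikeTrain(times, duration_s=base_params.duration_s, neuron_id=neuron_id)


def strong_baseline_params(duration_s: float = 110.0, seed: int = 0) -> BurstTrainParams:
    """Default baseline for evoked-response work: a strongly bursty train of
    ~12.4 spikes/s, the upper range the renewal generator supports.

    With 50 trials and 5 ms bins this yields ~3.1 baseline counts per bin,
    enough for the 2 SD excitation rule and the 35%-below-baseline
    inhibition rule to operate away from their small-count noise floor.
    """
    return BurstTrainParams(
        duration_s=duration_s,
        event_rate_hz=1.7,
        burst_prob_q=0.9,
        burst_len_mean=8.0,
        seed=seed,
    )


_LONG_LATENCY_GRID_MS = np.arange(25.0, 55.0, 5.0)


def _archetype_params(
    archetype: str,
    baseline: BurstTrainParams,
    rng: np.random.Generator,
    seed: int,
    excitation_gain: float,
    inhibition_fraction: float,
    short_onset_ms: float,
) -> EvokedResponseParams:
    common = dict(baseline=baseline, seed=seed)
    if archetype == "short_latency_excitation":
        return EvokedResponseParams(
            archetype=archetype, onset_latency_ms=short_onset_ms, epoch_duration_ms=75.0,
            excitation_gain=excitation_gain, **common,
        )
    if archetype == "long_latency_excitation":
        onset = float(rng.choice(_LONG_LATENCY_GRID_MS))
        return EvokedResponseParams(
            archetype=archetype, onset_latency_ms=onset, epoch_duration_ms=75.0,
            excitation_gain=excitation_gain, **common,
        )
    if archetype == "inhibition":
        return EvokedResponseParams(
            archetype=archetype, onset_latency_ms=10.0, epoch_duration_ms=150.0,
            inhibition_fraction=inhibition_fraction, **common,
        )
    return EvokedResponseParams(
        archetype="no_response", excitation_gain=1.0, inhibition_fraction=0.0, **common
    )


def simulate_population(
    composition: dict[str, int] | tuple[int, int, int, int],
    baseline: BurstTrainParams | None = None,
    seed: int = 0,
    excitation_gain: float = 5.0,
    inhibition_fraction: float = 0.8,
    short_onset_ms: float = 5.0,
    n_pulses: int = 50,
    frequency_hz: float = 0.5,
    lead_in_s: float = 5.0,
) -> list[dict]:
    """Simulate a recorded population with per-neuron ground-truth labels.

    ``composition`` gives neuron counts per archetype, either as a mapping
    or as a tuple in ``ARCHETYPES`` order (long- and short-latency
    excitation, inhibition, no response counts such as the published
    7/24/20/4 of 55).  Returns one record per neuron:
    ``{"train", "stim", "true_label", "params"}``.
    """
    if not isinstance(composition, dict):
        if len(composition) != len(ARCHETYPES):
            raise InvalidParameterError(f"composition tuple must have {len(ARCHETYPES)} entries")
        composition = dict(zip(ARCHETYPES, composition))
    unknown = set(composition) - set(ARCHETYPES)
    if unknown:
        raise InvalidParameterError(f"unknown archetypes: {sorted(unknown)}")
    if any(int(v) != v or v < 0 for v in composition.values()):
        raise InvalidParameterError("composition counts must be non-negative integers")

    baseline = baseline or strong_baseline_params()
    rng = np.random.default_rng((seed, 0xA11))
    seeds = np.random.SeedSequence(seed).generate_state(sum(int(v) for v in composition.values()))
    stim = StimulusTrain.regular(n_pulses=n_pulses, frequency_hz=frequency_hz, start_s=lead_in_s)

    records = []
    idx = 0
    for archetype in ARCHETYPES:
        for _ in range(int(composition.get(archetype, 0))):
            child_seed = int(seeds[idx]) % (2**31)
            params = _archetype_params(
                archetype, baseline, rng, child_seed,
                excitation_gain, inhibition_fraction, short_onset_ms,
            )
            train = simulate_evoked_neuron(params, stim, neuron_id=f"n{idx:03d}")
            records.append(
                {"train": train, "stim": stim, "true_label": archetype, "params": params}
            )
            idx += 1
    return records


def simulate_waveform_features(cell_class: str, n: int, seed: int = 0) -> pd.DataFrame:
    """Scalar waveform-feature table for ``n`` units of one cell class.

    ``DA`` rows satisfy all qualification criteria by construction (wide
    bi-/triphasic spikes, onset-to-trough within the observed 1.1-2.7 ms
    range, slow firing); ``fast_firing`` rows are the thin-spike, rapid
    profile that fails them.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if cell_class == "DA":
        table = pd.DataFrame(
            {
                "ap_duration_ms": rng.uniform(2.6, 3.6, n),
                "onset_to_trough_ms": rng.uniform(1.15, 2.7, n),
                "waveform_class": rng.choice(["biphasic", "triphasic"], n),
                "spontaneous_rate_sps": rng.uniform(1.5, 9.0, n),
            }
        )
    elif cell_class == "fast_firing":
        table = pd.DataFrame(
            {
                "ap_duration_ms": rng.uniform(0.8, 1.8, n),
                "onset_to_trough_ms": rng.uniform(0.3, 0.9, n),
                "waveform_class": rng.choice(["biphasic", "other"], n),
                "spontaneous_rate_sps": rng.uniform(12.0, 28.0, n),
            }
        )
    else:
        raise InvalidParameterError(f"cell_class must be 'DA' or 'fast_firing', got {cell_class!r}")
    table.insert(0, "neuron_id", [f"{cell_class.lower()}_{i:03d}" for i in range(n)])
    return table


@dataclass(frozen=True)
class TrajectoryParams:
    """Biased-random-walk trajectory generator parameters.

    ``center_bias`` scales the drift toward the target zone (the central
    square of the open field, the open arms of the plus maze); negative
    values repel.  Occupancy of the target zone is monotone in the bias and
    approaches 1 as it grows large.
    """

    arena: ArenaGeometry
    duration_s: float = 900.0
    sample_dt_s: float = 0.1
    center_bias: float = 0.0
    speed_cm_s: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.sample_dt_s <= 0:
            raise InvalidParameterError("duration_s and sample_dt_s must be positive")
        if self.speed_cm_s < 0:
            raise InvalidParameterError("speed_cm_s must be non-negative")


def _targets_of(arena: ArenaGeometry) -> np.ndarray:
    if arena.kind == OPEN_FIELD:
        c = arena.side_cm / 2.0
        return np.array([[c, c]])
    mid = arena.arm_width_cm / 2.0 + arena.arm_length_cm / 2.0
    if arena.open_arm_axis == "x":
        return np.array([[mid, 0.0], [-mid, 0.0]])
    return np.array([[0.0, mid], [0.0, -mid]])


def simulate_trajectory(params: TrajectoryParams) -> Trajectory:
    """Reflected biased random walk sampled uniformly at ``sample_dt_s``."""
    rng = np.random.default_rng(params.seed)
    arena = params.arena
    targets = _targets_of(arena)
    start = (
        np.array([arena.side_cm / 2.0, arena.side_cm / 2.0])
        if arena.kind == OPEN_FIELD
        else np.zeros(2)
    )
    n_steps = int(round(params.duration_s / params.sample_dt_s))
    step_len = params.speed_cm_s * params.sample_dt_s

    pos = start.copy()
    xs = [pos[0]]
    ys = [pos[1]]
    for _ in range(n_steps):
        d2 = ((targets - pos) ** 2).sum(axis=1)
        target = targets[int(np.argmin(d2))]
        to_target = target - pos
        norm = np.hypot(*to_target)
        drift = params.center_bias * to_target / norm if norm > 1e-9 else np.zeros(2)
        direction = drift + rng.standard_normal(2)
        dnorm = np.hypot(*direction)
        if dnorm > 1e-12 and step_len > 0:
            prop = pos + step_len * direction / dnorm
            # wall handling: keep whichever coordinates stay inside
            if arena.contains(*prop):
                pos = prop
            elif arena.contains(prop[0], pos[1]):
                pos = np.array([prop[0], pos[1]])
            elif arena.contains(pos[0], prop[1]):
                pos = np.array([pos[0], prop[1]])
        xs.append(pos[0])
        ys.append(pos[1])
    t = np.arange(n_steps + 1) * params.sample_dt_s
    return Trajectory(t_s=t, x_cm=np.asarray(xs), y_cm=np.asarray(ys))


@dataclass(frozen=True)
class GroupTableParams:
    """Per-rat metric table generator: normal model per group, n = 8 each."""

    group_names: tuple[str, ...] = ("control", "PTSD", "EA", "SEA")
    n_per_group: int = 8
    means: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    sds: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    metric: str = "value"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise InvalidParameterError("n_per_group must be >= 2")
        if not (len(self.group_names) == len(self.means) == len(self.sds)):
            raise InvalidParameterError("group_names, means and sds must have equal length")
        if any(sd < 0 for sd in self.sds):
            raise InvalidParameterError("sds must be non-negative")


def simulate_group_table(params: GroupTableParams) -> pd.DataFrame:
    """Draw the per-subject table: columns ``subject_id, group, <metric>``."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for name, mu, sd in zip(params.group_names, params.means, params.sds):
        values = rng.normal(mu, sd, params.n_per_group)
        for i, v in enumerate(values):
            rows.append({"subject_id": f"{name}_{i + 1:02d}", "group": name, params.metric: v})
    return pd.DataFrame(rows)


def simulate_sib_experiment(
    n_neurons: int,
    baseline_params: BurstTrainParams,
    stimulation_params: BurstTrainParams,
    baseline_duration_s: float = 300.0,
    n_pulses: int = 50,
    frequency_hz: float = 0.5,
    seed: int = 0,
) -> list[tuple[SpikeTrain, StimulusTrain]]:
    """Paired baseline/stimulation recordings for the %SIB contrast.

    Each neuron fires from ``baseline_params`` for ``baseline_duration_s``
    (at least the 5 min of spontaneous activity recorded per cell), then
    from ``stimulation_params`` for the span of the pulse train, so a
    stimulation-induced change in burst probability is encoded directly in
    the generative parameters.
    """
    if n_neurons < 1:
        raise InvalidParameterError("n_neurons must be >= 1")
    stim_span = n_pulses / frequency_hz
    seeds = np.random.SeedSequence((seed, 0x51B)).generate_state(2 * n_neurons)
    out = []
    for i in range(n_neurons):
        pre = simulate_burst_train(
            replace(baseline_params, duration_s=baseline_duration_s, seed=int(seeds[2 * i]) % 2**31)
        )
        during = simulate_burst_train(
            replace(stimulation_params, duration_s=stim_span, seed=int(seeds[2 * i + 1]) % 2**31)
        )
        times = np.concatenate([pre.times, during.times + baseline_duration_s])
        train = SpikeTrain(
            times, duration_s=baseline_duration_s + stim_span, neuron_id=f"n{i:03d}"
        )
        stim = StimulusTrain.regular(
            n_pulses=n_pulses, frequency_hz=frequency_hz, start_s=baseline_duration_s
        )
        out.append((train, stim))
    return out
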