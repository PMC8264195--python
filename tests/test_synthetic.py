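"""Generators: determinism, ground-truth recovery, bookkeeping invariants."""

import numpy as np
import pandas as pd
import pytest

from stimfire import (
    ARCHETYPES,
    ArenaGeometry,
    BurstTrainParams,
    EvokedResponseParams,
    GroupTableParams,
    InvalidParameterError,
    StimulusTrain,
    TrajectoryParams,
    detect_bursts,
    one_way_anova,
    qualify_da_neuron,
    simulate_burst_train,
    simulate_evoked_neuron,
    simulate_group_table,
    simulate_population,
    simulate_trajectory,
    simulate_waveform_features,
    summarize_bursting,
    strong_baseline_params,
)
from stimfire.bursting import WaveformFeatures


def burst_params(**kw):
    defaults = dict(duration_s=300.0, event_rate_hz=2.0, burst_prob_q=0.5, burst_len_mean=3.0, seed=0)
    defaults.update(kw)
    return BurstTrainParams(**defaults)


class TestBurstTrainGenerator:
    def test_identical_seed_is_bit_identical(self):
        a = simulate_burst_train(burst_params(seed=7))
        b = simulate_burst_train(burst_params(seed=7))
        c = simulate_burst_train(burst_params(seed=8))
        assert np.array_equal(a.times, b.times)
        assert not np.array_equal(a.times, c.times)

    def test_times_valid(self):
        train = simulate_burst_train(burst_params())
        assert np.all(np.diff(train.times) > 0)
        assert train.times[0] >= 0 and train.times[-1] <= train.duration_s

    def test_no_bursts_when_q_zero(self):
        for seed in range(5):
            train = simulate_burst_train(burst_params(burst_prob_q=0.0, seed=seed))
            assert detect_bursts(train) == []

    def test_closed_form_sib_recovered(self):
        # q = 0.5, E[L] = 3 -> generative %SIB = 1.5 / 2.0 = 75%
        params = burst_params()
        assert params.generative_pct_sib == pytest.approx(75.0)
        vals = []
        for seed in range(10):
            train = simulate_burst_train(burst_params(seed=seed))
            vals.append(summarize_bursting(train, detect_bursts(train)).pct_sib)
        assert np.mean(vals) == pytest.approx(75.0, abs=2.0)

    def test_spike_rate_matches_expectation(self):
        params = burst_params()
        rates = [
            simulate_burst_train(burst_params(seed=s)).rate_hz for s in range(10)
        ]
        assert np.mean(rates) == pytest.approx(params.expected_spike_rate_hz, rel=0.05)

    def test_target_solver_inverts_closed_form(self):
        p = BurstTrainParams.from_firing_targets(31.2, 3.0, 29.8)
        assert p.generative_pct_sib == pytest.approx(31.2)
        assert p.burst_len_mean == 3.0
        assert p.expected_spike_rate_hz == pytest.approx(2.98)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(burst_len_mean=1.5),
            dict(intra_burst_isi_ms=(50.0, 85.0)),
            dict(inter_event_gap_ms=150.0),
            dict(burst_prob_q=1.2),
            dict(event_rate_hz=10.0),  # gap would fall below its minimum
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            burst_params(**kw)


class TestEvokedGenerator:
    def test_epoch_past_interpulse_interval_rejected(self):
        stim = StimulusTrain.regular(n_pulses=3, frequency_hz=0.5, start_s=5.0)
        params = EvokedResponseParams(
            archetype="short_latency_excitation",
            baseline=strong_baseline_params(),
            onset_latency_ms=100.0,
            epoch_duration_ms=2500.0,
        )
        with pytest.raises(InvalidParameterError):
            simulate_evoked_neuron(params, stim)

    def test_no_response_must_be_neutral(self):
        with pytest.raises(InvalidParameterError):
            EvokedResponseParams(
                archetype="no_response", baseline=strong_baseline_params(), excitation_gain=2.0
            )

    def test_excitation_raises_epoch_rate(self):
        stim = StimulusTrain.regular(n_pulses=50, frequency_hz=0.5, start_s=5.0)
        base = strong_baseline_params()
        params = EvokedResponseParams(
            archetype="short_latency_excitation",
            baseline=base,
            onset_latency_ms=5.0,
            epoch_duration_ms=75.0,
            excitation_gain=5.0,
            seed=3,
        )
        train = simulate_evoked_neuron(params, stim)
        in_epoch = 0
        for p in stim.pulse_times_s:
            in_epoch += np.sum((train.times >= p + 0.005) & (train.times < p + 0.080))
        epoch_rate = in_epoch / (50 * 0.075)
        assert epoch_rate > 3.0 * base.expected_spike_rate_hz

    def test_inhibition_lowers_epoch_rate(self):
        stim = StimulusTrain.regular(n_pulses=50, frequency_hz=0.5, start_s=5.0)
        base = strong_baseline_params()
        params = EvokedResponseParams(
            archetype="inhibition",
            baseline=base,
            onset_latency_ms=10.0,
            epoch_duration_ms=150.0,
            inhibition_fraction=0.8,
            seed=3,
        )
        train = simulate_evoked_neuron(params, stim)
        in_epoch = 0
        for p in stim.pulse_times_s:
            in_epoch += np.sum((train.times >= p + 0.010) & (train.times < p + 0.160))
        epoch_rate = in_epoch / (50 * 0.150)
        assert epoch_rate < 0.5 * base.expected_spike_rate_hz


class TestPopulation:
    def test_label_multiset_equals_composition(self):
        comp = {"short_latency_excitation": 2, "inhibition": 3, "no_response": 1}
        records = simulate_population(comp, seed=1)
        labels = [r["true_label"] for r in records]
        assert len(records) == 6
        for k, v in comp.items():
            assert labels.count(k) == v

    def test_tuple_composition_order(self):
        records = simulate_population((1, 2, 3, 4), seed=0)
        labels = [r["true_label"] for r in records]
        assert [labels.count(a) for a in ARCHETYPES] == [1, 2, 3, 4]

    def test_protocol_shape(self):
        records = simulate_population({"no_response": 2}, seed=0)
        stim = records[0]["stim"]
        assert stim.n_pulses == 50
        assert np.allclose(np.diff(stim.pulse_times_s), 2.0)


class TestWaveformFeatures:
    def test_da_rows_all_qualify(self):
        table = simulate_waveform_features("DA", 40, seed=2)
        assert len(table) == 40
        assert (table["onset_to_trough_ms"] > 1.1).all()
        assert (table["onset_to_trough_ms"] <= 2.7).all()  # observed AP-width range
        for row in table.itertuples():
            ok, _ = qualify_da_neuron(
                WaveformFeatures(
                    row.ap_duration_ms, row.onset_to_trough_ms,
                    row.waveform_class, row.spontaneous_rate_sps,
                )
            )
            assert ok

    def test_fast_firing_rows_all_rejected(self):
        table = simulate_waveform_features("fast_firing", 40, seed=2)
        for row in table.itertuples():
            ok, _ = qualify_da_neuron(
                WaveformFeatures(
                    row.ap_duration_ms, row.onset_to_trough_ms,
                    row.waveform_class, row.spontaneous_rate_sps,
                )
            )
            assert not ok


class TestTrajectoryGenerator:
    def make_params(self, **kw):
        defaults = dict(
            arena=ArenaGeometry.open_field(), duration_s=120.0, sample_dt_s=0.1,
            center_bias=0.0, speed_cm_s=3.0, seed=0,
        )
        defaults.update(kw)
        return TrajectoryParams(**defaults)

    def test_determinism_and_distinct_seeds(self):
        a = simulate_trajectory(self.make_params(seed=5))
        b = simulate_trajectory(self.make_params(seed=5))
        c = simulate_trajectory(self.make_params(seed=6))
        assert np.array_equal(a.x_cm, b.x_cm) and np.array_equal(a.y_cm, b.y_cm)
        assert not np.array_equal(a.x_cm, c.x_cm)

    def test_positions_stay_inside(self):
        for arena in (ArenaGeometry.open_field(), ArenaGeometry.elevated_plus_maze()):
            traj = simulate_trajectory(self.make_params(arena=arena, center_bias=-3.0))
            assert arena.contains(traj.x_cm, traj.y_cm).all()

    def test_zero_speed_zero_distance(self):
        traj = simulate_trajectory(self.make_params(speed_cm_s=0.0))
        assert np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm)).sum() == 0.0

    def test_occupancy_monotone_in_bias(self):
        arena = ArenaGeometry.open_field()
        occ = []
        for bias in (-2.0, 0.0, 2.0, 8.0):
            traj = simulate_trajectory(self.make_params(center_bias=bias, duration_s=300.0))
            occ.append(np.mean(arena.zone_of(traj.x_cm, traj.y_cm) == "center"))
        assert occ == sorted(occ)
        assert occ[-1] > 0.95  # strong bias pins the walk to the centre


class TestGroupTable:
    def test_shape_and_grouping(self):
        table = simulate_group_table(GroupTableParams(seed=3))
        assert len(table) == 32
        assert table.groupby("group").size().eq(8).all()
        assert set(table.columns) == {"subject_id", "group", "value"}

    def test_design_df_matches_4x8(self):
        table = simulate_group_table(GroupTableParams(seed=1))
        res = one_way_anova(table)
        assert res.df == (3, 28)

    def test_zero_sd_distinct_means_degenerate(self):
        params = GroupTableParams(means=(0.0, 1.0, 2.0, 3.0), sds=(0.0,) * 4, seed=0)
        res = one_way_anova(simulate_group_table(params))
        assert res.degenerate and np.isinf(res.statistic)

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        n_rep = 400
        for seed in range(n_rep):
            table = simulate_group_table(GroupTableParams(seed=seed))
            if one_way_anova(table).p_value < 0.05:
                hits += 1
        # 3 sigma binomial band around 0.05
        assert abs(hits / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            GroupTableParams(n_per_group=1)
        with pytest.raises(InvalidParameterError):
            GroupTableParams(sds=(1.0, 1.0, -0.5, 1.0))
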