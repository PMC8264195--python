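"""PSTH construction, epoch detection, Rmag, classification, %SIB contrast."""

import numpy as np
import pytest

from stimfire import (
    BaselineStats,
    DegenerateDataError,
    EpochDetectionConfig,
    InvalidParameterError,
    PSTH,
    PsthConfig,
    SpikeTrain,
    StimulusTrain,
    baseline_stats,
    build_psth,
    classify_response,
    classify_train,
    compute_rmag,
    detect_excitation,
    detect_inhibition,
    sib_stimulation_contrast,
    simulate_population,
    simulate_sib_experiment,
)
from stimfire.evoked import ResponseEpoch
from stimfire.synthetic import BurstTrainParams


def make_psth(post, baseline_value=None, n_baseline=100, n_trials=50):
    post = np.asarray(post)
    base = np.full(n_baseline, baseline_value if baseline_value is not None else 0)
    return PSTH(
        counts=np.concatenate([base, post]),
        n_baseline_bins=n_baseline,
        bin_width_ms=5.0,
        n_trials=n_trials,
    )


# --------------------------------------------------------------------------
# independent exhaustive-scan oracles (loops over every candidate window)


def oracle_excitation(post, mean, sd, cfg=EpochDetectionConfig()):
    thr = mean + cfg.sd_multiplier * sd
    n = len(post)
    w = cfg.excitation_window_bins
    max_b = int(cfg.max_onset_ms / 5.0)
    for b in range(0, n - w + 1):
        if b > max_b:
            break
        if all(post[b + i] > thr for i in range(cfg.excitation_anchor_bins)) and (
            sum(post[b : b + w]) / w > thr
        ):
            offset = n
            for c in range(b + 1, n):
                tail = post[c : c + w]
                if sum(tail) / len(tail) <= thr:
                    offset = c
                    break
            return (b, offset)
    return None


def oracle_inhibition(post, mean, cfg=EpochDetectionConfig()):
    thr = (1.0 - cfg.inhibition_depth) * mean
    n = len(post)
    max_s = int(cfg.max_onset_ms / 5.0)
    for s in range(0, n - cfg.inhibition_min_bins + 1):
        if s > max_s:
            break
        if post[s] > thr:
            continue
        best = None
        for e in range(s + cfg.inhibition_min_bins - 1, n):
            if post[e] <= thr and sum(post[s : e + 1]) / (e + 1 - s) <= thr:
                best = e
        if best is not None:
            return (s, best + 1)
    return None


class TestBuildPsth:
    def test_empty_train_all_zero(self):
        train = SpikeTrain(np.array([]), duration_s=20.0)
        stim = StimulusTrain(np.array([10.0]))
        psth = build_psth(train, stim)
        assert psth.counts.sum() == 0
        assert psth.n_baseline_bins == 100
        assert psth.n_post_bins == 100

    def test_hand_binning_half_open(self):
        train = SpikeTrain(np.array([10.003, 10.012]), duration_s=20.0)
        psth = build_psth(train, StimulusTrain(np.array([10.0])))
        post = psth.post_counts
        assert post[0] == 1 and post[2] == 1 and post.sum() == 2

    def test_n_trials_counts_pulses(self):
        stim = StimulusTrain.regular(n_pulses=50, frequency_hz=0.5, start_s=5.0)
        train = SpikeTrain(np.array([50.0]), duration_s=110.0)
        psth = build_psth(train, stim)
        assert psth.n_trials == 50

    def test_counts_conserve_window_spikes(self, rng):
        times = np.sort(rng.uniform(0, 110, 400))
        train = SpikeTrain(np.unique(times), duration_s=110.0)
        stim = StimulusTrain.regular(n_pulses=50, frequency_hz=0.5, start_s=5.0)
        psth = build_psth(train, stim)
        expected = sum(
            np.sum((train.times >= p - 0.5) & (train.times < p + 0.5))
            for p in stim.pulse_times_s
        )
        assert psth.counts.sum() == expected

    def test_overlapping_windows_rejected(self):
        train = SpikeTrain(np.array([1.0]), duration_s=20.0)
        stim = StimulusTrain(np.array([5.0, 5.6]))
        with pytest.raises(InvalidParameterError):
            build_psth(train, stim)


class TestBaselineStats:
    def test_constant_baseline(self):
        psth = make_psth([0] * 100, baseline_value=4)
        stats = baseline_stats(psth)
        assert stats.mean_per_bin == 4.0 and stats.sd_per_bin == 0.0

    def test_alternating_baseline_sample_sd(self):
        base = np.tile([2, 4], 50)
        psth = PSTH(np.concatenate([base, np.zeros(100, int)]), 100, 5.0, 50)
        stats = baseline_stats(psth)
        assert stats.mean_per_bin == pytest.approx(3.0)
        assert stats.sd_per_bin == pytest.approx(np.sqrt(100 / 99))  # ~1.005

    def test_all_zero_flagged_degenerate(self):
        stats = baseline_stats(make_psth([0] * 100, baseline_value=0))
        assert stats.degenerate


class TestDetectExcitation:
    def test_flat_psth_none(self):
        base = BaselineStats(2.0, 0.5)
        assert detect_excitation(make_psth([2] * 100), base) is None

    def test_square_pulse_onset_and_offset(self):
        # post bins 10-19 at 10 on a floor of 2; threshold 2 + 2*0.5 = 3
        post = np.full(100, 2)
        post[10:20] = 10
        epoch = detect_excitation(make_psth(post), BaselineStats(2.0, 0.5))
        assert (epoch.onset_bin, epoch.offset_bin) == (10, 20)
        assert epoch.onset_latency_ms == 50.0

    def test_degenerate_baseline_raises_without_override(self):
        post = np.full(100, 2)
        post[10:20] = 10
        with pytest.raises(DegenerateDataError):
            detect_excitation(make_psth(post), BaselineStats(2.0, 0.0))
        cfg = EpochDetectionConfig(allow_degenerate_baseline=True)
        assert detect_excitation(make_psth(post), BaselineStats(2.0, 0.0), cfg) is not None

    def test_short_latency_archetype_detected_within_10ms(self):
        hits = []
        for seed in range(20):
            records = simulate_population({"short_latency_excitation": 1}, seed=seed)
            response, _, _ = classify_train(records[0]["train"], records[0]["stim"])
            assert response.label == "short_latency_excitation"
            exc = [e for e in response.epochs if e.kind == "excitation"][0]
            hits.append(exc.onset_latency_ms)
        assert max(hits) <= 10.0


class TestDetectInhibition:
    def test_square_dip_epoch(self):
        # baseline mean 4; bins 5-25 at 1 (1 <= 0.65*4 = 2.6) -> 21-bin epoch
        post = np.full(100, 4)
        post[5:26] = 1
        epoch = detect_inhibition(make_psth(post), BaselineStats(4.0, 1.0))
        assert (epoch.onset_bin, epoch.offset_bin) == (5, 26)
        assert epoch.n_bins == 21

    def test_short_dip_rejected(self):
        post = np.full(100, 4)
        post[5:15] = 1  # only 10 bins
        assert detect_inhibition(make_psth(post), BaselineStats(4.0, 1.0)) is None

    def test_shallow_dip_rejected(self):
        post = np.full(100, 4.0)
        post[5:40] = 2.8  # 30% below baseline, needs 35%
        psth = PSTH(np.concatenate([np.full(100, 4.0), post]), 100, 5.0, 50)
        assert detect_inhibition(psth, BaselineStats(4.0, 1.0)) is None

    def test_zero_baseline_mean_raises(self):
        with pytest.raises(DegenerateDataError):
            detect_inhibition(make_psth([0] * 100), BaselineStats(0.0, 0.0))


class TestOracleEquivalence:
    def test_epoch_detectors_match_exhaustive_scan(self, rng):
        cfg = EpochDetectionConfig()
        for _ in range(60):
            mean = rng.uniform(0.5, 6.0)
            post = rng.poisson(mean, size=rng.integers(30, 120))
            # inject structure in half the cases
            if rng.random() < 0.5:
                a = rng.integers(0, max(1, len(post) - 20))
                post[a : a + rng.integers(5, 20)] = rng.integers(0, 15)
            base = BaselineStats(mean, max(np.sqrt(mean), 0.3))
            psth = make_psth(post)
            exc = detect_excitation(psth, base, cfg)
            want = oracle_excitation(list(post), mean, base.sd_per_bin, cfg)
            assert (None if exc is None else (exc.onset_bin, exc.offset_bin)) == want
            inh = detect_inhibition(psth, base, cfg)
            want = oracle_inhibition(list(post), mean, cfg)
            assert (None if inh is None else (inh.onset_bin, inh.offset_bin)) == want


class TestRmag:
    def test_epoch_at_baseline_expectation_zero(self):
        post = np.full(100, 2)
        psth = make_psth(post)
        epoch = ResponseEpoch("excitation", 10, 20, 50.0)
        raw, norm = compute_rmag(psth, epoch, BaselineStats(2.0, 0.5))
        assert raw == 0.0 and norm == 0.0

    def test_excitation_arithmetic(self):
        post = np.zeros(100, int)
        post[10:20] = 5  # 10-bin epoch summing to 50
        raw, norm = compute_rmag(
            make_psth(post), ResponseEpoch("excitation", 10, 20, 50.0), BaselineStats(2.0, 0.5)
        )
        assert raw == pytest.approx(30.0) and norm == pytest.approx(15.0)

    def test_inhibition_negative(self):
        post = np.full(100, 2)
        post[5:25] = 0
        post[5:10] = 2  # 20-bin epoch summing to 10
        raw, _ = compute_rmag(
            make_psth(post), ResponseEpoch("inhibition", 5, 25, 25.0), BaselineStats(2.0, 0.5)
        )
        assert raw == pytest.approx(-30.0)

    def test_zero_baseline_norm_flagged(self):
        raw, norm = compute_rmag(
            make_psth([1] * 100), ResponseEpoch("excitation", 0, 15, 0.0), BaselineStats(0.0, 0.0)
        )
        assert np.isnan(norm)


class TestClassifyResponse:
    def test_no_epochs_is_no_response(self):
        assert classify_response(None, None).label == "no_response"

    def test_latency_boundary(self):
        short = ResponseEpoch("excitation", 2, 10, 10.0)
        late = ResponseEpoch("excitation", 6, 12, 30.0)
        boundary = ResponseEpoch("excitation", 4, 12, 20.0)
        assert classify_response(short, None).label == "short_latency_excitation"
        assert classify_response(late, None).label == "long_latency_excitation"
        assert classify_response(boundary, None).label == "short_latency_excitation"

    def test_both_kinds_earliest_onset_wins(self):
        exc = ResponseEpoch("excitation", 8, 14, 40.0)
        inh = ResponseEpoch("inhibition", 2, 20, 10.0)
        got = classify_response(exc, inh)
        assert got.label == "inhibition"
        assert len(got.epochs) == 2  # both retained
        assert classify_response(ResponseEpoch("excitation", 1, 6, 5.0), inh).label == (
            "short_latency_excitation"
        )

    def test_translation_invariance(self):
        records = simulate_population({"inhibition": 1, "long_latency_excitation": 1}, seed=4)
        for r in records:
            base, _, _ = classify_train(r["train"], r["stim"])
            shifted, _, _ = classify_train(r["train"].shifted(13.0), r["stim"].shifted(13.0))
            assert base.label == shifted.label

    def test_vanishing_effect_sizes_converge_to_no_response(self):
        records = simulate_population({"no_response": 10}, seed=9)
        labels = [classify_train(r["train"], r["stim"])[0].label for r in records]
        assert labels.count("no_response") >= 9


class TestSibContrast:
    @staticmethod
    def params(q):
        return BurstTrainParams(
            duration_s=300.0, event_rate_hz=1.8, burst_prob_q=q, burst_len_mean=3.0, seed=0
        )

    def test_identical_segments_give_t_zero(self):
        train = SpikeTrain(np.arange(0.5, 400.0, 0.5), duration_s=400.0)
        stim = StimulusTrain.regular(n_pulses=50, frequency_hz=0.5, start_s=300.0)
        table, test = sib_stimulation_contrast([(train, stim), (train, stim)])
        assert (table["baseline_pct_sib"] == table["stimulation_pct_sib"]).all()
        assert test.statistic == 0.0

    def test_burst_boost_detected(self):
        neurons = simulate_sib_experiment(8, self.params(0.2), self.params(0.7), seed=2)
        table, test = sib_stimulation_contrast(neurons)
        assert (table["stimulation_pct_sib"].mean() > table["baseline_pct_sib"].mean())
        assert test.p_value < 0.05

    def test_single_neuron_no_test(self):
        neurons = simulate_sib_experiment(1, self.params(0.3), self.params(0.3), seed=0)
        table, test = sib_stimulation_contrast(neurons)
        assert len(table) == 1 and test is None

    def test_short_baseline_rejected(self):
        train = SpikeTrain(np.arange(0.5, 120.0, 0.5), duration_s=120.0)
        stim = StimulusTrain.regular(n_pulses=5, frequency_hz=0.5, start_s=100.0)
        with pytest.raises(Exception):
            sib_stimulation_contrast([(train, stim)])
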