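"""HEP pipeline stages against constructed data and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from hepkit.channels import ECG_CHANNEL, EEG_CHANNELS
from hepkit.hep import (
    ANALYSIS_WINDOW,
    HeartbeatEpochSet,
    ParticipantExcluded,
    PreProbeWindow,
    TrialHEP,
    build_heartbeat_epochs,
    ecg_confound_check,
    effect_magnitude,
    extract_preprobe_windows,
    median_split,
    preprocess,
    regress_arousal,
    reject_artifacts,
    trial_average,
)
from hepkit.physio import RPeakSeries
from hepkit.simulate import RecordingBundle, epoch_time_axis
from hepkit.channels import standard_positions


def make_bundle(n_seconds=120.0, sfreq=250.0, probe_onsets=(30.0, 60.0, 90.0),
                data=None, seed=0):
    n = int(n_seconds * sfreq)
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.normal(0, 1, (32, n))
    return RecordingBundle(
        data=data, channel_names=list(EEG_CHANNELS) + [ECG_CHANNEL],
        channel_positions=dict(standard_positions()), sfreq=sfreq,
        probe_onsets=np.asarray(probe_onsets, dtype=float),
        run_boundaries=np.array([0.0]), participant_id="sub-test",
    )


def epoch_set(waves, ratings=None, ch_names=None, times=None):
    """Build a HeartbeatEpochSet from a list of (trial_id, waveform) pairs."""
    data = np.stack([w for _, w in waves])
    n_ch, n_t = data.shape[1:]
    return HeartbeatEpochSet(
        data=data,
        times=times if times is not None else epoch_time_axis(250.0)[:n_t],
        ch_names=ch_names or [f"ch{i}" for i in range(n_ch)],
        trial_ids=[tid for tid, _ in waves],
        rpeak_samples=np.arange(len(waves)),
        rejected=np.zeros(len(waves), dtype=bool),
    )


class TestPreprocess:
    def test_already_at_target_rate_keeps_shape(self):
        bundle = make_bundle()
        out = preprocess(bundle)
        assert out.sfreq == 250.0
        assert out.data.shape == bundle.data.shape

    def test_common_average_identity_on_eeg_only(self):
        out = preprocess(make_bundle())
        eeg = out.eeg
        assert np.abs(eeg.mean(axis=0)).max() < 1e-9
        # ECG is not drawn into the reference
        assert not np.allclose(out.ecg, 0)

    def test_slow_drift_attenuated_at_least_20_db(self):
        sfreq, n_sec = 250.0, 120.0
        t = np.arange(int(n_sec * sfreq)) / sfreq
        data = np.zeros((32, len(t)))
        drift = 100.0 * np.sin(2 * np.pi * 0.1 * t)
        data[3] = drift
        out = preprocess(make_bundle(data=data))
        mid = slice(int(20 * sfreq), int(100 * sfreq))
        ratio = np.sqrt(np.mean(out.data[3, mid] ** 2)) / np.sqrt(np.mean(drift[mid] ** 2))
        assert 20 * np.log10(1 / max(ratio, 1e-30)) >= 20.0

    def test_low_rate_rejected(self):
        bundle = make_bundle()
        bundle.sfreq = 100.0
        with pytest.raises(ValueError):
            preprocess(bundle)


class TestWindows:
    def test_window_bounds_and_cardinality(self):
        bundle = make_bundle(probe_onsets=(30.0, 60.0, 100.0))
        ratings = pd.DataFrame({"run": [0, 0, 0], "trial": [0, 1, 2],
                                "arousal": [40, 60, 50]})
        wins = extract_preprobe_windows(bundle, ratings)
        assert len(wins) == 3
        assert wins[2].start_s == 90.0 and wins[2].end_s == 100.0

    def test_missing_rating_excluded_with_log(self, caplog):
        bundle = make_bundle(probe_onsets=(30.0, 60.0, 90.0))
        ratings = pd.DataFrame({"run": [0, 0], "trial": [0, 2],
                                "arousal": [40, 60]})
        with caplog.at_level("WARNING", logger="hepkit.hep"):
            wins = extract_preprobe_windows(bundle, ratings)
        assert len(wins) == 2
        assert "1 probes excluded" in caplog.text

    def test_probe_too_early_names_the_probe(self):
        bundle = make_bundle(probe_onsets=(6.0, 60.0))
        ratings = pd.DataFrame({"run": [0, 0], "trial": [0, 1], "arousal": [1, 2]})
        with pytest.raises(ValueError, match="probe 0"):
            extract_preprobe_windows(bundle, ratings)


class TestEpoching:
    def test_one_hz_peaks_give_nine_or_ten_epochs(self):
        bundle = make_bundle()
        peaks = RPeakSeries(np.arange(0, 120 * 250, 250), 250.0)
        w = PreProbeWindow((0, 0), 20.0, 30.0, 50.0)
        out = build_heartbeat_epochs(w, peaks, bundle)
        assert len(out) in (9, 10)

    def test_epoch_grid_at_250_hz(self):
        bundle = make_bundle()
        peaks = RPeakSeries(np.array([5000]), 250.0)
        w = PreProbeWindow((0, 0), 10.0, 20.0, 50.0)
        out = build_heartbeat_epochs(w, peaks, bundle)
        assert out.data.shape[-1] == 188
        assert out.times[0] == pytest.approx(-0.100)
        assert out.times[-1] == pytest.approx(0.648)

    def test_epoch_near_window_end_retained(self):
        bundle = make_bundle()
        # R peak 50 ms before probe onset: epoch extends past the window end
        peak = int((30.0 - 0.05) * 250)
        out = build_heartbeat_epochs(
            PreProbeWindow((0, 0), 20.0, 30.0, 50.0),
            RPeakSeries(np.array([peak]), 250.0), bundle)
        assert len(out) == 1

    def test_epoch_values_match_raw_slice(self):
        bundle = make_bundle()
        peak = 5000
        out = build_heartbeat_epochs(
            PreProbeWindow((0, 0), 12.0, 22.0, 50.0),
            RPeakSeries(np.array([peak]), 250.0), bundle)
        np.testing.assert_array_equal(
            out.data[0, 0], bundle.data[0, peak - 25:peak + 163])


class TestRejection:
    def test_clean_epochs_all_retained(self, rng):
        es = epoch_set([((0, i), rng.normal(0, 5, (4, 50))) for i in range(6)])
        out = reject_artifacts(es, 150.0)
        assert out.rejected.sum() == 0

    def test_single_spiked_epoch_rejected(self, rng):
        waves = [((0, i), rng.normal(0, 5, (4, 50))) for i in range(6)]
        waves[3][1][2, 10] = 500.0
        out = reject_artifacts(epoch_set(waves), 150.0)
        assert list(np.flatnonzero(out.rejected)) == [3]

    def test_infinite_threshold_is_identity(self, rng):
        es = epoch_set([((0, i), rng.normal(0, 500, (4, 50))) for i in range(4)])
        out = reject_artifacts(es, np.inf)
        assert out.rejected.sum() == 0


class TestTrialAverage:
    def _windows(self, n, ratings=None):
        return [PreProbeWindow((0, i), 10.0 + 20 * i, 20.0 + 20 * i,
                               ratings[i] if ratings else 50.0)
                for i in range(n)]

    def test_identical_epochs_average_to_themselves(self):
        w = np.ones((3, 20))
        es = epoch_set([((0, 0), w), ((0, 0), w)])
        out = trial_average(es, self._windows(1))
        np.testing.assert_array_equal(out[0].mean_waveform, w)

    def test_antisymmetric_epochs_cancel(self, rng):
        v = rng.normal(size=(3, 20))
        es = epoch_set([((0, 0), v), ((0, 0), -v)])
        out = trial_average(es, self._windows(1))
        np.testing.assert_allclose(out[0].mean_waveform, 0, atol=1e-12)

    def test_noise_reduction_scales_with_sqrt_n(self, rng):
        sigma, n_ep = 4.0, 10
        sds = []
        for _ in range(40):
            es = epoch_set([((0, 0), rng.normal(0, sigma, (2, 100)))
                            for _ in range(n_ep)])
            sds.append(trial_average(es, self._windows(1))[0].mean_waveform.std())
        assert np.mean(sds) == pytest.approx(sigma / np.sqrt(n_ep), rel=0.1)

    def test_trials_without_retained_epochs_dropped(self, rng):
        es = epoch_set([((0, 0), rng.normal(size=(2, 20))),
                        ((0, 1), rng.normal(size=(2, 20)))])
        es.rejected[1] = True
        out = trial_average(es, self._windows(2))
        assert [t.trial_id for t in out] == [(0, 0)]


def _trials_from_ratings(ratings, value_fn, n_ch=2, rng=None):
    times = epoch_time_axis(250.0)
    out = []
    for i, r in enumerate(ratings):
        wave = np.zeros((n_ch, len(times)))
        wave[:] = value_fn(r)
        if rng is not None:
            wave += rng.normal(0, 0.1, wave.shape)
        out.append(TrialHEP((0, i), wave, 10, float(r),
                            [f"ch{c}" for c in range(n_ch)], times))
    return out


class TestRegression:
    def test_exact_linear_data_recovers_slope(self):
        trials = _trials_from_ratings([10, 30, 50, 70], lambda r: 2.0 * r + 7.0)
        sm = regress_arousal(trials, "p0")
        np.testing.assert_allclose(sm.slopes, 2.0, atol=1e-10)
        assert sm.times.min() >= ANALYSIS_WINDOW[0]
        assert sm.times.max() <= ANALYSIS_WINDOW[1]

    def test_matches_polyfit_oracle_on_toy_table(self, rng):
        ratings = [12, 35, 50, 64, 88]
        trials = _trials_from_ratings(ratings, lambda r: 0.0, rng=rng)
        sm = regress_arousal(trials, "p0")
        y = np.stack([t.mean_waveform for t in trials])
        tsel = np.isin(np.round(trials[0].times, 6), np.round(sm.times, 6))
        for ch in range(2):
            for k in range(0, sm.slopes.shape[1], 7):
                col = y[:, ch, tsel][:, k]
                oracle = np.polyfit(np.asarray(ratings, float), col, 1)[0]
                assert sm.slopes[ch, k] == pytest.approx(oracle, abs=1e-9)

    def test_permuted_ratings_center_slopes_on_zero(self, rng):
        slopes = []
        for _ in range(100):
            ratings = rng.permutation(np.linspace(10, 90, 20))
            trials = _trials_from_ratings(ratings, lambda r: 0.0, rng=rng)
            slopes.append(regress_arousal(trials, "p").slopes.mean())
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes))

    def test_constant_ratings_exclude_participant(self):
        trials = _trials_from_ratings([50, 50, 50, 50], lambda r: r)
        with pytest.raises(ParticipantExcluded):
            regress_arousal(trials, "p0")


class TestMedianSplit:
    def test_even_split(self):
        trials = _trials_from_ratings([10, 20, 30, 40], lambda r: float(r))
        ms = median_split(trials, "p0")
        assert (ms.n_low, ms.n_high) == (2, 2)
        assert ms.low.mean() == pytest.approx(15.0)
        assert ms.high.mean() == pytest.approx(35.0)

    def test_ties_go_to_low(self):
        trials = _trials_from_ratings([10, 20, 20, 40], lambda r: float(r))
        ms = median_split(trials, "p0")
        assert (ms.n_low, ms.n_high) == (3, 1)
        assert ms.high.mean() == pytest.approx(40.0)

    def test_partition_covers_all_trials(self, rng):
        ratings = rng.integers(0, 101, 15)
        if np.unique(ratings).size == 1:
            ratings[0] += 1
        trials = _trials_from_ratings(ratings, lambda r: float(r))
        ms = median_split(trials, "p0")
        assert ms.n_low + ms.n_high == len(trials)

    def test_identical_ratings_unsplittable(self):
        trials = _trials_from_ratings([30, 30, 30], lambda r: float(r))
        with pytest.raises(ParticipantExcluded):
            median_split(trials, "p0")


class TestEffectMagnitude:
    def _slope_map(self, fill):
        from hepkit.hep import SlopeMap
        times = epoch_time_axis(250.0)
        tsel = (times >= 0.250) & (times <= 0.450)
        slopes = np.full((2, tsel.sum()), np.nan)
        slopes[:] = fill
        return SlopeMap("p0", slopes, ["Fz", "Cz"], times[tsel], 10)

    def test_constant_cluster_returns_constant(self):
        sm = self._slope_map(3.5)
        assert effect_magnitude(sm, [("Fz", 0.30), ("Cz", 0.40)]) == pytest.approx(3.5)

    def test_two_point_average(self):
        sm = self._slope_map(0.0)
        sm.slopes[0, 0] = 1.0
        sm.slopes[1, 0] = 5.0
        t0 = sm.times[0]
        assert effect_magnitude(sm, [("Fz", t0), ("Cz", t0)]) == pytest.approx(3.0)

    def test_unknown_channel_raises(self):
        with pytest.raises(KeyError):
            effect_magnitude(self._slope_map(1.0), [("Oz", 0.3)])


class TestECGConfound:
    def test_planted_association_recovered(self, rng):
        ratings = np.linspace(5, 95, 30)
        trials = _trials_from_ratings(ratings, lambda r: 0.5 * r, n_ch=1, rng=rng)
        res = ecg_confound_check([trials], window=(0.340, 0.356))
        assert res.mean_slope == pytest.approx(0.5, abs=0.01)
        assert 1 / res.peak_bf01 > 3  # BF10 > 3

    def test_zero_ecg_gives_zero_slope(self):
        trials = _trials_from_ratings([10, 40, 70, 90], lambda r: 0.0, n_ch=1)
        res = ecg_confound_check([trials], window=(0.340, 0.356))
        assert res.mean_slope == 0.0

    def test_empty_window_rejected(self):
        trials = _trials_from_ratings([10, 40, 70], lambda r: 1.0, n_ch=1)
        with pytest.raises(ValueError):
            ecg_confound_check([trials], window=(0.4, 0.3))
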