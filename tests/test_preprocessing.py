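"""Signal-conditioning chain: zero-phase filter responses, resampling,
epoching, artifact rejection, and normalization."""

import numpy as np
import pytest

from mibci.preprocessing import (
    ContinuousRecording,
    PreprocessConfig,
    PreprocessError,
    TrialSet,
    bandpass_filter,
    epoch_trials,
    load_trialset,
    notch_filter,
    reject_amplitude,
    reject_joint_probability,
    resample,
    save_trialset,
    select_channels,
    zscore_trials,
)

RATE = 250.0


def sinusoid(freq, seconds=8.0, rate=RATE, channels=1):
    t = np.arange(int(seconds * rate)) / rate
    return ContinuousRecording(
        signals=np.tile(np.sin(2 * np.pi * freq * t), (channels, 1)),
        rate=rate,
        channel_names=tuple(f"ch{i}" for i in range(channels)),
    )


def _amplitude(x):
    core = x[len(x) // 4 : -len(x) // 4]  # ignore filter edge effects
    return np.sqrt(2) * np.sqrt(np.mean(core**2))


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = ContinuousRecording(np.zeros((2, 1000)), RATE, ("a", "b"))
        assert np.allclose(bandpass_filter(rec).signals, 0.0)

    def test_passband_gain_and_zero_lag(self):
        rec = sinusoid(10.0)
        out = bandpass_filter(rec)
        assert _amplitude(out.signals[0]) == pytest.approx(1.0, rel=0.05)
        xc = np.correlate(out.signals[0], rec.signals[0], mode="full")
        lag = xc.argmax() - (len(rec.signals[0]) - 1)
        assert lag == 0

    def test_stopband_attenuation_at_1hz(self):
        out = bandpass_filter(sinusoid(1.0))
        assert _amplitude(out.signals[0]) < 0.3

    def test_band_above_nyquist_rejected(self):
        rec = sinusoid(10.0, rate=60.0)
        with pytest.raises(PreprocessError):
            bandpass_filter(rec, PreprocessConfig(band=(4.0, 40.0)))

    def test_linearity(self, rng):
        x = ContinuousRecording(rng.normal(size=(1, 2000)), RATE, ("a",))
        y = ContinuousRecording(rng.normal(size=(1, 2000)), RATE, ("a",))
        combo = ContinuousRecording(
            2.0 * x.signals + 3.0 * y.signals, RATE, ("a",)
        )
        lhs = bandpass_filter(combo).signals
        rhs = 2.0 * bandpass_filter(x).signals + 3.0 * bandpass_filter(y).signals
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_input_not_mutated(self):
        rec = sinusoid(10.0)
        before = rec.signals.copy()
        bandpass_filter(rec)
        assert np.array_equal(rec.signals, before)


class TestNotch:
    def test_zero_in_zero_out(self):
        rec = ContinuousRecording(np.zeros((1, 1000)), RATE, ("a",))
        assert np.allclose(notch_filter(rec).signals, 0.0)

    def test_mains_attenuated_20db(self):
        out = notch_filter(sinusoid(50.0))
        assert _amplitude(out.signals[0]) <= 0.1  # >= 20 dB down

    def test_passband_preserved(self):
        out = notch_filter(sinusoid(10.0))
        assert _amplitude(out.signals[0]) == pytest.approx(1.0, rel=0.05)


class TestResample:
    def test_length_ratio_160_to_250(self):
        rec = ContinuousRecording(
            np.random.default_rng(0).normal(size=(2, 1600)), 160.0, ("a", "b")
        )
        out = resample(rec, 250.0)
        assert out.signals.shape[1] == 2500
        assert out.rate == 250.0

    def test_identity_at_same_rate(self):
        rec = sinusoid(10.0)
        assert resample(rec, RATE) is rec

    def test_frequency_preserved(self):
        rec = sinusoid(8.0, seconds=10.0, rate=160.0)
        out = resample(rec, 250.0)
        spec = np.abs(np.fft.rfft(out.signals[0]))
        freqs = np.fft.rfftfreq(out.signals.shape[1], 1 / 250.0)
        assert abs(freqs[spec.argmax()] - 8.0) <= freqs[1]


class TestEpoching:
    def _rec(self, events):
        rng = np.random.default_rng(0)
        return ContinuousRecording(rng.normal(size=(3, 5000)), RATE,
                                   ("a", "b", "c"), events=tuple(events))

    def test_cue_to_4s_window_gives_1000_samples(self):
        ts = epoch_trials(self._rec([(500, 0), (2000, 1)]), window_s=(0.0, 4.0))
        assert ts.trials.shape == (2, 3, 1000)

    def test_prestim_window_gives_1250_samples(self):
        ts = epoch_trials(self._rec([(500, 0)]), window_s=(-0.5, 4.5))
        assert ts.trials.shape == (1, 3, 1250)

    def test_out_of_bounds_event_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped 1"):
            ts = epoch_trials(self._rec([(0, 0), (500, 1)]), window_s=(-0.5, 4.5))
        assert len(ts) == 1

    def test_precue_baseline_subtracted(self):
        rec = self._rec([(500, 0)])
        ts = epoch_trials(rec, window_s=(-0.5, 4.5))
        pre = ts.trials[0, :, :125]
        np.testing.assert_allclose(pre.mean(axis=1), 0.0, atol=1e-12)

    def test_whole_trial_baseline_when_no_precue(self):
        ts = epoch_trials(self._rec([(500, 0)]), window_s=(0.0, 4.0))
        np.testing.assert_allclose(ts.trials[0].mean(axis=1), 0.0, atol=1e-12)


def _trials(n=10, amp=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return TrialSet(
        trials=amp * rng.normal(size=(n, 3, 100)),
        labels=rng.integers(0, 4, n),
        subject_ids=np.zeros(n, dtype=int),
        rate=RATE,
    )


class TestAmplitudeRejection:
    def test_boundary_strictly_exceeding(self):
        ts = _trials(2)
        ts.trials[0] *= 0
        ts.trials[0, 0, 0] = 99.9
        ts.trials[1] *= 0
        ts.trials[1, 0, 0] = 100.1
        kept, rejected = reject_amplitude(ts, 100.0)
        assert list(rejected) == [1]
        assert len(kept) == 1

    def test_constructed_outliers_exactly_flagged(self):
        ts = _trials(10, amp=1.0)
        bad = [2, 5, 7]
        for i in bad:
            ts.trials[i, 1, 50] = 150.0
        kept, rejected = reject_amplitude(ts, 100.0)
        assert sorted(rejected) == bad
        assert len(kept) == 7


class TestJointProbabilityRejection:
    def test_iid_normal_rejection_rate_bounded(self):
        """<= 5% of i.i.d. normal trials flagged, averaged over seeds."""
        fractions = []
        for seed in range(20):
            ts = _trials(100, seed=seed)
            _, rejected = reject_joint_probability(ts, 3.0)
            fractions.append(len(rejected) / 100)
        assert np.mean(fractions) <= 0.05

    def test_planted_outlier_rejected(self):
        ts = _trials(50, seed=1)
        ts.trials[13] *= 10.0
        _, rejected = reject_joint_probability(ts, 3.0)
        assert 13 in rejected

    def test_infinite_limit_rejects_nothing(self):
        _, rejected = reject_joint_probability(_trials(20), np.inf)
        assert len(rejected) == 0

    def test_too_few_trials_error(self):
        with pytest.raises(PreprocessError):
            reject_joint_probability(_trials(4), 3.0)


class TestZScore:
    def test_mean_zero_sd_one(self):
        out = zscore_trials(_trials(5))
        np.testing.assert_allclose(out.trials.mean(axis=2), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.trials.std(axis=2), 1.0, atol=1e-9)

    def test_idempotent(self):
        once = zscore_trials(_trials(5))
        twice = zscore_trials(once)
        np.testing.assert_allclose(once.trials, twice.trials, atol=1e-12)

    def test_constant_channel_error_names_location(self):
        ts = _trials(3)
        ts.trials[1, 2, :] = 7.0
        with pytest.raises(PreprocessError, match="channel 2 in trial 1"):
            zscore_trials(ts)


class TestChannelSelection:
    def test_subset_in_requested_order(self):
        rec = ContinuousRecording(
            np.arange(12.0).reshape(4, 3), RATE, ("a", "b", "c", "d")
        )
        out = select_channels(rec, ["d", "b"])
        assert out.channel_names == ("d", "b")
        np.testing.assert_array_equal(out.signals, rec.signals[[3, 1]])

    def test_identity_list(self):
        ts = _trials(3)
        ts = TrialSet(ts.trials, ts.labels, ts.subject_ids, RATE,
                      channel_names=("a", "b", "c"))
        out = select_channels(ts, ["a", "b", "c"])
        np.testing.assert_array_equal(out.trials, ts.trials)

    def test_unknown_channel_error(self):
        rec = ContinuousRecording(np.zeros((2, 10)), RATE, ("a", "b"))
        with pytest.raises(PreprocessError, match="nope"):
            select_channels(rec, ["a", "nope"])


class TestTrialSetIO:
    def test_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "trials.npz"
        save_trialset(small_dataset, path)
        loaded = load_trialset(path)
        np.testing.assert_allclose(
            loaded.trials, small_dataset.trials.astype(np.float32), rtol=1e-6
        )
        assert np.array_equal(loaded.labels, small_dataset.labels)
        assert loaded.classes == small_dataset.classes
        assert loaded.rate == small_dataset.rate
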