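"""Preprocessing contracts: re-referencing, filter gain, block-average
downsampling, epoch arithmetic, baseline correction and pair averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from rsvpauth.preprocess import (
    EpochSet,
    average_adjacent_pairs,
    baseline_correct,
    design_lowpass,
    downsample_avg,
    extract_epochs,
    lowpass,
    preprocess_pipeline,
    rereference,
)
from rsvpauth.simulate import ContinuousRecording


def make_rec(data, fs=600.0, events=None):
    data = np.asarray(data, float)
    names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ContinuousRecording(data=data, fs=fs, channel_names=names,
                               events=events or [])


class TestRereference:
    def test_identical_channels_cancel(self):
        rec = make_rec(np.tile(np.sin(np.arange(100)), (4, 1)))
        out = rereference(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_identity_matrix_is_noop(self, rng):
        rec = make_rec(rng.standard_normal((4, 50)))
        out = rereference(rec, np.eye(4))
        np.testing.assert_array_equal(out.data, rec.data)

    def test_channel_mean_is_zero_after_average_reference(self, rng):
        rec = make_rec(rng.standard_normal((4, 100)))
        out = rereference(rec)
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-9

    def test_matrix_shape_mismatch_raises(self, rng):
        rec = make_rec(rng.standard_normal((4, 50)))
        with pytest.raises(ValueError, match="matrix"):
            rereference(rec, np.eye(3))


@pytest.fixture(scope="module")
def response():
    fs = 2400.0
    sos = design_lowpass(fs)
    freqs = np.linspace(0.1, 120.0, 600)
    _, h = sp_signal.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
    return freqs, 20 * np.log10(np.maximum(np.abs(h), 1e-12))


class TestLowpass:
    """Gain contract measured on the designed frequency response."""

    def test_passband_within_1db(self, response):
        freqs, gain_db = response
        assert gain_db[freqs <= 40.0].min() >= -1.0 - 1e-6

    def test_stopband_at_least_40db_down(self, response):
        freqs, gain_db = response
        assert gain_db[freqs >= 49.0].max() <= -40.0

    def test_dc_gain_unity(self):
        rec = make_rec(np.full((2, 4000), 5.0), fs=2400.0)
        out = lowpass(rec)
        np.testing.assert_allclose(out.data, 5.0, rtol=1e-6)

    def test_invalid_band_edges(self):
        with pytest.raises(ValueError):
            design_lowpass(fs=2400.0, passband_hz=50.0, stopband_hz=49.0)


class TestDownsample:
    def test_four_sample_average(self):
        rec = make_rec([[1, 2, 3, 4, 5, 6, 7, 8]], fs=2400.0)
        out = downsample_avg(rec, 4)
        np.testing.assert_array_equal(out.data, [[2.5, 6.5]])
        assert out.fs == 600.0

    def test_factor_one_identity(self, rng):
        rec = make_rec(rng.standard_normal((2, 10)))
        out = downsample_avg(rec, 1)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_constant_preserved_trailing_dropped(self):
        rec = make_rec(np.full((1, 11), 3.25))
        out = downsample_avg(rec, 4)
        np.testing.assert_array_equal(out.data, np.full((1, 2), 3.25))

    def test_events_floor_divided(self):
        rec = make_rec(np.zeros((1, 100)), events=[(5, "self"), (97, "nonself")])
        out = downsample_avg(rec, 4)
        assert out.events == [(1, "self"), (24, "nonself")]

    def test_factor_exceeding_length_raises(self):
        with pytest.raises(ValueError):
            downsample_avg(make_rec(np.zeros((1, 3))), 4)

    @given(st.integers(1, 6), st.integers(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_matches_reshape_oracle(self, factor, extra):
        n = factor * 5 + extra
        data = np.arange(2.0 * n).reshape(2, n)
        out = downsample_avg(make_rec(data), factor)
        keep = (n // factor) * factor
        oracle = data[:, :keep].reshape(2, -1, factor).mean(axis=2)
        np.testing.assert_allclose(out.data, oracle)


class TestEpochs:
    def test_sample_counts_at_600hz(self):
        rec = make_rec(np.zeros((2, 5000)), fs=600.0,
                       events=[(1000, "self"), (3000, "nonself")])
        assert extract_epochs(rec, 0.0, 1000.0).n_times == 600
        assert extract_epochs(rec, -200.0, 1000.0).n_times == 720

    def test_edge_event_rejected_with_count_decrement(self, caplog):
        rec = make_rec(np.zeros((1, 2000)), fs=600.0,
                       events=[(50, "self"), (1000, "self")])
        with caplog.at_level("WARNING"):
            ep = extract_epochs(rec, -200.0, 1000.0)
        assert ep.n_trials == 1
        assert "rejected" in caplog.text

    def test_labels_follow_event_labels(self):
        rec = make_rec(np.zeros((1, 4000)), fs=600.0,
                       events=[(500, "self"), (1500, "nonself"), (2500, "self")])
        ep = extract_epochs(rec, 0.0, 1000.0)
        np.testing.assert_array_equal(ep.labels, [1, 0, 1])

    def test_epoch_then_downsample_equals_downsample_then_epoch(self, rng):
        # For factor-aligned events, both orders yield identical epochs.
        factor, fs = 4, 2400.0
        data = rng.standard_normal((3, 48000))
        events = [(4800, "self"), (24000, "nonself")]
        a = downsample_avg(make_rec(data, fs, events), factor)
        ep_a = extract_epochs(a, 0.0, 1000.0)
        ep_b = extract_epochs(make_rec(data, fs, events), 0.0, 1000.0)
        manual = ep_b.data.reshape(2, 3, -1, factor).mean(axis=3)
        np.testing.assert_allclose(ep_a.data, manual, atol=1e-12)


class TestBaseline:
    def make_epochs(self, data, fs=600.0, t0=-200.0):
        labels = np.zeros(data.shape[0], int)
        labels[::2] = 1
        names = tuple(f"ch{i}" for i in range(data.shape[1]))
        return EpochSet(data=data, labels=labels, fs=fs, t0=t0, channel_names=names)

    def test_constant_epoch_zeroed(self):
        ep = self.make_epochs(np.full((2, 3, 720), 5.0))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_mean_zero_after_correction(self, rng):
        ep = self.make_epochs(rng.standard_normal((4, 2, 720)))
        out = baseline_correct(ep)
        window = out.times < 0
        assert np.max(np.abs(out.data[:, :, window].mean(axis=2))) < 1e-9

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_idempotent(self, seed):
        data = np.random.default_rng(seed).standard_normal((2, 2, 720))
        once = baseline_correct(self.make_epochs(data))
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_empty_window_raises(self):
        ep = self.make_epochs(np.zeros((1, 1, 600)), t0=0.0)
        with pytest.raises(ValueError):
            baseline_correct(ep, (-200.0, 0.0))


class TestPairAveraging:
    def make_epochs(self, n_self, n_nonself, n_times=60, fill=None, rng=None):
        n = n_self + n_nonself
        labels = np.array([1] * n_self + [0] * n_nonself)
        if rng is not None:
            data = rng.standard_normal((n, 2, n_times))
        else:
            data = np.broadcast_to(np.asarray(fill, float)[:, None, None],
                                   (n, 2, n_times)).copy()
        return EpochSet(data=data, labels=labels, fs=600.0, t0=0.0,
                        channel_names=("a", "b"))

    def test_200_trials_become_100(self, rng):
        ep = self.make_epochs(100, 100, rng=rng)
        assert average_adjacent_pairs(ep).n_trials == 100

    def test_identical_pair_passthrough(self):
        ep = self.make_epochs(2, 0, fill=[3.0, 3.0])
        out = average_adjacent_pairs(ep)
        np.testing.assert_array_equal(out.data[0], ep.data[0])

    def test_opposite_pair_cancels(self):
        ep = self.make_epochs(2, 0, fill=[4.0, -4.0])
        out = average_adjacent_pairs(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_classes_never_mixed_and_odd_trial_dropped(self):
        ep = self.make_epochs(3, 2, fill=[1, 1, 1, -1, -1])
        out = average_adjacent_pairs(ep)
        assert out.n_trials == 2
        assert sorted(out.labels) == [0, 1]
        # class values preserved: self pair averages to 1, nonself to -1
        assert {out.data[out.labels == 1].mean(), out.data[out.labels == 0].mean()} == {1.0, -1.0}

    def test_white_noise_variance_halves(self, rng):
        ep = self.make_epochs(200, 0, n_times=200, rng=rng)
        out = average_adjacent_pairs(ep)
        ratio = out.data.var() / ep.data.var()
        assert abs(ratio - 0.5) < 0.05

    def test_fewer_than_two_trials_raises(self):
        ep = self.make_epochs(1, 0, fill=[1.0])
        with pytest.raises(ValueError):
            average_adjacent_pairs(ep)


class TestPipeline:
    def test_full_chain_shape_and_provenance(self, tiny_recording, small_config):
        ep = preprocess_pipeline(tiny_recording)
        assert ep.fs == 600.0
        assert ep.n_times == 720  # −200..1000 ms at 600 Hz
        assert ep.n_trials == small_config.n_trials // 2
        assert ep.provenance["downsample_factor"] == 4
        crop = ep.crop(0.0, 1000.0)
        assert crop.n_times == 600
        assert crop.t0 == 0.0
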