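import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import speechtrf as st
from speechtrf.preprocess import qc_gate


def _rec(data, fs=1000.0, positions=None):
    n = data.shape[0]
    labels = tuple(f"ch{i}" for i in range(n))
    if positions is None:
        _, pos = st.default_montage()
        positions = pos[:n]
    return st.EEGRecording(data, fs, labels, positions)


class TestResample:
    def test_sine_preserved_analytically(self):
        t = np.arange(10_000) / 1000.0
        rec = _rec(np.sin(2 * np.pi * 4 * t)[None, :], fs=1000.0)
        out = st.resample(rec, 100.0)
        assert out.fs == 100.0
        assert out.n_times == 1000
        ref = np.sin(2 * np.pi * 4 * np.arange(1000) / 100.0)
        r = np.corrcoef(out.data[0], ref)[0, 1]
        assert r > 0.999

    def test_identity_when_target_equals_fs(self):
        rec = _rec(np.random.default_rng(0).normal(size=(4, 500)))
        out = st.resample(rec, rec.fs)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_biosemi_rate_length(self):
        rec = _rec(np.zeros((1, 10240)), fs=1024.0)
        out = st.resample(rec, 100.0)
        assert out.n_times == round(10240 * 100 / 1024)

    def test_upsampling_rejected(self):
        rec = _rec(np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError, match="upsampling"):
            st.resample(rec, 200.0)


class TestBandpass:
    def test_zero_phase_pulse_latency(self):
        t = np.arange(2000)
        pulse = np.exp(-0.5 * ((t - 1000) / 40.0) ** 2)
        rec = _rec(pulse[None, :], fs=100.0)
        out = st.bandpass_zero_phase(rec, 1.0, 8.0)
        assert abs(int(np.argmax(out.data[0])) - 1000) <= 1

    @pytest.mark.parametrize(
        "freq,check",
        [(4.0, lambda g: 0.9 < g <= 1.0), (20.0, lambda g: g < 10 ** (-10 / 20))],
    )
    def test_filter_gain_matches_response_oracle(self, freq, check):
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * freq * t)[None, :], fs=fs)
        out = st.bandpass_zero_phase(rec, 1.0, 8.0)
        mid = slice(500, -500)  # ignore edge transients
        gain = out.data[0, mid].std() / rec.data[0, mid].std()
        assert check(gain)

    def test_dc_rejected(self):
        rec = _rec(np.full((2, 3000), 7.0), fs=100.0)
        out = st.bandpass_zero_phase(rec, 1.0, 8.0)
        assert np.abs(out.data).max() < 1e-6

    def test_band_outside_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError):
            st.bandpass_zero_phase(rec, 1.0, 60.0)


class TestBadChannels:
    def test_direct_rule(self, rng):
        data = rng.normal(size=(4, 2000))
        data *= np.array([1.0, 1.0, 1.0, np.sqrt(10)])[:, None]
        rec = _rec(data, fs=100.0)
        assert st.detect_bad_channels(rec) == ["ch3"]

    def test_all_equal_variances_flag_nothing(self, rng):
        base = rng.normal(size=2000)
        rec = _rec(np.stack([base, -base, base[::-1]]), fs=100.0)
        assert st.detect_bad_channels(rec) == []

    def test_median_based_rule(self, rng):
        scales = np.sqrt(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        data = rng.normal(size=(5, 20000)) * scales[:, None]
        rec = _rec(data, fs=100.0)
        assert st.detect_bad_channels(rec) == ["ch4"]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hst.lists(hst.floats(0.1, 50.0), min_size=3, max_size=12),
           hst.integers(0, 10_000))
    def test_matches_one_line_restatement(self, scales, seed):
        g = np.random.default_rng(seed)
        data = g.normal(size=(len(scales), 500)) * np.sqrt(scales)[:, None]
        rec = _rec(data, fs=100.0)
        var = data.var(axis=1)
        expected = [f"ch{i}" for i in np.flatnonzero(var > 3 * np.median(var))]
        assert st.detect_bad_channels(rec) == expected


class TestInterpolation:
    def test_smooth_field_recovery(self, montage):
        labels, pos = montage
        # order-1 spherical harmonic: a linear function of position
        truth = pos @ np.array([0.3, -0.8, 0.5])
        data = np.tile(truth[:, None], (1, 50))
        rec = st.EEGRecording(data.copy(), 100.0, tuple(labels), pos)
        bad = labels[30]
        corrupted = rec.data.copy()
        corrupted[30] = 40.0
        rec = st.EEGRecording(corrupted, 100.0, tuple(labels), pos)
        out = st.interpolate_channels(rec, [bad])
        err = np.abs(out.data[30] - data[30]).max()
        assert err < 0.05 * np.abs(truth).max()

    def test_empty_bad_list_is_identity(self, recording):
        out = st.interpolate_channels(recording, [])
        np.testing.assert_array_equal(out.data, recording.data)

    def test_idempotent(self, recording):
        once = st.interpolate_channels(recording, ["Cz"])
        twice = st.interpolate_channels(once, ["Cz"])
        np.testing.assert_allclose(twice.data, once.data, atol=1e-8)

    def test_too_few_clean_channels(self):
        data = np.zeros((5, 10))
        _, pos = st.default_montage()
        rec = st.EEGRecording(data, 100.0, tuple("abcde"), pos[:5])
        with pytest.raises(ValueError, match="clean channels"):
            st.interpolate_channels(rec, ["a", "b"])


class TestRereference:
    def test_average_reference_zero_mean(self, recording):
        out = st.rereference(recording, "average")
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-10)

    def test_none_is_identity(self, recording):
        out = st.rereference(recording, "none")
        np.testing.assert_array_equal(out.data, recording.data)

    def test_zero_channel_reference_is_identity(self):
        data = np.random.default_rng(0).normal(size=(3, 100))
        data[2] = 0.0
        _, pos = st.default_montage()
        rec = st.EEGRecording(data, 100.0, ("a", "b", "z"), pos[:3])
        out = st.rereference(rec, "channel:z")
        np.testing.assert_array_equal(out.data, rec.data)

    def test_unknown_channel_rejected(self, recording):
        with pytest.raises(ValueError):
            st.rereference(recording, "channel:nope")


def test_chain_records_documented_order(recording):
    out, bad = st.preprocess_chain(recording, target_fs=50.0, bad_factor=1e6)
    ops = [h["op"] for h in out.history if h["op"] != "simulate"]
    assert ops == ["resample", "bandpass", "interpolate"]


def test_qc_gate_warns_and_fails_above_limits():
    assert qc_gate(4, 0.3)
    with pytest.warns(UserWarning, match="QC gate"):
        assert not qc_gate(5, 0.0)
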