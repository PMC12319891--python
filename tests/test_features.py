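import numpy as np
import pytest

import speechtrf as st
from speechtrf.features import greenwood_frequency, greenwood_position


FS_AUDIO = 16_000.0


class TestEnvelope:
    def test_tone_amplitude_recovered(self):
        t = np.arange(int(2 * FS_AUDIO)) / FS_AUDIO
        env = st.compute_envelope(0.5 * np.sin(2 * np.pi * 1000 * t), FS_AUDIO, 100.0)
        mid = env[50:-50]
        assert np.allclose(mid, 0.5, rtol=0.01)

    def test_silence_is_zero(self):
        env = st.compute_envelope(np.zeros(int(FS_AUDIO)), FS_AUDIO, 100.0)
        assert np.allclose(env, 0.0, atol=1e-12)

    def test_am_tone_matches_modulator(self):
        t = np.arange(int(4 * FS_AUDIO)) / FS_AUDIO
        mod = 1 + 0.5 * np.cos(2 * np.pi * 3 * t)
        env = st.compute_envelope(mod * np.sin(2 * np.pi * 1000 * t), FS_AUDIO, 100.0)
        t100 = np.arange(len(env)) / 100.0
        ref = 1 + 0.5 * np.cos(2 * np.pi * 3 * t100)
        sl = slice(50, -50)
        assert np.corrcoef(env[sl], ref[sl])[0, 1] > 0.99

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError, match="mono"):
            st.compute_envelope(np.zeros((2, 100)), FS_AUDIO, 100.0)


class TestGreenwood:
    def test_paper_band_configuration(self):
        edges = st.greenwood_band_edges(8, 250.0, 8000.0)
        assert edges.shape == (9,)
        assert edges[0] == 250.0 and edges[-1] == 8000.0
        assert np.all(np.diff(edges) > 0)

    def test_edges_match_closed_form_oracle(self):
        edges = st.greenwood_band_edges(8, 250.0, 8000.0)
        # independent evaluation: uniform cochlear positions mapped by
        # F(x) = 165.4 (10^{2.1 x} - 0.88)
        x_lo = np.log10(250.0 / 165.4 + 0.88) / 2.1
        x_hi = np.log10(8000.0 / 165.4 + 0.88) / 2.1
        xs = np.linspace(x_lo, x_hi, 9)
        ref = 165.4 * (10 ** (2.1 * xs) - 0.88)
        np.testing.assert_allclose(edges[1:-1], ref[1:-1], rtol=1e-12)

    def test_map_round_trip(self):
        f = np.array([300.0, 1000.0, 4000.0])
        np.testing.assert_allclose(greenwood_frequency(greenwood_position(f)), f)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            st.greenwood_band_edges(0)
        with pytest.raises(ValueError):
            st.greenwood_band_edges(8, -1.0, 8000.0)


class TestSpectrogram:
    edges = st.greenwood_band_edges(8, 250.0, 8000.0)

    def test_tone_energy_in_its_band(self):
        t = np.arange(int(2 * FS_AUDIO)) / FS_AUDIO
        sg = st.compute_spectrogram(
            np.sin(2 * np.pi * 1000 * t), FS_AUDIO, self.edges, 100.0
        )
        band = np.searchsorted(self.edges, 1000.0) - 1
        power = sg[50:-50].mean(axis=0)
        assert power[band] / power.sum() > 0.9

    def test_silence_all_zero(self):
        sg = st.compute_spectrogram(
            np.zeros(int(FS_AUDIO)), FS_AUDIO, self.edges, 100.0
        )
        assert np.allclose(sg, 0.0, atol=1e-12)

    def test_white_noise_hits_every_band(self, rng):
        sg = st.compute_spectrogram(
            rng.normal(size=int(2 * FS_AUDIO)), FS_AUDIO, self.edges, 100.0
        )
        assert (sg[50:-50].mean(axis=0) > 0).all()


class TestPhoneticEncoding:
    def test_single_p_activates_its_three_features(self, inventory):
        feats = st.encode_phonetic_features([(0.5, "P")], inventory, 1.0, 100.0)
        row = feats.matrix[50]
        active = {f for f, v in zip(feats.feature_labels, row) if v}
        assert active == {"voiceless", "plosive", "bilabial"}
        assert feats.matrix.sum() == 3
        assert np.all(feats.matrix[np.arange(100) != 50] == 0)

    def test_empty_intervals_zero_matrix(self, inventory):
        feats = st.encode_phonetic_features([], inventory, 1.0, 100.0)
        assert feats.matrix.shape == (100, 19)
        assert not feats.matrix.any()

    def test_total_ones_match_brute_force_tally(self, inventory, rng):
        labels = rng.choice(inventory.phoneme_labels, size=40)
        onsets = np.sort(rng.uniform(0, 9.9, size=40))
        # keep onsets on distinct samples so the tally is exact
        onsets = np.unique(np.round(onsets * 100)) / 100
        labels = labels[: onsets.size]
        ivs = list(zip(onsets, labels))
        feats = st.encode_phonetic_features(ivs, inventory, 10.0, 100.0)
        expected = sum(
            inventory.feature_matrix[inventory.index(l)].sum() for _, l in ivs
        )
        assert feats.matrix.sum() == expected

    def test_unknown_label_named_in_error(self, inventory):
        with pytest.raises(ValueError, match="QQ"):
            st.encode_phonetic_features([(0.1, "QQ")], inventory, 1.0, 100.0)


class TestSurprisalEncoding:
    def test_probability_one_word_codes_zero(self):
        col = st.encode_surprisal(
            [st.WordAnnotation("the", 0.5, 0.0)], 1.0, 100.0
        )
        assert col.matrix.sum() == 0.0

    def test_counts_and_sum_match_tally(self, rng):
        onsets = np.unique(np.round(np.sort(rng.uniform(0, 9.9, 25)) * 100)) / 100
        vals = rng.lognormal(1.0, 0.5, size=onsets.size)
        words = [st.WordAnnotation(f"w{i}", float(t), float(v))
                 for i, (t, v) in enumerate(zip(onsets, vals))]
        col = st.encode_surprisal(words, 10.0, 100.0)
        assert (col.matrix != 0).sum() == len(words)
        assert col.matrix.sum() == pytest.approx(vals.sum())

    def test_collision_sums_with_warning(self):
        words = [st.WordAnnotation("a", 0.501, 1.0),
                 st.WordAnnotation("b", 0.502, 2.0)]
        with pytest.warns(UserWarning, match="summed"):
            col = st.encode_surprisal(words, 1.0, 100.0)
        assert col.matrix[50, 0] == pytest.approx(3.0)

    def test_negative_surprisal_rejected(self):
        with pytest.raises(ValueError):
            st.WordAnnotation("x", 0.1, -0.5)


class TestStimulusMetrics:
    def test_linear_envelope_slope_exact(self):
        fs = 100.0
        m = 2.5
        env = m * np.arange(300) / fs
        words = [st.WordAnnotation("w", 0.5, 1.0)]
        out = st.stimulus_metrics(env, fs, words, 30, 3.0)
        assert out["per_word"]["slope"][0] == pytest.approx(m)

    def test_speech_rate_is_a_ratio(self):
        out = st.stimulus_metrics(np.zeros(100), 100.0, [], 300, 100.0)
        assert out["speech_rate"] == pytest.approx(3.0)

    def test_vocalic_area_shoelace(self):
        out = st.stimulus_metrics(
            np.zeros(100), 100.0, [], 10, 1.0,
            corner_vowel_formants=[(300, 2300), (700, 1200), (300, 800)],
        )
        # shoelace: 0.5 * |300*(1200-800) + 700*(800-2300) + 300*(2300-1200)|
        assert out["vocalic_area"] == pytest.approx(300_000.0)

    def test_word_near_end_flagged_missing(self):
        words = [st.WordAnnotation("w", 0.95, 1.0)]
        out = st.stimulus_metrics(np.zeros(100), 100.0, words, 10, 1.0)
        assert np.isnan(out["per_word"]["slope"][0])
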