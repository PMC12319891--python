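"""Stimulus regressors for speech-encoding models.

Builds the four regressor families used by the encoding analyses:

* broadband speech envelope (Hilbert magnitude, smoothed and resampled);
* band spectrogram with edges spaced along the Greenwood cochlear map
  (default 8 bands spanning 250-8000 Hz);
* sparse phonetic-feature onsets — 19 binary articulatory-feature columns
  with ones at phoneme onsets;
* sparse surprisal-coded word onsets — word surprisal (−log p) at each
  word-onset sample, zero elsewhere;

plus the stimulus characterization metrics (envelope rising slope and peak
around word onsets, speech rate, corner-vowel vocalic area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .inventory import PhonemeInventory

__all__ = [
    "StimulusFeatures",
    "WordAnnotation",
    "compute_envelope",
    "greenwood_band_edges",
    "compute_spectrogram",
    "encode_phonetic_features",
    "encode_surprisal",
    "stimulus_metrics",
]

# human Greenwood map F(x) = A (10^(a x) - k), x in [0, 1]
_GREENWOOD_A = 165.4
_GREENWOOD_ALPHA = 2.1
_GREENWOOD_K = 0.88


@dataclass(frozen=True)
class StimulusFeatures:
    """Time-by-feature regressor matrix at a fixed sampling rate.

    ``kinds`` tags each column ``dense`` (continuous, e.g. envelope) or
    ``sparse`` (onset-coded, zero except at event samples).
    """

    matrix: np.ndarray
    fs: float
    feature_labels: tuple[str, ...]
    kinds: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, float))
        if m.shape[1] != len(self.feature_labels):
            raise ValueError("feature label count does not match matrix columns")
        if np.isnan(m).any():
            raise ValueError("feature matrix contains NaNs")
        kinds = self.kinds or ("dense",) * m.shape[1]
        if len(kinds) != m.shape[1]:
            raise ValueError("one kind tag per feature required")
        if any(k not in ("dense", "sparse") for k in kinds):
            raise ValueError("kinds must be 'dense' or 'sparse'")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "feature_labels", tuple(self.feature_labels))
        object.__setattr__(self, "kinds", tuple(kinds))

    @property
    def n_times(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            return self.matrix[:, self.feature_labels.index(label)]
        except ValueError:
            raise KeyError(f"no feature named {label!r}") from None

    def select(self, labels: list[str]) -> "StimulusFeatures":
        idx = [self.feature_labels.index(l) for l in labels]
        return StimulusFeatures(
            self.matrix[:, idx],
            self.fs,
            tuple(labels),
            tuple(self.kinds[i] for i in idx),
        )

    @staticmethod
    def hstack(parts: list["StimulusFeatures"]) -> "StimulusFeatures":
        fs = parts[0].fs
        n = parts[0].n_times
        if any(p.fs != fs or p.n_times != n for p in parts):
            raise ValueError("all parts must share fs and length")
        return StimulusFeatures(
            np.hstack([p.matrix for p in parts]),
            fs,
            tuple(l for p in parts for l in p.feature_labels),
            tuple(k for p in parts for k in p.kinds),
        )


@dataclass(frozen=True)
class WordAnnotation:
    """A word onset with its contextual surprisal (−log p, in nats)."""

    word: str
    onset: float
    surprisal: float

    def __post_init__(self) -> None:
        if self.surprisal < 0:
            raise ValueError("surprisal must be nonnegative")


def _smooth_resample(
    x: np.ndarray, fs_in: float, fs_out: float, cutoff: float = 30.0
) -> np.ndarray:
    """Low-pass (4th-order Butterworth, zero phase) then polyphase resample."""
    if cutoff < fs_in / 2:
        sos = signal.butter(4, cutoff, btype="low", fs=fs_in, output="sos")
        x = signal.sosfiltfilt(sos, x)
    if fs_out == fs_in:
        return x
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    out = signal.resample_poly(x, frac.numerator, frac.denominator)
    n_new = int(round(len(x) * fs_out / fs_in))
    return out[:n_new] if len(out) >= n_new else np.pad(out, (0, n_new - len(out)))


def compute_envelope(
    audio: np.ndarray, fs_audio: float, target_fs: float, cutoff: float = 30.0
) -> np.ndarray:
    """Broadband amplitude envelope via the Hilbert transform.

    The magnitude of the analytic signal is low-pass smoothed (default
    30 Hz, preventing aliasing into the analysis rate) and resampled to
    ``target_fs``; the result is clipped to be nonnegative.
    """
    audio = np.asarray(audio, float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono; mix multichannel audio down first")
    env = np.abs(signal.hilbert(audio))
    env = _smooth_resample(env, fs_audio, target_fs, cutoff)
    return np.clip(env, 0.0, None)


def greenwood_position(f: np.ndarray) -> np.ndarray:
    """Inverse Greenwood map: frequency (Hz) -> relative cochlear position."""
    f = np.asarray(f, float)
    return np.log10(f / _GREENWOOD_A + _GREENWOOD_K) / _GREENWOOD_ALPHA


def greenwood_frequency(x: np.ndarray) -> np.ndarray:
    """Greenwood map: relative cochlear position in [0, 1] -> frequency (Hz)."""
    x = np.asarray(x, float)
    return _GREENWOOD_A * (10 ** (_GREENWOOD_ALPHA * x) - _GREENWOOD_K)


def greenwood_band_edges(
    n_bands: int = 8, f_lo: float = 250.0, f_hi: float = 8000.0
) -> np.ndarray:
    """Band edges equally spaced along the cochlea between f_lo and f_hi.

    Returns ``n_bands + 1`` strictly increasing frequencies with the first
    and last pinned exactly to ``f_lo`` and ``f_hi``.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    x = np.linspace(greenwood_position(f_lo), greenwood_position(f_hi), n_bands + 1)
    edges = greenwood_frequency(x)
    edges[0], edges[-1] = f_lo, f_hi
    return edges


def compute_spectrogram(
    audio: np.ndarray,
    fs_audio: float,
    edges: np.ndarray,
    target_fs: float,
    cutoff: float = 30.0,
) -> np.ndarray:
    """Per-band Hilbert envelopes (time x n_bands), low band first."""
    audio = np.asarray(audio, float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono; mix multichannel audio down first")
    edges = np.asarray(edges, float)
    cols = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        hi = min(hi, 0.999 * fs_audio / 2)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs_audio, output="sos")
        band = signal.sosfiltfilt(sos, audio)
        env = np.abs(signal.hilbert(band))
        cols.append(np.clip(_smooth_resample(env, fs_audio, target_fs, cutoff), 0, None))
    return np.column_stack(cols)


def encode_phonetic_features(
    intervals: list[tuple[float, str]] | list[tuple[float, float, str]],
    inventory: PhonemeInventory,
    duration: float,
    fs: float,
) -> StimulusFeatures:
    """Sparse onset coding of phonemes on the articulatory-feature basis.

    ``intervals`` holds ``(onset, label)`` or ``(onset, offset, label)``
    tuples in seconds.  For a phoneme onset at sample ``s``, every feature
    active for that phoneme gets a 1 at row ``s``; everything else is 0.
    """
    n = int(round(duration * fs))
    mat = np.zeros((n, inventory.n_features))
    unknown = sorted(
        {iv[-1] for iv in intervals if iv[-1] not in inventory.phoneme_labels}
    )
    if unknown:
        raise ValueError(f"phoneme labels not in inventory: {unknown}")
    for iv in intervals:
        onset, label = iv[0], iv[-1]
        if onset >= duration:
            raise ValueError(f"onset {onset} s beyond duration {duration} s")
        s = int(round(onset * fs))
        if s >= n:
            s = n - 1
        mat[s] = np.maximum(mat[s], inventory.feature_matrix[inventory.index(label)])
    return StimulusFeatures(
        mat, fs, inventory.feature_labels, ("sparse",) * inventory.n_features
    )


def encode_phoneme_onsets(
    intervals: list[tuple[float, str]] | list[tuple[float, float, str]],
    inventory: PhonemeInventory,
    duration: float,
    fs: float,
) -> StimulusFeatures:
    """One sparse onset column per phoneme (the phoneme-domain analogue)."""
    n = int(round(duration * fs))
    mat = np.zeros((n, inventory.n_phonemes))
    for iv in intervals:
        onset, label = iv[0], iv[-1]
        s = min(int(round(onset * fs)), n - 1)
        mat[s, inventory.index(label)] = 1.0
    return StimulusFeatures(
        mat, fs, inventory.phoneme_labels, ("sparse",) * inventory.n_phonemes
    )


def encode_surprisal(
    words: list[WordAnnotation], duration: float, fs: float
) -> StimulusFeatures:
    """Single sparse column: word surprisal at word-onset samples.

    Words whose onsets round to the same sample have their surprisal
    summed (with a warning).
    """
    n = int(round(duration * fs))
    col = np.zeros(n)
    seen: set[int] = set()
    for w in words:
        if w.onset >= duration:
            raise ValueError(f"word onset {w.onset} s beyond duration {duration} s")
        s = min(int(round(w.onset * fs)), n - 1)
        if s in seen:
            warnings.warn(
                f"two word onsets round to sample {s}; surprisal summed",
                stacklevel=2,
            )
        seen.add(s)
        col[s] += w.surprisal
    return StimulusFeatures(col[:, None], fs, ("surprisal",), ("sparse",))


def stimulus_metrics(
    envelope: np.ndarray,
    fs: float,
    words: list[WordAnnotation],
    syllable_count: int,
    duration: float,
    corner_vowel_formants: list[tuple[float, float]] | None = None,
    word_offsets: list[float] | None = None,
    slope_window_s: float = 0.2,
) -> dict:
    """Stimulus characterization metrics.

    Per word: least-squares slope of the envelope over the first 200 ms
    after onset and the maximal envelope value over the word's interval
    (onset to offset; onset to next onset if offsets are not given).
    Global: speech rate (syllables/second) and, if corner-vowel (F1, F2)
    pairs for /a/, /i/, /u/ are given, the vocalic triangle area by the
    shoelace formula (Hz^2).
    """
    envelope = np.asarray(envelope, float)
    n = len(envelope)
    rows = []
    onsets = [w.onset for w in words]
    for i, w in enumerate(words):
        s0 = int(round(w.onset * fs))
        s1 = s0 + int(round(slope_window_s * fs))
        if s1 > n:
            slope = np.nan
        else:
            seg = envelope[s0:s1]
            t = np.arange(len(seg)) / fs
            slope = np.polyfit(t, seg, 1)[0]
        if word_offsets is not None:
            end = word_offsets[i]
        elif i + 1 < len(onsets):
            end = onsets[i + 1]
        else:
            end = duration
        e1 = max(int(round(end * fs)), s0 + 1)
        peak = envelope[s0 : min(e1, n)].max() if s0 < n else np.nan
        rows.append({"word": w.word, "onset": w.onset, "slope": slope, "peak": peak})

    out = {
        "per_word": pd.DataFrame(rows),
        "speech_rate": syllable_count / duration,
    }
    if corner_vowel_formants is not None:
        if len(corner_vowel_formants) != 3:
            raise ValueError("need exactly three corner-vowel (F1, F2) pairs")
        (x1, y1), (x2, y2), (x3, y3) = corner_vowel_formants
        out["vocalic_area"] = 0.5 * abs(
            x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2)
        )
    return out
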