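"""EEG conditioning: resampling, zero-phase band-pass, bad-channel handling.

The conditioning chain used for continuous-speech encoding analyses is
deliberately light: polyphase resampling to the analysis rate (default
100 Hz), a zero-phase Butterworth band-pass restricted to the low
frequencies that track the speech envelope (1-8 Hz, order 2 applied
forward and backward), rejection of channels whose variance exceeds a
multiple of the median channel variance, spherical-spline interpolation of
the rejected channels from their clean neighbours, and optional
re-referencing.  Every operation returns a new :class:`EEGRecording` and
appends itself to the recording's provenance history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

__all__ = [
    "EEGRecording",
    "resample",
    "bandpass_zero_phase",
    "detect_bad_channels",
    "interpolate_channels",
    "rereference",
    "qc_gate",
    "preprocess_chain",
]


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG with metadata and preprocessing provenance.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_times)
        Signal amplitudes (uV by convention).
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
    channel_positions : ndarray, shape (n_channels, 3)
        Unit-sphere sensor coordinates.
    reference : str
        Current reference label.
    history : tuple of dict
        Ordered record of applied operations with their parameters.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    channel_positions: np.ndarray
    reference: str = "none"
    history: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, float)
        pos = np.asarray(self.channel_positions, float)
        if data.ndim != 2:
            raise ValueError("data must be channels x time")
        if not (data.shape[0] == len(self.channel_labels) == pos.shape[0]):
            raise ValueError("channel count mismatch between data/labels/positions")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_positions", pos)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(self, "history", tuple(self.history))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def _evolve(self, data: np.ndarray, op: str, **params) -> "EEGRecording":
        entry = {"op": op, **params}
        return replace(self, data=data, history=self.history + (entry,))


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``target_fs`` (downsampling only).

    The output length is ``round(n_times * target_fs / fs)``.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported; target_fs must be <= fs")
    if target_fs == rec.fs:
        return rec._evolve(rec.data.copy(), "resample", target_fs=target_fs)
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_new = int(round(rec.n_times * target_fs / rec.fs))
    if out.shape[1] >= n_new:
        out = out[:, :n_new]
    else:  # pragma: no cover - polyphase length never undershoots by >1
        out = np.pad(out, ((0, 0), (0, n_new - out.shape[1])))
    new = replace(rec, data=out, fs=float(target_fs))
    return new._evolve(out, "resample", target_fs=float(target_fs))


def bandpass_zero_phase(
    rec: EEGRecording, lo: float = 1.0, hi: float = 8.0, order: int = 2
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (order ``order`` per pass).

    The filter is applied forward and backward (``sosfiltfilt``), doubling
    the effective magnitude order and cancelling phase delay; DC is removed
    by the high-pass edge.
    """
    nyq = rec.fs / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec._evolve(out, "bandpass", lo=lo, hi=hi, order=order)


def detect_bad_channels(rec: EEGRecording, factor: float = 3.0) -> list[str]:
    """Channels whose variance exceeds ``factor`` times the median variance."""
    if rec.n_channels < 3:
        raise ValueError("need at least 3 channels for the variance rule")
    var = rec.data.var(axis=1)
    med = np.median(var)
    return [lab for lab, v in zip(rec.channel_labels, var) if v > factor * med]


def _spline_gram(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    # Legendre series g(x) = 1/(4*pi) * sum_n (2n+1)/(n(n+1))^m P_n(x)
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m / (4 * np.pi)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef)


def interpolate_channels(
    rec: EEGRecording,
    bad: list[str],
    stiffness: int = 4,
    reg: float = 1e-5,
) -> EEGRecording:
    """Replace ``bad`` channels by spherical-spline interpolation.

    Uses the classic spherical-spline scalp-potential interpolant
    (stiffness ``m`` = 4, diagonal regularization 1e-5) fitted on the clean
    channels; positions must lie on the unit sphere.
    """
    if not bad:
        return rec._evolve(rec.data.copy(), "interpolate", bad=[])
    unknown = [b for b in bad if b not in rec.channel_labels]
    if unknown:
        raise ValueError(f"unknown channel labels: {unknown}")
    bad_idx = np.array([rec.channel_labels.index(b) for b in bad])
    good_idx = np.array([i for i in range(rec.n_channels) if i not in set(bad_idx)])
    if good_idx.size < 4:
        raise ValueError("need at least 4 clean channels to interpolate")

    pos = rec.channel_positions / np.linalg.norm(
        rec.channel_positions, axis=1, keepdims=True
    )
    g_good = _spline_gram(pos[good_idx] @ pos[good_idx].T, m=stiffness)
    g_bad = _spline_gram(pos[bad_idx] @ pos[good_idx].T, m=stiffness)

    k = good_idx.size
    # augmented system enforcing sum(c) = 0 alongside the spline fit
    lhs = np.zeros((k + 1, k + 1))
    lhs[:k, :k] = g_good + reg * np.eye(k)
    lhs[:k, k] = 1.0
    lhs[k, :k] = 1.0
    rhs = np.zeros((k + 1, rec.n_times))
    rhs[:k] = rec.data[good_idx]
    sol = np.linalg.solve(lhs, rhs)
    c, mu = sol[:k], sol[k]

    out = rec.data.copy()
    out[bad_idx] = g_bad @ c + mu
    return rec._evolve(out, "interpolate", bad=list(bad))


def rereference(rec: EEGRecording, scheme: str = "none") -> EEGRecording:
    """Re-reference: ``none``, ``average`` or ``channel:<label>``."""
    if scheme == "none":
        out = rec.data.copy()
    elif scheme == "average":
        out = rec.data - rec.data.mean(axis=0, keepdims=True)
    elif scheme.startswith("channel:"):
        label = scheme.split(":", 1)[1]
        if label not in rec.channel_labels:
            raise ValueError(f"unknown reference channel: {label!r}")
        out = rec.data - rec.data[rec.channel_labels.index(label)]
    else:
        raise ValueError(f"unknown reference scheme: {scheme!r}")
    new = replace(rec, reference=scheme)
    return new._evolve(out, "rereference", scheme=scheme)


def qc_gate(
    n_interpolated: int,
    rejected_fraction: float = 0.0,
    max_interpolated: int = 4,
    max_rejected_fraction: float = 0.3,
) -> bool:
    """Participant-level quality gate.

    Returns True if the recording passes (few enough interpolated
    electrodes and little enough rejected data); emits a warning otherwise.
    """
    ok = (
        n_interpolated <= max_interpolated
        and rejected_fraction <= max_rejected_fraction
    )
    if not ok:
        warnings.warn(
            f"QC gate failed: {n_interpolated} interpolated electrodes, "
            f"{rejected_fraction:.0%} rejected data",
            stacklevel=2,
        )
    return ok


def preprocess_chain(
    rec: EEGRecording,
    target_fs: float = 100.0,
    lo: float = 1.0,
    hi: float = 8.0,
    order: int = 2,
    bad_factor: float = 3.0,
    reference: str = "none",
) -> tuple[EEGRecording, list[str]]:
    """The documented chain: resample, band-pass, reject, interpolate.

    Returns the conditioned recording and the list of interpolated channels.
    """
    out = resample(rec, target_fs)
    out = bandpass_zero_phase(out, lo=lo, hi=hi, order=order)
    bad = detect_bad_channels(out, factor=bad_factor)
    out = interpolate_channels(out, bad)
    if reference != "none":
        out = rereference(out, reference)
    qc_gate(len(bad))
    return out, bad
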