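"""Phoneme distance maps: rotation, embedding, and alignment.

Phonetic-feature TRF weights are rotated into the phoneme domain through
the inventory's binary feature-to-phoneme indicator matrix.  Pairwise
Euclidean distances between the phonemes' weight vectors (flattened over
selected lags and channels) summarize how distinctly the EEG encodes each
phoneme pair; classical (Torgerson) multidimensional scaling embeds the
distance matrix, a similarity Procrustes transform (translation,
orthogonal transform with reflections, isotropic scale) aligns each
embedding to a reference map, and per-phoneme residual distances quantify
the remaining misfit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inventory import PhonemeInventory
from .trf import TRFModel

__all__ = [
    "PhonemeWeights",
    "PhonemeMap",
    "AlignmentResult",
    "rotate_to_phonemes",
    "phoneme_distance_matrix",
    "classical_mds",
    "procrustes_align",
    "map_from_weights",
    "residual_distance_table",
]


@dataclass(frozen=True)
class PhonemeWeights:
    """TRF weights rotated to the phoneme domain: (lag, phoneme, channel)."""

    weights: np.ndarray
    phoneme_labels: tuple[str, ...]
    lag_window: tuple[float, float]
    fs: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 3 or w.shape[1] != len(self.phoneme_labels):
            raise ValueError("weights must be (lag, phoneme, channel)")
        if not np.isfinite(w).all():
            raise ValueError("non-finite phoneme weights")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "phoneme_labels", tuple(self.phoneme_labels))

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lag_window[0] + np.arange(self.weights.shape[0]) * 1000.0 / self.fs


@dataclass(frozen=True)
class PhonemeMap:
    """Phoneme coordinates in a k-dim space plus their source distances."""

    coordinates: np.ndarray
    distance_matrix: np.ndarray
    phoneme_labels: tuple[str, ...]
    k: int
    provenance: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_matrix, float)
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("invalid distance matrix")
        if self.coordinates.shape[0] != len(self.phoneme_labels):
            raise ValueError("coordinate row count must match phoneme count")


@dataclass(frozen=True)
class AlignmentResult:
    """Similarity-Procrustes fit of a source map onto a reference."""

    transformed: np.ndarray
    per_phoneme_residual: np.ndarray
    dissimilarity: float
    scale: float
    rotation: np.ndarray
    translation: np.ndarray


def rotate_to_phonemes(
    model: TRFModel,
    inventory: PhonemeInventory,
    normalize: bool = False,
) -> PhonemeWeights:
    """Rotate phonetic-feature weights into the phoneme domain.

    ``W_p[l, p, c] = sum_f M[p, f] W_f[l, f, c]`` with ``M`` the binary
    feature indicator of the inventory; ``normalize=True`` divides each
    phoneme row by its active-feature count (averaging instead of
    summing).
    """
    missing = [f for f in inventory.feature_labels
               if f not in model.feature_labels]
    if missing:
        raise ValueError(f"model lacks phonetic-feature columns: {missing}")
    cols = [model.feature_labels.index(f) for f in inventory.feature_labels]
    wf = model.weights[:, cols, :]
    M = inventory.feature_matrix
    if normalize:
        M = M / M.sum(axis=1, keepdims=True)
    wp = np.einsum("pf,lfc->lpc", M, wf)
    return PhonemeWeights(wp, inventory.phoneme_labels, model.lag_window, model.fs)


def phoneme_distance_matrix(
    pw: PhonemeWeights,
    window: tuple[float, float] | None = None,
    channels: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Pairwise Euclidean distances between phoneme weight vectors.

    Each phoneme's vector is its weights flattened over the selected lags
    and channels (defaults: the full lag window, all channels).
    """
    lags = pw.lags_ms
    if window is None:
        keep = np.arange(lags.size)
    else:
        lo, hi = window
        keep = np.flatnonzero((lags >= lo - 1e-9) & (lags <= hi + 1e-9))
    if keep.size == 0:
        raise ValueError("empty lag selection")
    w = pw.weights[keep]
    if channels is not None:
        channels = np.asarray(channels, int)
        if channels.size == 0:
            raise ValueError("empty channel selection")
        w = w[:, :, channels]
    flat = w.transpose(1, 0, 2).reshape(w.shape[1], -1)
    from scipy.spatial.distance import squareform, pdist

    return squareform(pdist(flat, metric="euclidean"))


def classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and keeps the
    top-k positive-eigenvalue axes.  If fewer than ``k`` eigenvalues are
    positive the embedding is truncated with a warning; the remaining
    columns are zero so the output shape stays (n, k).
    """
    D = np.asarray(D, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding truncated from "
            f"k={k}",
            stacklevel=2,
        )
    if (vals[: max(n_pos, 1)] < -1e-9 * max(vals.max(), 1)).any():  # pragma: no cover
        warnings.warn("negative eigenvalues clipped", stacklevel=2)
    coords = np.zeros((n, k))
    m = min(k, n_pos)
    coords[:, :m] = vecs[:, :m] * np.sqrt(vals[:m])
    return coords


def procrustes_align(source: np.ndarray, reference: np.ndarray) -> AlignmentResult:
    """Similarity Procrustes: fit ``source`` onto ``reference``.

    Finds translation, orthogonal transform (reflections permitted) and
    isotropic scale minimizing the summed squared misfit.  The normalized
    dissimilarity is the residual sum of squares divided by the centered
    reference's sum of squares, in [0, 1]; per-phoneme residuals are the
    Euclidean distances between transformed source and reference points.
    """
    S = np.asarray(source, float)
    R = np.asarray(reference, float)
    if S.shape != R.shape:
        raise ValueError("source and reference must have the same shape")
    mu_s, mu_r = S.mean(axis=0), R.mean(axis=0)
    Sc, Rc = S - mu_s, R - mu_r
    ns, nr = np.linalg.norm(Sc), np.linalg.norm(Rc)
    if ns == 0:
        raise ValueError("degenerate source configuration (all points equal)")
    if nr == 0:
        raise ValueError("degenerate reference configuration")
    U, sv, Vt = np.linalg.svd(Rc.T @ Sc / (nr * ns))
    Q = (U @ Vt).T  # maps source -> reference frame
    scale = sv.sum() * nr / ns
    transformed = scale * Sc @ Q + mu_r
    resid = np.linalg.norm(transformed - R, axis=1)
    dissimilarity = float(max(0.0, 1.0 - sv.sum() ** 2))
    translation = mu_r - scale * mu_s @ Q
    return AlignmentResult(transformed, resid, dissimilarity, float(scale), Q,
                           translation)


def map_from_weights(
    pw: PhonemeWeights,
    k: int = 2,
    window: tuple[float, float] | None = None,
    channels=None,
    provenance: str = "",
) -> PhonemeMap:
    """Distance matrix + classical MDS embedding in one step."""
    D = phoneme_distance_matrix(pw, window=window, channels=channels)
    coords = classical_mds(D, k=k)
    return PhonemeMap(coords, D, pw.phoneme_labels, k, provenance)


def residual_distance_table(
    cohort_maps: dict[tuple, PhonemeMap],
    reference: PhonemeMap,
) -> pd.DataFrame:
    """Align every cohort map to the reference; tidy per-phoneme residuals.

    ``cohort_maps`` maps ``(participant, condition)`` to a PhonemeMap;
    every map (and the reference) must share the phoneme inventory.
    Returns one row per participant x condition x phoneme.
    """
    rows = []
    for (participant, condition), pm in cohort_maps.items():
        if pm.phoneme_labels != reference.phoneme_labels:
            raise ValueError(
                f"phoneme inventory mismatch for ({participant}, {condition})"
            )
        res = procrustes_align(pm.coordinates, reference.coordinates)
        for ph, r in zip(pm.phoneme_labels, res.per_phoneme_residual):
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "phoneme": ph,
                    "residual": r,
                }
            )
    return pd.DataFrame(rows)
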