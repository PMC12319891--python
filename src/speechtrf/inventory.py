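"""Phoneme inventory and the binary articulatory-feature basis.

Phonetic-feature encoding models describe each phoneme as a linear
combination of binary articulatory descriptors (voicing, manner, place for
consonants; frontness, height, diphthong status for vowels).  The module
ships a general-American ARPAbet inventory (39 phonemes) coded on the
19-dimensional feature set used throughout the package:

voiced, voiceless, plosive, fricative, affricate, nasal, liquid, glide,
front, back, central, diphthong, close, open, bilabial, labiodental,
dental, alveopalatal, velar-glottal.

Because the place axis is collapsed to five categories, a handful of
assignments are pragmatic rather than strictly phonetic: /s z/ carry both
``dental`` and ``alveopalatal`` to keep them distinct from both the
interdental and the postalveolar fricatives, /r/ and the rhotic vowel ER
carry ``central``, lax vowels carry ``central`` in addition to their
frontness, and /w/ is coded labio-velar.  Every phoneme row is unique, so
the feature-to-phoneme indicator matrix has full row rank structure
suitable for rotating feature-domain regression weights into the phoneme
domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEATURE_LABELS: tuple[str, ...] = (
    "voiced",
    "voiceless",
    "plosive",
    "fricative",
    "affricate",
    "nasal",
    "liquid",
    "glide",
    "front",
    "back",
    "central",
    "diphthong",
    "close",
    "open",
    "bilabial",
    "labiodental",
    "dental",
    "alveopalatal",
    "velar-glottal",
)

# phoneme -> active features (ARPAbet, general American)
_ARPABET_FEATURES: dict[str, tuple[str, ...]] = {
    # plosives
    "P": ("voiceless", "plosive", "bilabial"),
    "B": ("voiced", "plosive", "bilabial"),
    "T": ("voiceless", "plosive", "alveopalatal"),
    "D": ("voiced", "plosive", "alveopalatal"),
    "K": ("voiceless", "plosive", "velar-glottal"),
    "G": ("voiced", "plosive", "velar-glottal"),
    # affricates
    "CH": ("voiceless", "affricate", "alveopalatal"),
    "JH": ("voiced", "affricate", "alveopalatal"),
    # fricatives
    "F": ("voiceless", "fricative", "labiodental"),
    "V": ("voiced", "fricative", "labiodental"),
    "TH": ("voiceless", "fricative", "dental"),
    "DH": ("voiced", "fricative", "dental"),
    "S": ("voiceless", "fricative", "dental", "alveopalatal"),
    "Z": ("voiced", "fricative", "dental", "alveopalatal"),
    "SH": ("voiceless", "fricative", "alveopalatal"),
    "ZH": ("voiced", "fricative", "alveopalatal"),
    "HH": ("voiceless", "fricative", "velar-glottal"),
    # nasals
    "M": ("voiced", "nasal", "bilabial"),
    "N": ("voiced", "nasal", "alveopalatal"),
    "NG": ("voiced", "nasal", "velar-glottal"),
    # liquids
    "L": ("voiced", "liquid", "alveopalatal"),
    "R": ("voiced", "liquid", "central", "alveopalatal"),
    # glides
    "W": ("voiced", "glide", "bilabial", "velar-glottal"),
    "Y": ("voiced", "glide", "alveopalatal"),
    # monophthong vowels
    "IY": ("front", "close"),
    "IH": ("front", "central", "close"),
    "EH": ("front", "central"),
    "AE": ("front", "open"),
    "AA": ("central", "open"),
    "AO": ("back", "open"),
    "UW": ("back", "close"),
    "UH": ("back", "central", "close"),
    "AH": ("central",),
    "ER": ("central", "liquid"),
    # diphthongs
    "EY": ("diphthong", "front"),
    "AY": ("diphthong", "front", "open"),
    "AW": ("diphthong", "back", "open"),
    "OY": ("diphthong", "back", "close"),
    "OW": ("diphthong", "back"),
}


@dataclass(frozen=True)
class PhonemeInventory:
    """A phoneme set together with its binary articulatory-feature coding.

    Attributes
    ----------
    phoneme_labels : tuple of str
        Phoneme identifiers (ARPAbet-style).
    feature_matrix : ndarray, shape (n_phonemes, n_features)
        Binary indicator; entry (p, f) is 1 iff feature ``f`` is active for
        phoneme ``p``.
    feature_labels : tuple of str
        The 19 articulatory-feature names, fixed order.
    """

    phoneme_labels: tuple[str, ...]
    feature_matrix: np.ndarray
    feature_labels: tuple[str, ...] = field(default=FEATURE_LABELS)

    def __post_init__(self) -> None:
        m = np.asarray(self.feature_matrix)
        if m.shape != (len(self.phoneme_labels), len(self.feature_labels)):
            raise ValueError(
                f"feature_matrix shape {m.shape} does not match "
                f"{len(self.phoneme_labels)} phonemes x "
                f"{len(self.feature_labels)} features"
            )
        if not np.isin(m, (0, 1)).all():
            raise ValueError("feature_matrix entries must be 0 or 1")
        if (m.sum(axis=1) < 1).any():
            bad = [p for p, row in zip(self.phoneme_labels, m) if row.sum() < 1]
            raise ValueError(f"phonemes with no active feature: {bad}")
        if len({tuple(row) for row in m.astype(int)}) != len(self.phoneme_labels):
            raise ValueError("two phonemes share an identical feature row")
        object.__setattr__(self, "feature_matrix", m.astype(float))

    @property
    def n_phonemes(self) -> int:
        return len(self.phoneme_labels)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)

    def index(self, phoneme: str) -> int:
        try:
            return self.phoneme_labels.index(phoneme)
        except ValueError:
            raise KeyError(f"unknown phoneme label: {phoneme!r}") from None

    def features_of(self, phoneme: str) -> tuple[str, ...]:
        """Names of the active features of ``phoneme``."""
        row = self.feature_matrix[self.index(phoneme)]
        return tuple(f for f, v in zip(self.feature_labels, row) if v)

    def subset(self, phonemes: list[str]) -> "PhonemeInventory":
        """Restrict the inventory to ``phonemes`` (order preserved)."""
        idx = [self.index(p) for p in phonemes]
        return PhonemeInventory(
            tuple(phonemes), self.feature_matrix[idx], self.feature_labels
        )


def default_inventory() -> PhonemeInventory:
    """The shipped 39-phoneme ARPAbet inventory on the 19-feature basis."""
    labels = tuple(_ARPABET_FEATURES)
    mat = np.zeros((len(labels), len(FEATURE_LABELS)))
    for i, ph in enumerate(labels):
        for f in _ARPABET_FEATURES[ph]:
            mat[i, FEATURE_LABELS.index(f)] = 1.0
    return PhonemeInventory(labels, mat)
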