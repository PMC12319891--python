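"""File I/O: portable HDF5 containers, EEG readers, annotation formats.

The package's portable array container is a small HDF5 layout::

    /eeg        channels x time (float64)
    /fs         scalar
    /labels     channel labels (UTF-8)
    /positions  channels x 3 unit-sphere coordinates
    /history    JSON-encoded preprocessing provenance

BrainVision (.vhdr) and BioSemi (.bdf) recordings are read through MNE
when available.  Phoneme/word alignments are accepted as Praat TextGrid
interval tiers (a minimal reader/writer is included) or tab-separated
``onset  offset  label`` files; per-word surprisal as CSV with columns
``word, onset_s, surprisal``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import WordAnnotation
from .montage import default_montage
from .preprocess import EEGRecording
from .trf import TRFModel

__all__ = [
    "save_recording",
    "load_recording",
    "save_trf",
    "load_trf",
    "read_brainvision",
    "read_bdf",
    "read_intervals_tsv",
    "write_intervals_tsv",
    "read_textgrid",
    "write_textgrid",
    "read_surprisal_csv",
    "write_surprisal_csv",
]


# ---------------------------------------------------------------- containers

def save_recording(rec: EEGRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=rec.data)
        f["fs"] = rec.fs
        f.create_dataset(
            "labels", data=np.array(rec.channel_labels, dtype=h5py.string_dtype())
        )
        f.create_dataset("positions", data=rec.channel_positions)
        f["reference"] = rec.reference
        f["history"] = json.dumps(list(rec.history))


def load_recording(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        return EEGRecording(
            f["eeg"][()],
            float(f["fs"][()]),
            tuple(s.decode() for s in f["labels"][()]),
            f["positions"][()],
            reference=f["reference"][()].decode(),
            history=tuple(json.loads(f["history"][()].decode())),
        )


def save_trf(model: TRFModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.create_dataset("bias", data=model.bias)
        f["lambda"] = model.lam
        f["lag_window"] = np.asarray(model.lag_window, float)
        f["fs"] = model.fs
        f.create_dataset(
            "feature_labels",
            data=np.array(model.feature_labels, dtype=h5py.string_dtype()),
        )
        if model.feature_scale is not None:
            f.create_dataset("feature_scale", data=model.feature_scale)


def load_trf(path) -> TRFModel:
    with h5py.File(path, "r") as f:
        scale = f["feature_scale"][()] if "feature_scale" in f else None
        return TRFModel(
            f["weights"][()],
            f["bias"][()],
            float(f["lambda"][()]),
            tuple(f["lag_window"][()]),
            float(f["fs"][()]),
            tuple(s.decode() for s in f["feature_labels"][()]),
            scale,
        )


# ---------------------------------------------------------------- EEG readers

def _from_mne_raw(raw) -> EEGRecording:
    data = raw.get_data(picks="eeg") * 1e6  # volts -> microvolts
    labels = [raw.ch_names[i] for i in
              [raw.ch_names.index(ch) for ch in raw.copy().pick("eeg").ch_names]]
    montage_labels, montage_pos = default_montage()
    lookup = {l.lower(): p for l, p in zip(montage_labels, montage_pos)}
    pos = np.array([lookup.get(l.lower(), (np.nan,) * 3) for l in labels])
    return EEGRecording(data, float(raw.info["sfreq"]), tuple(labels), pos,
                        history=({"op": "load", "source": "mne"},))


def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision (.vhdr/.vmrk/.eeg) recording (requires MNE)."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _from_mne_raw(raw)


def read_bdf(bdf_path) -> EEGRecording:
    """Read a BioSemi .bdf recording (requires MNE)."""
    import mne

    raw = mne.io.read_raw_bdf(bdf_path, preload=True, verbose="error")
    return _from_mne_raw(raw)


# ---------------------------------------------------------------- alignments

def read_intervals_tsv(path) -> list[tuple[float, float, str]]:
    """Tab-separated ``onset<TAB>offset<TAB>label`` intervals."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["onset", "offset", "label"])
    return [
        (float(r.onset), float(r.offset), str(r.label)) for r in df.itertuples()
    ]


def write_intervals_tsv(intervals, path) -> None:
    pd.DataFrame(intervals, columns=["onset", "offset", "label"]).to_csv(
        path, sep="\t", header=False, index=False
    )


_TG_FLOAT = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"


def read_textgrid(path, tier: str) -> list[tuple[float, float, str]]:
    """Intervals of one named tier of a Praat TextGrid (long text format)."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    tiers = re.split(r'item\s*\[\d+\]\s*:', text)[1:]
    for block in tiers:
        name_m = re.search(r'name\s*=\s*"([^"]*)"', block)
        if not name_m or name_m.group(1) != tier:
            continue
        out = []
        for m in re.finditer(
            rf'xmin\s*=\s*({_TG_FLOAT})\s*xmax\s*=\s*({_TG_FLOAT})\s*'
            rf'text\s*=\s*"([^"]*)"',
            block,
        ):
            label = m.group(3).strip()
            if label:
                out.append((float(m.group(1)), float(m.group(2)), label))
        return out
    raise ValueError(f"tier {tier!r} not found in {path}")


def write_textgrid(tiers: dict[str, list[tuple[float, float, str]]],
                   path, xmax: float | None = None) -> None:
    """Write interval tiers as a (long-format) Praat TextGrid."""
    if xmax is None:
        xmax = max((iv[1] for t in tiers.values() for iv in t), default=1.0)
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for i, (name, ivs) in enumerate(tiers.items(), 1):
        lines += [
            f"    item [{i}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {xmax}",
            f"        intervals: size = {len(ivs)}",
        ]
        for j, (a, b, lab) in enumerate(ivs, 1):
            lines += [
                f"        intervals [{j}]:",
                f"            xmin = {a}",
                f"            xmax = {b}",
                f'            text = "{lab}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------- surprisal

def read_surprisal_csv(path) -> list[WordAnnotation]:
    """CSV with columns ``word, onset_s, surprisal``."""
    df = pd.read_csv(path)
    required = {"word", "onset_s", "surprisal"}
    if not required.issubset(df.columns):
        raise ValueError(f"surprisal CSV must have columns {sorted(required)}")
    return [
        WordAnnotation(str(r.word), float(r.onset_s), float(r.surprisal))
        for r in df.itertuples()
    ]


def write_surprisal_csv(words: list[WordAnnotation], path) -> None:
    pd.DataFrame(
        [{"word": w.word, "onset_s": w.onset, "surprisal": w.surprisal}
         for w in words]
    ).to_csv(path, index=False)
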