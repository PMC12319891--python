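"""Sensor montage utilities.

A 64-channel montage with 10-20 extended labels is shipped with the
package as a plain CSV of unit-sphere coordinates.  Positions are used for
simulated scalp topographies, spherical-spline channel interpolation, and
the spatial adjacency of the cluster-based permutation test.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_montage", "default_montage"]


def load_montage(path) -> tuple[list[str], np.ndarray]:
    """Read a montage CSV (columns label, x, y, z).

    Returns ``(labels, positions)`` with positions as an (n, 3) float array.
    """
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage file must have columns {sorted(required)}")
    pos = df[["x", "y", "z"]].to_numpy(float)
    if not np.isfinite(pos).all():
        raise ValueError("non-finite sensor positions")
    return df["label"].astype(str).tolist(), pos


def default_montage() -> tuple[list[str], np.ndarray]:
    """The shipped 64-channel 10-20 extended montage on the unit sphere."""
    ref = resources.files("speechtrf.data").joinpath("montage64.csv")
    with resources.as_file(ref) as p:
        return load_montage(p)
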