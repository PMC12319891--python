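"""ERP-like component metrics read off TRF weights.

TRF weights of a forward model play the role that evoked-response
averages play in epoched designs: the envelope TRF shows an early
negative/positive complex (N1-P2) and the surprisal TRF a late
centro-parietal negativity (an N400-like response).  The metrics here are
the peak-to-peak N1-P2 amplitude in a search window (default 30-180 ms),
the signed mean surprisal weight in a late window (e.g. 440-640 ms), and
the correlation of a channel-averaged component value with behavioral
scores across observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .trf import TRFModel

__all__ = [
    "n1p2",
    "n400_window_amplitude",
    "component_table",
    "behavior_correlation",
]


def _window_slice(model: TRFModel, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ValueError("empty component window")
    tmin, tmax = model.lag_window
    if lo < tmin or hi > tmax:
        raise ValueError(
            f"window {window} ms outside model lag window {model.lag_window} ms"
        )
    lags = model.lags_ms
    idx = np.flatnonzero((lags >= lo - 1e-9) & (lags <= hi + 1e-9))
    if idx.size == 0:
        raise ValueError("component window contains no lag samples")
    return idx


def n1p2(
    model: TRFModel,
    feature: str = "env",
    window: tuple[float, float] = (30.0, 180.0),
) -> pd.DataFrame:
    """Peak-to-peak N1-P2 amplitude per channel.

    Per electrode, N1 is the most negative and P2 the most positive
    weight of ``feature`` inside ``window``; the value is P2 − N1 (always
    nonnegative).  No N1-before-P2 ordering is imposed, and extrema at the
    window edges are accepted but flagged (``at_edge``) for auditability.
    """
    idx = _window_slice(model, window)
    w = model.kernel(feature)[idx]  # (n_window_lags, n_channels)
    lags = model.lags_ms[idx]
    i_min = w.argmin(axis=0)
    i_max = w.argmax(axis=0)
    value = w.max(axis=0) - w.min(axis=0)
    at_edge = np.isin(i_min, (0, len(idx) - 1)) | np.isin(i_max, (0, len(idx) - 1))
    return pd.DataFrame(
        {
            "channel": np.arange(w.shape[1]),
            "value": value,
            "n1_latency_ms": lags[i_min],
            "p2_latency_ms": lags[i_max],
            "at_edge": at_edge,
            "component": "N1P2",
        }
    )


def n400_window_amplitude(
    model: TRFModel,
    feature: str = "surprisal",
    window: tuple[float, float] = (440.0, 640.0),
) -> pd.DataFrame:
    """Signed mean surprisal weight per channel in a late window.

    More negative values indicate a stronger N400-like response.
    """
    idx = _window_slice(model, window)
    w = model.kernel(feature)[idx]
    return pd.DataFrame(
        {
            "channel": np.arange(w.shape[1]),
            "value": w.mean(axis=0),
            "component": "N400",
        }
    )


def component_table(
    models: dict[tuple, TRFModel],
    component: str = "N1P2",
    feature: str = "env",
    window: tuple[float, float] = (30.0, 180.0),
    channel_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy cohort table: participant, condition, channel, component, value.

    ``models`` maps ``(participant, condition)`` to a fitted TRF.  The
    table is ready for group-level mixed-model fits in external tools.
    """
    fn = {"N1P2": n1p2, "N400": n400_window_amplitude}[component]
    rows = []
    for (participant, condition), model in models.items():
        df = fn(model, feature=feature, window=window)
        df.insert(0, "participant", participant)
        df.insert(1, "condition", condition)
        df["window_lo_ms"], df["window_hi_ms"] = window
        if channel_labels is not None:
            df["channel"] = [channel_labels[c] for c in df["channel"]]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def behavior_correlation(
    component_values: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between component amplitudes and behavior.

    ``component_values`` are channel-averaged component amplitudes, one
    per participant-by-condition observation; ``scores`` the matching
    behavioral scores (e.g. comprehension accuracy).  Returns ``(r, p)``.
    """
    x = np.asarray(component_values, float)
    y = np.asarray(scores, float)
    if x.shape != y.shape:
        raise ValueError("component values and scores must be matched")
    if x.size < 3:
        raise ValueError("need at least 3 observation pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
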