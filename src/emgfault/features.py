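"""Window-level time-domain features and the classification feature table.

Five features per window per channel, using the standard myoelectric
pattern-recognition definitions:

    MAV = (1/N) sum |x_i|                 mean absolute value
    RMS = sqrt((1/N) sum x_i^2)           root mean square
    WL  = sum |x_{i+1} - x_i|             waveform length
    MFL = log10(sqrt(sum (x_{i+1}-x_i)^2))  maximum fractal length
    PWR = (1/N) sum x_i^2                 mean power

All are invariant under sign flip, so they can be computed on the signed
normalized view (the default) or the rectified view interchangeably for MAV,
RMS and PWR; WL and MFL differ between views, and the signed view is used
because rectification discards slope information.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preprocess import WindowStream
from .synthetic import EmgRecording

__all__ = ["FEATURE_NAMES", "MFL_SENTINEL", "feature_vector", "feature_matrix",
           "build_feature_table", "feature_columns"]

log = logging.getLogger(__name__)

FEATURE_NAMES = ("mav", "rms", "wl", "mfl", "pwr")

#: MFL of a constant window (log of zero); large negative sentinel
MFL_SENTINEL = -16.0


class Features(NamedTuple):
    mav: float
    rms: float
    wl: float
    mfl: float
    pwr: float


def feature_matrix(windows: np.ndarray) -> np.ndarray:
    """Features for a stack of windows: (k, N) -> (k, 5) in FEATURE_NAMES order."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[1] < 2:
        raise ValueError("windows must be (k, N>=2)")
    mav = np.mean(np.abs(windows), axis=1)
    pwr = np.mean(windows**2, axis=1)
    rms = np.sqrt(pwr)
    d = np.diff(windows, axis=1)
    wl = np.sum(np.abs(d), axis=1)
    ss = np.sum(d**2, axis=1)
    mfl = np.where(ss > 0, 0.5 * np.log10(np.where(ss > 0, ss, 1.0)), MFL_SENTINEL)
    if np.any(ss == 0):
        log.warning("constant window(s): MFL set to sentinel %.1f", MFL_SENTINEL)
    return np.column_stack([mav, rms, wl, mfl, pwr])


def feature_vector(window: np.ndarray) -> Features:
    """The five features of a single window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return Features(*feature_matrix(window[None, :])[0])


def feature_columns(n_channels: int) -> list[str]:
    """Fixed column order: channel-major, features in FEATURE_NAMES order."""
    return [f"ch{c + 1}_{f}" for c in range(n_channels) for f in FEATURE_NAMES]


def build_feature_table(
    stream: WindowStream, recording: EmgRecording, provenance: str = "clean"
) -> pd.DataFrame:
    """One row per window position: all channels' features plus bookkeeping.

    Columns are ``ch{c}_{feat}`` in the fixed order of
    :func:`feature_columns`, then ``label`` (majority window label),
    ``repetition`` (majority, 0 for rest), ``fold_repetition`` (the
    repetition of the nearest preceding movement window, so rest windows can
    be assigned to cross-validation folds) and ``provenance``.
    """
    if stream.n_channels != recording.n_channels:
        raise ValueError("stream/recording channel mismatch")
    if stream.starts[-1] + stream.length > recording.n_samples:
        raise ValueError("stream extends past the recording")
    idx = stream.starts[:, None] + np.arange(stream.length)[None, :]
    blocks = [
        feature_matrix(recording.signal[:, c][idx])
        for c in range(recording.n_channels)
    ]
    table = pd.DataFrame(
        np.hstack(blocks), columns=feature_columns(recording.n_channels)
    )
    table["label"] = stream.labels
    table["repetition"] = stream.repetitions
    fold_rep = np.asarray(stream.repetitions, dtype=int).copy()
    last = 1
    for i in range(len(fold_rep)):
        if stream.labels[i] > 0 and fold_rep[i] > 0:
            last = fold_rep[i]
        else:
            fold_rep[i] = last
    table["fold_repetition"] = fold_rep
    table["provenance"] = provenance
    if table[feature_columns(recording.n_channels)].isna().any().any():
        raise ValueError("feature table contains missing values")
    return table
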