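"""Recording IO and the standard sEMG preprocessing chain.

The chain is: order-20 Butterworth band-pass (20-500 Hz at 2 kS/s, realized as
cascaded second-order sections and applied zero-phase), per-channel max-abs
normalization over the full record, rectification where magnitude is needed,
and segmentation into 300 ms sliding windows advanced in 75 ms increments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic import EmgRecording

__all__ = [
    "PreprocessConfig",
    "WindowStream",
    "design_bandpass",
    "half_power_frequencies",
    "bandpass_filter",
    "rectify_normalize",
    "segment_windows",
    "window_count",
    "read_recording",
    "write_recording",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter band/order, sampling rate and sliding-window geometry."""

    band_low: float = 20.0
    band_high: float = 500.0
    filter_order: int = 20
    fs: float = 2000.0
    window_ms: float = 300.0
    increment_ms: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.fs / 2):
            raise ValueError("need 0 < band_low < band_high < fs/2")
        if self.filter_order <= 0 or self.filter_order % 2:
            raise ValueError("filter_order must be a positive even integer")
        if not (self.window_ms >= self.increment_ms > 0):
            raise ValueError("need window_ms >= increment_ms > 0")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs / 1000.0))

    @property
    def increment_samples(self) -> int:
        return int(round(self.increment_ms * self.fs / 1000.0))


def design_bandpass(cfg: PreprocessConfig) -> np.ndarray:
    """Second-order sections of the band-pass Butterworth filter.

    ``filter_order`` is the overall band-pass order; scipy's ``butter`` takes
    the low-pass prototype order, i.e. ``filter_order // 2``.  A direct-form
    order-20 transfer function is numerically unstable at these edge
    frequencies, hence the SOS realization.
    """
    return sps.butter(
        cfg.filter_order // 2,
        [cfg.band_low, cfg.band_high],
        btype="bandpass",
        fs=cfg.fs,
        output="sos",
    )


def half_power_frequencies(
    cfg: PreprocessConfig | None = None, n_grid: int = 1 << 18
) -> tuple[float, float]:
    """Lower and upper -3 dB (1/sqrt(2) magnitude) frequencies of the filter.

    Evaluated on a dense frequency grid with linear interpolation at the
    crossings.  For a Butterworth band-pass these sit at the design edges.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    sos = design_bandpass(cfg)
    w, h = sps.sosfreqz(sos, worN=n_grid, fs=cfg.fs)
    mag = np.abs(h)
    thr = 1.0 / np.sqrt(2.0)
    above = mag >= thr
    if not above.any():
        raise ValueError("filter response never reaches the half-power level")
    idx = np.flatnonzero(above)
    lo_i, hi_i = idx[0], idx[-1]

    def _interp(i0: int, i1: int) -> float:
        m0, m1 = mag[i0], mag[i1]
        if m1 == m0:
            return float(w[i0])
        frac = (thr - m0) / (m1 - m0)
        return float(w[i0] + frac * (w[i1] - w[i0]))

    f_lo = _interp(lo_i - 1, lo_i) if lo_i > 0 else float(w[0])
    f_hi = _interp(hi_i + 1, hi_i) if hi_i + 1 < len(w) else float(w[-1])
    return f_lo, f_hi


def bandpass_filter(
    recording: EmgRecording, cfg: PreprocessConfig | None = None
) -> EmgRecording:
    """Zero-phase band-pass of every channel; shape preserved."""
    if cfg is None:
        cfg = PreprocessConfig(fs=recording.fs)
    if recording.fs != cfg.fs:
        raise ValueError("recording sampling rate inconsistent with config")
    sos = design_bandpass(cfg)
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=0)
    out = recording.copy()
    out.signal = filtered
    out.meta["filtered"] = True
    return out


def rectify_normalize(
    recording: EmgRecording,
) -> tuple[EmgRecording, EmgRecording]:
    """Per-channel max-abs normalization over the full record.

    Returns (signed_view, rectified_view).  The signed view keeps polarity
    (virtual-sensor models assume sign-preserving dynamics); the rectified
    view is its absolute value.  An identically-zero channel passes through
    unscaled with a logged warning.
    """
    x = recording.signal
    peak = np.max(np.abs(x), axis=0)
    zero = peak == 0
    if zero.any():
        log.warning(
            "channels %s are identically zero; left unscaled",
            np.flatnonzero(zero).tolist(),
        )
    scale = np.where(zero, 1.0, peak)
    signed = recording.copy()
    signed.signal = x / scale
    signed.meta["normalized"] = True
    rectified = signed.copy()
    rectified.signal = np.abs(signed.signal)
    rectified.meta["rectified"] = True
    return signed, rectified


def window_count(n_samples: int, window: int, increment: int) -> int:
    """floor((N - W) / S) + 1 for N >= W."""
    if n_samples < window:
        raise ValueError("record shorter than one window")
    return (n_samples - window) // increment + 1


def _majority(values: np.ndarray) -> int:
    """Majority vote; ties broken toward the smallest id."""
    counts = np.bincount(values)
    return int(np.argmax(counts))  # argmax returns the first (lowest) maximum


@dataclass(frozen=True)
class WindowStream:
    """Ordered sliding-window positions over a preprocessed recording."""

    starts: np.ndarray
    length: int
    increment: int
    labels: np.ndarray
    repetitions: np.ndarray
    n_channels: int

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def iter_channel_windows(self):
        """Yield (channel, start, length, label) over channels x positions."""
        for c in range(self.n_channels):
            for s, lab in zip(self.starts, self.labels):
                yield c, int(s), self.length, int(lab)


def segment_windows(
    recording: EmgRecording, cfg: PreprocessConfig | None = None
) -> WindowStream:
    """Segment a recording into the sliding-window stream.

    Window label (and repetition) are the majority of the per-sample values
    inside the window, ties resolved toward the smaller id.
    """
    if cfg is None:
        cfg = PreprocessConfig(fs=recording.fs)
    W, S = cfg.window_samples, cfg.increment_samples
    k = window_count(recording.n_samples, W, S)
    starts = np.arange(k) * S
    labels = np.empty(k, dtype=np.int16)
    reps = np.empty(k, dtype=np.int16)
    for i, s in enumerate(starts):
        labels[i] = _majority(recording.label[s : s + W])
        reps[i] = _majority(recording.repetition[s : s + W])
    return WindowStream(
        starts=starts,
        length=W,
        increment=S,
        labels=labels,
        repetitions=reps,
        n_channels=recording.n_channels,
    )


def write_recording(recording: EmgRecording, path, format: str = "csv") -> None:
    """Write as a delimited matrix (ch1..chM, label, repetition) or HDF5."""
    if format == "csv":
        cols = {f"ch{c + 1}": recording.signal[:, c] for c in range(recording.n_channels)}
        cols["label"] = recording.label
        cols["repetition"] = recording.repetition
        pd.DataFrame(cols).to_csv(path, index=False)
    elif format == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=recording.signal)
            f.create_dataset("label", data=recording.label)
            f.create_dataset("repetition", data=recording.repetition)
            f.attrs["fs"] = recording.fs
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path, format: str | None = None, fs: float = 2000.0) -> EmgRecording:
    """Read a recording written by :func:`write_recording`.

    For CSV the channel count is inferred from the ``ch*`` columns (a count
    other than 12 is accepted with a logged warning); ``label`` and
    ``repetition`` columns are required.
    """
    if format is None:
        format = "h5" if str(path).endswith((".h5", ".hdf5")) else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        ch_cols = [c for c in df.columns if c.startswith("ch")]
        if not ch_cols:
            raise ValueError("no channel columns (ch1..chM) found")
        ch_cols = sorted(ch_cols, key=lambda c: int(c[2:]))
        for required in ("label", "repetition"):
            if required not in df.columns:
                raise ValueError(f"missing required column {required!r}")
        if len(ch_cols) != 12:
            log.warning("expected 12 channels, found %d; accepting", len(ch_cols))
        signal = df[ch_cols].to_numpy(dtype=float)
        return EmgRecording(
            signal=signal,
            fs=fs,
            label=df["label"].to_numpy(),
            repetition=df["repetition"].to_numpy(),
        )
    elif format == "h5":
        with h5py.File(path, "r") as f:
            return EmgRecording(
                signal=f["signal"][...],
                fs=float(f.attrs["fs"]),
                label=f["label"][...],
                repetition=f["repetition"][...],
            )
    else:
        raise ValueError(f"unknown format {format!r}")
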