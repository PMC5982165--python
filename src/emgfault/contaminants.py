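"""Simulators for the five canonical sEMG contaminants and the 16-case map.

Contaminants: motion artifact (low-frequency electrode drift), electrode
displacement (15 dB additive white Gaussian noise), amplifier saturation (six
sinusoids at random frequencies in 200-240 Hz), power-line interference (60 Hz
fundamental of 0.4 V plus harmonics) and ECG bleed-through (cardiac waveform
normalized to maximum amplitude 0.2).  Contamination is inserted into the raw
signal over the entire record, before any filtering or segmentation, into the
channel sets defined by the 16 degradation cases (single electrodes of the
8-electrode forearm ring, the flexor/extensor and bicep/tricep electrodes and
their combinations, and the whole ring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .synthetic import EmgRecording, synth_ecg

__all__ = [
    "CASE_MAP",
    "ContaminantSpec",
    "simulate_motion_artifact",
    "simulate_displacement_awgn",
    "simulate_saturation",
    "simulate_powerline",
    "simulate_ecg_interference",
    "apply_case",
    "measure_snr",
]

#: case id -> contaminated channel ids (1-based, matching electrode numbering)
CASE_MAP: dict[int, tuple[int, ...]] = {
    **{k: (k,) for k in range(1, 9)},  # single uniformly-spaced electrodes
    9: (9,),  # flexor digitorum
    10: (10,),  # extensor digitorum
    11: (11,),  # bicep
    12: (12,),  # tricep
    13: (9, 10),
    14: (11, 12),
    15: (9, 10, 11, 12),
    16: tuple(range(1, 9)),  # whole forearm ring
}

KINDS = ("motion_artifact", "electrode_displacement", "saturation", "power_line", "ecg")


@dataclass(frozen=True)
class ContaminantSpec:
    """Which contaminant to insert and with what parameters."""

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown contaminant kind {self.kind!r}")


def simulate_motion_artifact(
    n: int,
    fs: float,
    seed: int = 0,
    rel_power_db: float = 0.0,
) -> np.ndarray:
    """Motion-artifact trace: low-frequency drift with intensity bursts.

    The dominant component is a <7 Hz band-limited stochastic drift whose
    intensity is modulated by a slow burst envelope (continuous baseline sway
    plus occasional tugs).  A small wide-band component (2.5% of the power,
    band-limited to 60 Hz and gated by the same bursts) represents the
    electrode-gel transients that accompany movement; at least 95% of the
    total power stays below 10 Hz.  Output is scaled to ``rel_power_db``
    relative to unit power; a gain of zero (``-inf`` dB) yields a zero vector.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if np.isneginf(rel_power_db):
        return np.zeros(n)
    rng = np.random.default_rng([404, seed])
    # filter a padded draw and trim: the edge transients of a very-low-cutoff
    # zero-phase filter are broadband and would otherwise dominate the tiny
    # passband power
    pad = int(round(2.0 * fs))
    sos_drift = sps.butter(4, 6.0, btype="low", fs=fs, output="sos")
    drift = sps.sosfiltfilt(sos_drift, rng.standard_normal(n + 2 * pad))[pad:-pad]

    # burst envelope: 0.5 baseline + bursts of 0.3-1.2 s every 1-4 s,
    # 200 ms cosine ramps so the modulation stays narrow-band
    env = np.full(n, 0.5)
    ramp = int(round(0.2 * fs))
    t = 0.0
    while t < n / fs:
        t += rng.uniform(1.0, 4.0)
        dur = rng.uniform(0.3, 1.2)
        i0, i1 = int(t * fs), int((t + dur) * fs)
        if i0 >= n:
            break
        i1 = min(i1, n)
        burst = np.ones(i1 - i0)
        r = min(ramp, len(burst) // 2)
        if r > 0:
            burst[:r] = 0.5 * (1 - np.cos(np.linspace(0, np.pi, r)))
            burst[-r:] = 0.5 * (1 + np.cos(np.linspace(0, np.pi, r)))
        env[i0:i1] += burst
        t += dur
    drift *= env

    sos_wb = sps.butter(4, 60.0, btype="low", fs=fs, output="sos")
    wideband = sps.sosfiltfilt(sos_wb, rng.standard_normal(n + 2 * pad))[pad:-pad]
    wideband = wideband * (env - 0.4)

    def _unit_power(x: np.ndarray) -> np.ndarray:
        p = np.mean(x**2)
        return x / np.sqrt(p) if p > 0 else x

    x = np.sqrt(0.975) * _unit_power(drift) + np.sqrt(0.025) * _unit_power(wideband)
    x = _unit_power(x) * 10.0 ** (rel_power_db / 20.0)
    return x


def simulate_displacement_awgn(
    clean: np.ndarray, snr_db: float = 15.0, seed: int = 0
) -> np.ndarray:
    """Electrode displacement: clean + white Gaussian noise at ``snr_db``."""
    clean = np.asarray(clean, dtype=float)
    p_clean = np.mean(clean**2)
    if p_clean == 0:
        raise ValueError("clean signal has zero power")
    rng = np.random.default_rng([505, seed])
    p_noise = p_clean / 10.0 ** (snr_db / 10.0)
    return clean + np.sqrt(p_noise) * rng.standard_normal(clean.shape)


class SaturationNoise(NamedTuple):
    signal: np.ndarray
    frequencies: np.ndarray


def simulate_saturation(
    n: int,
    fs: float,
    seed: int = 0,
    n_components: int = 6,
    amplitude: float = 0.5,
) -> SaturationNoise:
    """Amplifier saturation: sum of sinusoids at random 200-240 Hz frequencies.

    Each of the ``n_components`` sinusoids has uniform-random frequency in
    [200, 240] Hz, uniform-random phase, and amplitude ``amplitude`` (the
    source work fixes the count and band but not the level; the default makes
    the artifact comparable to movement-level sEMG, befitting saturation).
    Returns the trace together with the drawn component frequencies.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if fs <= 480:
        raise ValueError("sampling rate too low for the 200-240 Hz band")
    rng = np.random.default_rng([606, seed])
    freqs = rng.uniform(200.0, 240.0, size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, ph in zip(freqs, phases):
        x += amplitude * np.sin(2 * np.pi * f * t + ph)
    return SaturationNoise(signal=x, frequencies=freqs)


def simulate_powerline(
    n: int,
    fs: float,
    amplitude: float = 0.4,
    f0: float = 60.0,
    n_harmonics: int = 3,
) -> np.ndarray:
    """Power-line interference: ``amplitude`` V fundamental plus harmonics.

    Harmonic k (k = 2..n_harmonics+1) has amplitude ``amplitude``/k, keeping
    the fundamental dominant.  Deterministic (zero phase).
    """
    if f0 * (n_harmonics + 1) >= fs / 2:
        raise ValueError("highest harmonic would alias")
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * f0 * t)
    for k in range(2, n_harmonics + 2):
        x += (amplitude / k) * np.sin(2 * np.pi * k * f0 * t)
    return x


def simulate_ecg_interference(
    n: int,
    fs: float,
    max_amplitude: float = 0.2,
    seed: int = 0,
    bpm: float = 72.0,
) -> np.ndarray:
    """ECG bleed-through: normalized cardiac waveform scaled to ``max_amplitude``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if max_amplitude == 0:
        return np.zeros(n)
    ecg = synth_ecg(fs=fs, duration=n / fs, bpm=bpm, seed=seed)[:n]
    peak = np.max(np.abs(ecg))
    if peak > 0:
        ecg = ecg / peak
    return max_amplitude * ecg


def contaminant_trace(
    spec: ContaminantSpec,
    n: int,
    fs: float,
    clean: np.ndarray | None = None,
    channel_seed: int = 0,
) -> np.ndarray:
    """The additive noise vector for one channel under ``spec``.

    For electrode displacement the noise level is tied to the clean channel's
    own power (the 15 dB SNR definition), so ``clean`` is required there.
    """
    seed = spec.seed + 1009 * channel_seed
    p = spec.params
    if spec.kind == "motion_artifact":
        return simulate_motion_artifact(
            n, fs, seed=seed, rel_power_db=p.get("rel_power_db", 0.0)
        )
    if spec.kind == "electrode_displacement":
        if clean is None:
            raise ValueError("displacement noise needs the clean channel")
        noisy = simulate_displacement_awgn(clean, p.get("snr_db", 15.0), seed=seed)
        return noisy - clean
    if spec.kind == "saturation":
        return simulate_saturation(
            n,
            fs,
            seed=seed,
            n_components=p.get("n_components", 6),
            amplitude=p.get("amplitude", 0.5),
        ).signal
    if spec.kind == "power_line":
        return simulate_powerline(
            n,
            fs,
            amplitude=p.get("amplitude", 0.4),
            f0=p.get("f0", 60.0),
            n_harmonics=p.get("n_harmonics", 3),
        )
    if spec.kind == "ecg":
        return simulate_ecg_interference(
            n,
            fs,
            max_amplitude=p.get("max_amplitude", 0.2),
            seed=seed,
            bpm=p.get("bpm", 72.0),
        )
    raise ValueError(f"unknown contaminant kind {spec.kind!r}")


def apply_case(
    recording: EmgRecording, case_id: int, spec: ContaminantSpec
) -> EmgRecording:
    """Insert a contaminant into the channels of one degradation case.

    The noise is added over the entire record to exactly the case's channels
    (independent seeds per channel for the stochastic contaminants; the
    power-line trace is common-mode); all other channels are bit-identical to
    the input.  Provenance (case, kind, seed, channels) is attached to the
    returned recording's ``meta``.
    """
    if case_id not in CASE_MAP:
        raise ValueError(f"unknown case id {case_id}")
    channels = CASE_MAP[case_id]
    out = recording.copy()
    n, fs = recording.n_samples, recording.fs
    for ch in channels:
        c = ch - 1
        trace = contaminant_trace(
            spec, n, fs, clean=recording.signal[:, c], channel_seed=ch
        )
        out.signal[:, c] = out.signal[:, c] + trace
    out.meta["contamination"] = {
        "case": case_id,
        "kind": spec.kind,
        "seed": spec.seed,
        "channels": channels,
    }
    return out


def measure_snr(clean: np.ndarray, contaminated: np.ndarray) -> float:
    """10 log10(P_clean / P_noise) with noise = contaminated - clean, in dB."""
    clean = np.asarray(clean, dtype=float)
    contaminated = np.asarray(contaminated, dtype=float)
    if clean.shape != contaminated.shape:
        raise ValueError("length mismatch")
    p_noise = np.mean((contaminated - clean) ** 2)
    if p_noise == 0:
        raise ValueError("zero noise power")
    return float(10.0 * np.log10(np.mean(clean**2) / p_noise))
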