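"""Frontal EEG feature pipeline.

The wearable headband provides four channels (TP9, Fp1, Fp2, TP10) sampled
at 500 Hz. The PSD of each channel is a Welch-style average of
Hamming-windowed 256-sample segments with 90% overlap, truncated to
0-110 Hz. Absolute bandpower is the log10 of the summed PSD bins within a
band (delta 1-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-100 Hz);
derived indexes are engagement beta/(alpha+theta), frontal alpha asymmetry
Fp2-Fp1, and the theta/beta ratio. Frontal quantities average the Fp1 and
Fp2 contributions; the temporal channels are carried but excluded from the
indexes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
from scipy import signal

CHANNELS: Tuple[str, ...] = ("TP9", "Fp1", "Fp2", "TP10")
FRONTAL: Tuple[str, str] = ("Fp1", "Fp2")

EEG_BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

PSD_WINDOW = 256  # samples, Hamming
PSD_HOP = 26  # samples: 90% of 256 = 230.4 overlap, fixed at 230 (hop 26)
PSD_FMAX = 110.0  # Hz


@dataclass(frozen=True)
class EEGRecording:
    """Uniformly sampled multichannel voltage series (uV)."""

    fs: float
    data: np.ndarray  # shape (n_channels, n_samples)
    channels: Tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != len(self.channels):
            raise ValueError("data must be a (channels x samples) matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("EEG samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


@dataclass(frozen=True)
class PSDFrame:
    """One-sided power spectral density per channel (uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channels: Tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD values must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        return self.power[self.channels.index(name)]


@dataclass(frozen=True)
class BandpowerSet:
    """Per-channel log10 absolute bandpowers (Bels) and their linear sums."""

    log: Mapping[str, Mapping[str, float]]  # channel -> band -> Bels
    linear: Mapping[str, Mapping[str, float]]  # channel -> band -> uV^2/Hz sum
    channels: Tuple[str, ...] = CHANNELS

    def frontal_log(self, band: str) -> float:
        """Frontal bandpower: mean of the Fp1 and Fp2 log powers."""
        return float(np.mean([self.log[ch][band] for ch in FRONTAL]))

    def frontal_linear(self, band: str) -> float:
        return float(np.mean([self.linear[ch][band] for ch in FRONTAL]))


def compute_psd(rec: EEGRecording) -> PSDFrame:
    """Welch PSD: Hamming window, 256-sample segments, 90% overlap,
    one-sided density truncated to [0, 110] Hz. Segment means are removed
    so sensor DC offsets cannot smear through the window's main lobe into
    the delta band."""
    if rec.n_samples < PSD_WINDOW:
        raise ValueError(
            f"recording has {rec.n_samples} samples; >= {PSD_WINDOW} required"
        )
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window="hamming",
        nperseg=PSD_WINDOW,
        noverlap=PSD_WINDOW - PSD_HOP,
        detrend="constant",
        axis=-1,
    )
    keep = freqs <= PSD_FMAX
    return PSDFrame(freqs=freqs[keep], power=power[:, keep], channels=rec.channels)


def absolute_bandpowers(psd: PSDFrame) -> BandpowerSet:
    """log10 of the summed PSD bins whose center lies in [lo, hi) per band.

    A band with zero summed power maps to -inf Bels (no crash); the derived
    indexes then propagate an undefined value.
    """
    f = psd.freqs
    for lo, hi in EEG_BANDS.values():
        if lo < f[0] or hi > f[-1] + (f[1] - f[0]):
            raise ValueError(f"band [{lo}, {hi}) outside the PSD grid")
    log: Dict[str, Dict[str, float]] = {}
    linear: Dict[str, Dict[str, float]] = {}
    for ch in psd.channels:
        p = psd.channel(ch)
        linear[ch] = {}
        log[ch] = {}
        for band, (lo, hi) in EEG_BANDS.items():
            s = float(p[(f >= lo) & (f < hi)].sum())
            linear[ch][band] = s
            with np.errstate(divide="ignore"):
                log[ch][band] = float(np.log10(s)) if s > 0 else float("-inf")
    return BandpowerSet(log=log, linear=linear, channels=psd.channels)


def derived_indexes(bp: BandpowerSet, use_log_ratios: bool = False) -> Dict[str, float]:
    """Engagement, frontal alpha asymmetry and theta/beta ratio.

    Ratios (engagement, theta/beta) are computed on frontal-averaged linear
    band sums by default — ratios of log powers are scale artifacts — with
    ``use_log_ratios`` as a documented alternative. Asymmetry is the log
    alpha power difference Fp2 - Fp1 (standard asymmetry convention).
    Zero denominators yield NaN rather than raising.
    """
    if use_log_ratios:
        theta = bp.frontal_log("theta")
        alpha = bp.frontal_log("alpha")
        beta = bp.frontal_log("beta")
    else:
        theta = bp.frontal_linear("theta")
        alpha = bp.frontal_linear("alpha")
        beta = bp.frontal_linear("beta")
    engagement = beta / (alpha + theta) if (alpha + theta) > 0 else float("nan")
    theta_beta = theta / beta if beta > 0 else float("nan")
    asymmetry = bp.log["Fp2"]["alpha"] - bp.log["Fp1"]["alpha"]
    if not np.isfinite(asymmetry):
        asymmetry = float("nan")
    return {
        "engagement": float(engagement),
        "asymmetry": float(asymmetry),
        "theta_beta": float(theta_beta),
    }


def extract_features(rec: EEGRecording) -> Dict[str, float]:
    """Convenience: frontal log bandpowers plus the three indexes."""
    bp = absolute_bandpowers(compute_psd(rec))
    out = {f"frontal_{band}": bp.frontal_log(band) for band in EEG_BANDS}
    out.update(derived_indexes(bp))
    return out
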