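"""Heart-rate-variability feature pipeline.

Raw input is the beat-to-beat R-to-R interval (RRI) series streamed by a
chest-strap monitor in device units of 1/1024 s. Time-domain features are
mean HR, SDNN and RMSSD; frequency-domain features are the VLF / LF / HF
band powers of the RR tachogram obtained from a Welch PSD (Hann window)
integrated with a trapezoidal area-under-the-curve rule.

Bands: VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.40 Hz.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import interpolate, signal

DEVICE_UNITS_PER_SECOND = 1024.0

HRV_BANDS: Dict[str, Tuple[float, float]] = {
    "vlf": (0.0033, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.40),
}

#: physiologically plausible RR range in seconds; values outside warn.
_PLAUSIBLE_RR_S = (0.3, 2.0)


@dataclass(frozen=True)
class RRISeries:
    """Beat-to-beat intervals in 1/1024-s device units."""

    intervals: np.ndarray
    origin: str = "unknown"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("RRI series must be a nonempty 1-D sequence")
        if np.any(arr <= 0):
            raise ValueError("RRI intervals must be positive")
        object.__setattr__(self, "intervals", arr)
        secs = arr / DEVICE_UNITS_PER_SECOND
        lo, hi = _PLAUSIBLE_RR_S
        if np.any((secs < lo) | (secs > hi)):
            warnings.warn(
                f"{int(np.sum((secs < lo) | (secs > hi)))} RR interval(s) "
                f"outside the plausible [{lo}, {hi}] s range",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / DEVICE_UNITS_PER_SECOND)

    @classmethod
    def from_seconds(cls, seconds: Sequence[float], origin: str = "unknown") -> "RRISeries":
        units = np.rint(np.asarray(seconds, dtype=float) * DEVICE_UNITS_PER_SECOND)
        return cls(intervals=units.astype(np.int64), origin=origin)


@dataclass(frozen=True)
class HRVSummary:
    """Time- and frequency-domain HRV features for one recording block."""

    mean_hr: float  # beats/min
    sdnn: float  # ms
    rmssd: float  # ms
    vlf: float = float("nan")  # ms^2
    lf: float = float("nan")  # ms^2
    hf: float = float("nan")  # ms^2

    def as_dict(self) -> Dict[str, float]:
        return {
            "mean_hr": self.mean_hr,
            "sdnn": self.sdnn,
            "rmssd": self.rmssd,
            "vlf": self.vlf,
            "lf": self.lf,
            "hf": self.hf,
        }


def rri_to_seconds(rri: RRISeries) -> np.ndarray:
    """Convert device units (1/1024 s) to seconds, order preserved."""
    return rri.intervals / DEVICE_UNITS_PER_SECOND


def time_domain_summary(rri: RRISeries) -> Dict[str, float]:
    """Mean HR (BPM), SDNN (ms, n-1 denominator) and RMSSD (ms).

    Requires at least 3 intervals (2 successive differences for RMSSD).
    """
    if len(rri) < 3:
        raise ValueError("need >= 3 intervals for the time-domain summary")
    rr_s = rri_to_seconds(rri)
    rr_ms = rr_s * 1000.0
    mean_hr = 60.0 / float(np.mean(rr_s))
    sdnn = float(np.std(rr_ms, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(rr_ms) ** 2)))
    return {"mean_hr": mean_hr, "sdnn": sdnn, "rmssd": rmssd}


def _band_auc(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def spectral_summary(
    rri: RRISeries,
    resample_hz: float = 4.0,
    seg_len: int = 256,
) -> Dict[str, float]:
    """VLF / LF / HF band powers (ms^2) of the RR tachogram.

    The unevenly sampled tachogram is cubic-interpolated onto a uniform
    grid at ``resample_hz``, mean-removed, Welch-estimated with Hann
    windows of ``seg_len`` samples and 50% overlap, and each band power is
    the trapezoidal area under the one-sided PSD over the band.
    """
    if resample_hz < 1:
        raise ValueError("resample_hz must be >= 1 Hz")
    rr_s = rri_to_seconds(rri)
    beat_times = np.cumsum(rr_s)
    span = beat_times[-1] - beat_times[0]
    if span < 120.0:
        raise ValueError(
            f"recording spans {span:.1f} s; >= 120 s required for the "
            "spectral summary"
        )
    grid = np.arange(beat_times[0], beat_times[-1], 1.0 / resample_hz)
    tach_ms = interpolate.interp1d(beat_times, rr_s * 1000.0, kind="cubic")(grid)
    if seg_len > tach_ms.size:
        raise ValueError("seg_len longer than the resampled series")
    tach_ms = tach_ms - tach_ms.mean()
    freqs, psd = signal.welch(
        tach_ms,
        fs=resample_hz,
        window="hann",
        nperseg=seg_len,
        noverlap=seg_len // 2,
        detrend=False,
    )
    return {name: _band_auc(freqs, psd, lo, hi) for name, (lo, hi) in HRV_BANDS.items()}


def analyze(rri: RRISeries, resample_hz: float = 4.0, seg_len: int = 256) -> HRVSummary:
    """Full HRV summary (time + frequency domain) for one block."""
    td = time_domain_summary(rri)
    fd = spectral_summary(rri, resample_hz=resample_hz, seg_len=seg_len)
    return HRVSummary(**td, **fd)
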