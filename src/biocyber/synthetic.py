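"""Synthetic trainee physiology.

The study cohort's raw data are not publicly available, so this module
generates seeded surrogate signals with controllable state-dependent
structure:

* RR-interval series from an integral pulse frequency modulation (IPFM)
  model, so frequency-domain HRV targets (LF 0.1 Hz, HF 0.25 Hz
  modulation) are constructible by design;
* multichannel EEG as sums of band-limited Gaussian components (one per
  canonical band) synthesised in the frequency domain, so injected band
  power is exactly confined to its band;
* a 10-participant x 4-condition cohort emulating the characterization
  study's trends — mean HR rising and frontal theta falling with
  simulation difficulty — with participant-level random offsets;
* a first-order "trainee plant" whose heart rate relaxes toward a
  setpoint determined by the current simulation difficulty, used by the
  closed-loop adaptation engine.

All generators are pure functions of their arguments and the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .difficulty import DifficultyConfig, difficulty_index
from .eeg import CHANNELS, EEG_BANDS, EEGRecording
from .hrv import RRISeries

CONDITIONS: Tuple[str, ...] = ("baseline", "easy", "medium", "hard")

# IPFM modulation frequencies (Hz): mid-LF and mid-HF.
LF_MOD_HZ = 0.1
HF_MOD_HZ = 0.25

_DEFAULT_BAND_AMPS = {"delta": 6.0, "theta": 8.0, "alpha": 7.0, "beta": 5.0, "gamma": 2.0}


@dataclass(frozen=True)
class StateProfile:
    """Generator parameters for one psychophysiological state.

    ``hr_mean`` in BPM; ``lf_amp``/``hf_amp`` are dimensionless modulation
    depths of the instantaneous beat rate at 0.1 and 0.25 Hz;
    ``rate_noise`` is the white-noise depth on the beat rate;
    ``band_amps`` are per-band EEG component amplitudes (uV, std of the
    band-limited component, applied to every channel scaled by
    ``channel_gains``); ``noise_sd`` is broadband EEG noise (uV).
    """

    label: str = "custom"
    hr_mean: float = 70.0
    lf_amp: float = 0.04
    hf_amp: float = 0.06
    rate_noise: float = 0.02
    band_amps: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BAND_AMPS))
    channel_gains: Mapping[str, float] = field(
        default_factory=lambda: {ch: 1.0 for ch in CHANNELS}
    )
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (30.0 <= self.hr_mean <= 220.0):
            raise ValueError("hr_mean must lie in [30, 220] BPM")
        for name in ("lf_amp", "hf_amp", "rate_noise"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5)")
        if any(a < 0 for a in self.band_amps.values()) or self.noise_sd < 0:
            raise ValueError("EEG amplitudes must be non-negative")


@dataclass(frozen=True)
class PlantState:
    """Instantaneous state of the simulated trainee."""

    hr: float  # beats/min
    theta: float  # frontal theta log power, Bels
    arousal: float = 0.0  # latent, dimensionless
    time: float = 0.0  # s

    def __post_init__(self) -> None:
        vals = (self.hr, self.theta, self.arousal, self.time)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("plant state fields must be finite")
        if self.hr <= 0:
            raise ValueError("hr must be positive")


@dataclass(frozen=True)
class PlantParams:
    """First-order trainee-plant dynamics.

    ``tau`` (s) is the HR relaxation time constant (physiological HR
    responses settle on the order of tens of seconds). The HR setpoint maps
    the difficulty index linearly from ``hr_rest`` (70 BPM) to ``hr_max``
    (125 BPM); frontal theta follows the opposite-signed mapping from
    ``theta_rest`` down by ``theta_span`` Bels. Noise standard deviations
    are per sqrt-second.
    """

    tau: float = 20.0
    hr_rest: float = 70.0
    hr_max: float = 125.0
    theta_rest: float = 2.0
    theta_span: float = 0.6
    hr_noise_sd: float = 0.5
    theta_noise_sd: float = 0.02


DEFAULT_PLANT = PlantParams()


def hr_setpoint(difficulty: DifficultyConfig, params: PlantParams = DEFAULT_PLANT) -> float:
    """HR setpoint (BPM): linear in the normalized difficulty index."""
    idx = difficulty_index(difficulty)
    return params.hr_rest + (params.hr_max - params.hr_rest) * idx


def theta_setpoint(difficulty: DifficultyConfig, params: PlantParams = DEFAULT_PLANT) -> float:
    """Frontal theta setpoint (Bels): falls as difficulty rises."""
    idx = difficulty_index(difficulty)
    return params.theta_rest - params.theta_span * idx


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic repeated-measures cohort.

    ``condition_effects`` maps every condition label to its StateProfile;
    participant-level Gaussian offsets (hr_mean sd 5 BPM, theta amplitude
    sd 10%) provide between-subject variability shared across conditions.
    """

    n_participants: int = 10
    condition_effects: Mapping[str, StateProfile] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PROFILES)
    )
    block_duration: float = 180.0  # s
    eeg_fs: float = 500.0  # Hz
    seed: int = 0
    hr_offset_sd: float = 5.0  # BPM
    theta_offset_sd: float = 0.10  # fractional

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.block_duration < 60.0:
            raise ValueError("block_duration must be >= 60 s")
        missing = [c for c in CONDITIONS if c not in self.condition_effects]
        if missing:
            raise ValueError(f"condition_effects missing conditions: {missing}")


def generate_rri(profile: StateProfile, duration: float, seed: int) -> RRISeries:
    """IPFM RR-interval generator.

    Beats are emitted whenever the running integral of the instantaneous
    beat rate m(t) = (hr_mean/60) * (1 + lf_amp sin(2 pi 0.1 t + phi1)
    + hf_amp sin(2 pi 0.25 t + phi2)) + white noise crosses successive
    integer thresholds; intervals are reported in 1/1024-s device units.
    Phases are drawn from the seed; a beat is anchored at t = 0.
    """
    if duration < 30.0:
        raise ValueError("duration must be >= 30 s")
    rng = np.random.default_rng(seed)
    base = profile.hr_mean / 60.0  # Hz
    dt = 1.0 / 128.0
    t = np.arange(0.0, duration + dt, dt)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    m = base * (
        1.0
        + profile.lf_amp * np.sin(2 * np.pi * LF_MOD_HZ * t + phi1)
        + profile.hf_amp * np.sin(2 * np.pi * HF_MOD_HZ * t + phi2)
    )
    if profile.rate_noise > 0:
        m = m + rng.normal(0.0, profile.rate_noise * base, size=t.size)
    m = np.clip(m, 0.1 * base, None)
    # left-rectangle cumulative integral: exact for a constant rate
    integral = np.concatenate(([0.0], np.cumsum(m[:-1]) * dt))
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 2:
        raise ValueError("duration too short for the requested heart rate")
    beat_times = np.interp(np.arange(1, n_beats + 1), integral, t)
    intervals_s = np.diff(np.concatenate(([0.0], beat_times)))
    units = np.rint(intervals_s * 1024.0).astype(np.int64)
    return RRISeries(intervals=units, origin=f"ipfm:{profile.label}")


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, amp: float
) -> np.ndarray:
    """Gaussian noise with power exactly confined to [lo, hi) Hz and
    standard deviation ``amp``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    if k == 0 or amp == 0:
        # draw anyway to keep the rng stream independent of amplitudes
        rng.standard_normal(2 * k)
        return np.zeros(n)
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def generate_eeg(
    profile: StateProfile, duration: float, fs: float = 500.0, seed: int = 0
) -> EEGRecording:
    """Per channel: sum of independent band-limited Gaussian components
    (std = band amplitude x channel gain, uV) plus broadband noise."""
    if fs < 200.0 or fs <= 2 * max(hi for _, hi in EEG_BANDS.values()):
        raise ValueError("fs must exceed twice the highest band edge (>= 200 Hz)")
    if duration < 10.0:
        raise ValueError("duration must be >= 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = np.zeros((len(CHANNELS), n))
    for i, ch in enumerate(CHANNELS):
        gain = float(profile.channel_gains.get(ch, 1.0))
        for band, (lo, hi) in EEG_BANDS.items():
            amp = float(profile.band_amps.get(band, 0.0)) * gain
            data[i] += _bandlimited_noise(rng, n, fs, lo, hi, amp)
        if profile.noise_sd > 0:
            data[i] += rng.normal(0.0, profile.noise_sd, size=n)
        else:
            rng.standard_normal(0)
    return EEGRecording(fs=fs, data=data, channels=CHANNELS)


#: Study-condition profiles: HR rises and frontal theta amplitude falls
#: with simulation difficulty; HF modulation (vagal tone) recedes under
#: stress while LF grows.
DEFAULT_CONDITION_PROFILES: Dict[str, StateProfile] = {
    "baseline": StateProfile(
        label="baseline", hr_mean=75.0, lf_amp=0.04, hf_amp=0.08,
        band_amps={**_DEFAULT_BAND_AMPS, "theta": 9.0},
    ),
    "easy": StateProfile(
        label="easy", hr_mean=95.0, lf_amp=0.05, hf_amp=0.06,
        band_amps={**_DEFAULT_BAND_AMPS, "theta": 8.5},
    ),
    "medium": StateProfile(
        label="medium", hr_mean=105.0, lf_amp=0.06, hf_amp=0.05,
        band_amps={**_DEFAULT_BAND_AMPS, "theta": 7.5},
    ),
    "hard": StateProfile(
        label="hard", hr_mean=115.0, lf_amp=0.06, hf_amp=0.04,
        band_amps={**_DEFAULT_BAND_AMPS, "theta": 6.5},
    ),
}


@dataclass(frozen=True)
class CohortRecord:
    participant: int
    condition: str
    rri: Optional[RRISeries]
    eeg: Optional[EEGRecording]


def generate_cohort(
    spec: CohortSpec, signals: Tuple[str, ...] = ("rri", "eeg")
) -> Tuple[CohortRecord, ...]:
    """Per-participant, per-condition raw signal set.

    Participant offsets (hr_mean, theta amplitude) are drawn once per
    participant and shared across their four conditions, preserving the
    repeated-measures pairing. ``signals`` selects which modalities to
    synthesise. Deterministic under ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    records = []
    for p in range(spec.n_participants):
        hr_off = master.normal(0.0, spec.hr_offset_sd)
        theta_scale = max(0.0, master.normal(1.0, spec.theta_offset_sd))
        for cond in CONDITIONS:
            base = spec.condition_effects[cond]
            amps = dict(base.band_amps)
            amps["theta"] = amps.get("theta", 0.0) * theta_scale
            hr = float(np.clip(base.hr_mean + hr_off, 30.0, 220.0))
            prof = replace(base, hr_mean=hr, band_amps=amps)
            sub = master.integers(0, 2**31 - 1, size=2)
            rri = (
                generate_rri(prof, spec.block_duration, int(sub[0]))
                if "rri" in signals
                else None
            )
            eeg = (
                generate_eeg(prof, spec.block_duration, fs=spec.eeg_fs, seed=int(sub[1]))
                if "eeg" in signals
                else None
            )
            records.append(CohortRecord(participant=p, condition=cond, rri=rri, eeg=eeg))
    return tuple(records)


def plant_step(
    state: PlantState,
    difficulty: DifficultyConfig,
    dt: float,
    seed: Optional[int] = None,
    *,
    params: PlantParams = DEFAULT_PLANT,
    rng: Optional[np.random.Generator] = None,
) -> PlantState:
    """One Euler step of the first-order trainee plant.

    hr <- hr + (dt/tau) (setpoint(difficulty) - hr) + noise, and theta
    relaxes likewise toward its opposite-signed setpoint. Pass ``rng`` to
    advance an existing stream (as the closed loop does) or ``seed`` for a
    one-shot reproducible step; both absent means deterministic (no noise).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    hr_sp = hr_setpoint(difficulty, params)
    th_sp = theta_setpoint(difficulty, params)
    a = dt / params.tau
    hr = state.hr + a * (hr_sp - state.hr)
    theta = state.theta + a * (th_sp - state.theta)
    if rng is not None:
        hr += rng.normal(0.0, params.hr_noise_sd * np.sqrt(dt))
        theta += rng.normal(0.0, params.theta_noise_sd * np.sqrt(dt))
    arousal = (hr - params.hr_rest) / (params.hr_max - params.hr_rest)
    return PlantState(hr=hr, theta=theta, arousal=arousal, time=state.time + dt)
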