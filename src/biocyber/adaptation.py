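"""Closed-loop biocybernetic difficulty adaptation.

The adaptive rule buffers the trainee's heart rate and frontal theta,
averages each buffer, and compares the averages against trainer-specified
targets: a 100-115 BPM heart-rate zone (the arousal range firearms
trainers consider optimal for shooting) and a frontal-theta concentration
threshold. Below the zone with theta still high (under-challenged), the
rule increases simulation difficulty — faster targets, smaller targets,
more targets, heavier rain, darker scene; above the zone it steps
difficulty back down; inside the zone it holds. Every emitted difficulty
configuration is clamped to the simulator's hard variable ranges.

The closed-loop runner couples the rule to the first-order trainee plant
and logs the full trajectory. A zone controller with hold and decrease
branches is required for bounded behaviour even though only the increase
branch is strictly dictated by the under-challenge scenario.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .difficulty import PRESETS, DifficultyConfig
from .synthetic import DEFAULT_PLANT, PlantParams, PlantState, plant_step


@dataclass(frozen=True)
class AdaptiveRule:
    """Buffered-average zone controller configuration.

    ``buffer_len`` counts metric samples (the runner samples at 1 Hz, so
    the default is a 30-s average); the rule is evaluated every
    ``update_period`` seconds. ``gate_metric`` selects which EEG bandpower
    gates the increase branch: ``frontal_theta`` (concentration, default)
    with difficulty increased only while theta exceeds ``gate_threshold``,
    or the alternative ``frontal_alpha`` variant gated at -0.01 Bels
    (-0.1 dB).
    """

    hr_zone: Tuple[float, float] = (100.0, 115.0)
    gate_metric: str = "frontal_theta"
    gate_threshold: float = 1.5  # Bels
    buffer_len: int = 30
    update_period: float = 5.0  # s
    increase_step: Mapping[str, float] = field(
        default_factory=lambda: {
            "target_speed": 0.25,  # m/s, additive
            "target_size": 0.9,  # multiplicative
            "n_targets": 1,  # additive
            "rain": 0.05,  # additive
            "daylight": -0.5,  # additive
        }
    )

    def __post_init__(self) -> None:
        if self.hr_zone[0] >= self.hr_zone[1]:
            raise ValueError("hr_zone lower bound must be below the upper bound")
        if self.buffer_len < 1:
            raise ValueError("buffer_len must be >= 1")
        if self.gate_metric not in ("frontal_theta", "frontal_alpha"):
            raise ValueError("gate_metric must be frontal_theta or frontal_alpha")


def alpha_rule_variant(**overrides) -> AdaptiveRule:
    """The alternative rule gated on frontal alpha at -0.1 dB (-0.01 Bels)."""
    kw = dict(gate_metric="frontal_alpha", gate_threshold=-0.01)
    kw.update(overrides)
    return AdaptiveRule(**kw)


@dataclass(frozen=True)
class ModulationDecision:
    direction: str  # increase | hold | decrease
    step: Mapping[str, float]
    tags: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "hold", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "hold" and self.step:
            raise ValueError("hold decisions carry a zero step")


@dataclass(frozen=True)
class PerformanceRecord:
    shots: int
    destroyed: int
    headshots: int = 0

    def __post_init__(self) -> None:
        if self.shots < 0 or self.destroyed < 0 or self.headshots < 0:
            raise ValueError("counts must be non-negative")
        if self.destroyed > self.shots:
            raise ValueError("destroyed targets cannot exceed shot bullets")

    @property
    def performance(self) -> float:
        return shooting_performance(self.shots, self.destroyed)


@dataclass(frozen=True)
class SessionProtocol:
    """The study's block structure: 3-min baseline then easy/medium/hard
    3-min blocks with 2-min rests."""

    blocks: Tuple[str, ...] = ("baseline", "easy", "medium", "hard")
    block_duration: float = 180.0  # s
    rest_duration: float = 120.0  # s
    presets: Mapping[str, DifficultyConfig] = field(default_factory=lambda: dict(PRESETS))

    def __post_init__(self) -> None:
        if self.block_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")


def buffered_average(stream: Sequence[float], buffer_len: int) -> np.ndarray:
    """Sliding-window mean over the most recent ``buffer_len`` samples,
    emitting only once the buffer is full."""
    if buffer_len < 1:
        raise ValueError("buffer_len must be >= 1")
    x = np.asarray(stream, dtype=float)
    if x.size < buffer_len:
        return np.empty(0)
    kernel = np.ones(buffer_len) / buffer_len
    return np.convolve(x, kernel, mode="valid")


def evaluate_rule(rule: AdaptiveRule, hr_avg: float, theta_avg: float) -> ModulationDecision:
    """Decision table of the zone controller.

    Below the HR zone with the gate metric above its threshold the trainee
    is under-challenged: increase difficulty. Below the zone but gated
    (concentration already depleted): hold. Inside the zone: hold. Above
    the zone: decrease.
    """
    if not (np.isfinite(hr_avg) and np.isfinite(theta_avg)):
        raise ValueError("averaged inputs must be finite")
    lo, hi = rule.hr_zone
    if hr_avg < lo:
        if theta_avg > rule.gate_threshold:
            return ModulationDecision("increase", dict(rule.increase_step), ("below-zone",))
        return ModulationDecision("hold", {}, ("below-zone", "gated"))
    if hr_avg > hi:
        return ModulationDecision("decrease", dict(rule.increase_step), ("above-zone",))
    return ModulationDecision("hold", {}, ("in-zone",))


def apply_modulation(cfg: DifficultyConfig, d: ModulationDecision) -> DifficultyConfig:
    """Apply a decision's step vector; additive fields add (or subtract,
    for decrease) and target size scales by its factor (or its inverse);
    every field is clamped to its hard range."""
    if d.direction == "hold":
        return cfg
    sign = 1.0 if d.direction == "increase" else -1.0
    updates: Dict[str, float] = {}
    for name, step in d.step.items():
        if name == "target_size":
            factor = step if sign > 0 else 1.0 / step
            updates[name] = cfg.target_size * factor
        else:
            updates[name] = getattr(cfg, name) + sign * step
    return cfg.clamped(**updates)


def shooting_performance(shots: int, destroyed: int) -> float:
    """Destroyed-targets-to-shot-bullets ratio; NaN when no shots fired."""
    if shots < 0 or destroyed < 0:
        raise ValueError("counts must be non-negative")
    if destroyed > shots:
        raise ValueError("destroyed targets cannot exceed shot bullets")
    if shots == 0:
        return float("nan")
    return destroyed / shots


def biofeedback_metrics(
    hr_avg: float, theta_avg: float, rule: AdaptiveRule
) -> Dict[str, float]:
    """Calmness and focus displays in [0, 1].

    Calmness is 1 at the HR-zone center and falls linearly to 0 at three
    zone half-widths from the center; focus maps theta affinely from half
    a Bel below the gate threshold (0) up to the threshold (1). Both clamp.
    """
    lo, hi = rule.hr_zone
    center = (lo + hi) / 2.0
    halfwidth_scaled = 3.0 * (hi - lo) / 2.0
    calmness = 1.0 - min(max(abs(hr_avg - center) / halfwidth_scaled, 0.0), 1.0)
    floor = rule.gate_threshold - 0.5
    focus = (theta_avg - floor) / (rule.gate_threshold - floor)
    focus = min(max(focus, 0.0), 1.0)
    return {"calmness": float(calmness), "focus": float(focus)}


@dataclass(frozen=True)
class LoopResult:
    """Closed-loop trajectory: one row per plant step (1 Hz) with the HR,
    theta, all six difficulty fields and the latest decision."""

    frame: pd.DataFrame
    rule: AdaptiveRule

    def final_minute_mean_hr(self) -> float:
        tail = self.frame[self.frame["time"] > self.frame["time"].max() - 60.0]
        return float(tail["hr"].mean())


def run_closed_loop(
    rule: AdaptiveRule,
    initial_state: Optional[PlantState] = None,
    duration: float = 600.0,
    seed: int = 0,
    *,
    initial_difficulty: Optional[DifficultyConfig] = None,
    plant_params: PlantParams = DEFAULT_PLANT,
    dt: float = 1.0,
) -> LoopResult:
    """Run the biocybernetic loop against the trainee plant.

    The plant advances at ``dt`` (1 s); every sample feeds the HR and
    theta buffers; every ``update_period`` the rule is evaluated on the
    buffered averages (once full) and the resulting modulation is applied
    to the difficulty configuration. Deterministic under ``seed``.
    """
    if duration < 10 * rule.update_period:
        raise ValueError("duration must cover at least 10 update periods")
    rng = np.random.default_rng(seed)
    state = initial_state or PlantState(
        hr=plant_params.hr_rest, theta=plant_params.theta_rest
    )
    cfg = initial_difficulty or PRESETS["easy"]
    hr_buf: List[float] = []
    th_buf: List[float] = []
    rows = []
    last_decision = "hold"
    n_steps = int(round(duration / dt))
    for k in range(1, n_steps + 1):
        state = plant_step(state, cfg, dt, params=plant_params, rng=rng)
        hr_buf.append(state.hr)
        th_buf.append(state.theta)
        if len(hr_buf) > rule.buffer_len:
            hr_buf.pop(0)
            th_buf.pop(0)
        due = (k * dt) % rule.update_period < dt / 2 or abs(
            (k * dt) % rule.update_period - rule.update_period
        ) < dt / 2
        if due and len(hr_buf) == rule.buffer_len:
            decision = evaluate_rule(
                rule, float(np.mean(hr_buf)), float(np.mean(th_buf))
            )
            cfg = apply_modulation(cfg, decision)
            last_decision = decision.direction
        rows.append(
            {
                "time": state.time,
                "hr": state.hr,
                "theta": state.theta,
                **cfg.as_dict(),
                "decision": last_decision,
            }
        )
    return LoopResult(frame=pd.DataFrame(rows), rule=rule)
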