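"""Simulation difficulty variables and their hard ranges.

The shooting-range simulator exposes six trainer-controllable variables
(target count, size, horizontal speed, hardness, daylight, rain intensity),
each with a hard range. A scalar difficulty index in [0, 1] aggregates them
for the trainee plant's heart-rate setpoint mapping.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

#: (low, high) hard range per simulation variable.
RANGES: Dict[str, Tuple[float, float]] = {
    "n_targets": (3, 20),
    "target_size": (0.3, 3.0),
    "target_speed": (0.0, 5.0),
    "target_hardness": (1.0, 20.0),
    "daylight": (0.0, 10.0),
    "rain": (0.0, 1.0),
}

FIELDS = tuple(RANGES)


@dataclass(frozen=True)
class DifficultyConfig:
    """One setting of the six simulation variables.

    Units: ``target_size`` and ``target_hardness`` in simulator units,
    ``target_speed`` in m/s, ``daylight`` in simulator units (10 = full day),
    ``rain`` as an intensity fraction.
    """

    n_targets: int = 10
    target_size: float = 1.5
    target_speed: float = 0.0
    target_hardness: float = 10.0
    daylight: float = 8.0
    rain: float = 0.1

    def __post_init__(self) -> None:
        for name, (lo, hi) in RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside hard range [{lo}, {hi}]")

    def clamped(self, **updates: float) -> "DifficultyConfig":
        """Return a copy with ``updates`` applied and every field clamped
        to its hard range. Clamping is idempotent."""
        values = {f: getattr(self, f) for f in FIELDS}
        values.update(updates)
        for name, (lo, hi) in RANGES.items():
            values[name] = min(max(values[name], lo), hi)
        values["n_targets"] = int(round(values["n_targets"]))
        return DifficultyConfig(**values)

    def as_dict(self) -> Dict[str, float]:
        return {f: getattr(self, f) for f in FIELDS}


def difficulty_index(cfg: DifficultyConfig) -> float:
    """Scalar difficulty in [0, 1]: mean of min-max-normalized variables.

    Harder = more/faster/smaller/tougher targets, darker scene, heavier rain.
    Size enters through its reciprocal (small targets are hard), min-max
    normalized on the reciprocal scale.
    """
    lo_s, hi_s = RANGES["target_size"]
    inv = 1.0 / cfg.target_size
    parts = [
        (cfg.n_targets - RANGES["n_targets"][0])
        / (RANGES["n_targets"][1] - RANGES["n_targets"][0]),
        (inv - 1.0 / hi_s) / (1.0 / lo_s - 1.0 / hi_s),
        cfg.target_speed / RANGES["target_speed"][1],
        (cfg.target_hardness - RANGES["target_hardness"][0])
        / (RANGES["target_hardness"][1] - RANGES["target_hardness"][0]),
        (RANGES["daylight"][1] - cfg.daylight) / RANGES["daylight"][1],
        cfg.rain / RANGES["rain"][1],
    ]
    return float(sum(parts) / len(parts))


# Study presets: 3-min blocks; easy = 10 static targets, medium = 10 targets
# at 0.5 m/s, hard = 20 targets at 1 m/s; size and hardness held constant.
PRESETS: Dict[str, DifficultyConfig] = {
    "easy": DifficultyConfig(n_targets=10, target_speed=0.0),
    "medium": DifficultyConfig(n_targets=10, target_speed=0.5),
    "hard": DifficultyConfig(n_targets=20, target_speed=1.0),
}
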