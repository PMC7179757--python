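"""Simulator Sickness Questionnaire (SSQ) scoring.

Sixteen symptoms rated 0-3 (none / slight / moderate / severe) load onto
three clusters — nausea, oculomotor, disorientation — through a fixed 16x3
binary matrix (shipped as a data asset). Scale scores are the raw cluster
sums times the standard unit weights (N x 9.54, O x 7.58, D x 13.92) and
total severity TS = (raw_N + raw_O + raw_D) x 3.74. Cut-offs from the
instrument's calibration sample: 9.5 (N), 15.2 (O), 0 (D), 15 (TS); a
scale flags when its score strictly exceeds the cut-off (strict, so the
zero disorientation cut-off reads "any symptom").
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Tuple

import numpy as np

WEIGHT_N = 9.54
WEIGHT_O = 7.58
WEIGHT_D = 13.92
WEIGHT_TS = 3.74

CUTOFFS = {"nausea": 9.5, "oculomotor": 15.2, "disorientation": 0.0, "total": 15.0}


def _load_matrix() -> Tuple[Tuple[str, ...], np.ndarray]:
    path = resources.files("biocyber.data").joinpath("ssq_weights.csv")
    items = []
    rows = []
    with path.open() as fh:
        for row in csv.DictReader(fh):
            items.append(row["item"])
            rows.append(
                [int(row["nausea"]), int(row["oculomotor"]), int(row["disorientation"])]
            )
    return tuple(items), np.array(rows, dtype=int)


SSQ_ITEMS, LOADING_MATRIX = _load_matrix()


@dataclass(frozen=True)
class SSQResponse:
    """One respondent's 16 item ratings, each in {0, 1, 2, 3}."""

    items: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [it for it in SSQ_ITEMS if it not in self.items]
        if missing:
            raise ValueError(f"missing SSQ items: {missing}")
        for it in SSQ_ITEMS:
            v = self.items[it]
            if v not in (0, 1, 2, 3):
                raise ValueError(f"item {it!r} rating {v!r} not in 0..3")

    def vector(self) -> np.ndarray:
        return np.array([self.items[it] for it in SSQ_ITEMS], dtype=int)


@dataclass(frozen=True)
class SSQScores:
    nausea: float
    oculomotor: float
    disorientation: float
    total: float

    def __post_init__(self) -> None:
        if min(self.nausea, self.oculomotor, self.disorientation, self.total) < 0:
            raise ValueError("SSQ scores must be non-negative")

    @property
    def flags(self) -> Dict[str, bool]:
        return flag_cutoffs(self)


def score_ssq(r: SSQResponse) -> SSQScores:
    """Weighted cluster scores and total severity for one response."""
    v = r.vector()
    raw_n, raw_o, raw_d = (v @ LOADING_MATRIX).astype(float)
    return SSQScores(
        nausea=raw_n * WEIGHT_N,
        oculomotor=raw_o * WEIGHT_O,
        disorientation=raw_d * WEIGHT_D,
        total=(raw_n + raw_o + raw_d) * WEIGHT_TS,
    )


def flag_cutoffs(s: SSQScores) -> Dict[str, bool]:
    """True where a scale score strictly exceeds its cut-off."""
    return {
        "nausea": s.nausea > CUTOFFS["nausea"],
        "oculomotor": s.oculomotor > CUTOFFS["oculomotor"],
        "disorientation": s.disorientation > CUTOFFS["disorientation"],
        "total": s.total > CUTOFFS["total"],
    }


def generate_responses(n: int, seed: int, mean_rating: float = 0.35) -> Tuple[SSQResponse, ...]:
    """Synthetic mild-symptom responses (for end-to-end study runs).

    Item ratings are drawn independently with P(rating >= r) decaying
    geometrically, tuned by ``mean_rating`` toward the mild symptom levels
    a well-tolerated VR session produces.
    """
    rng = np.random.default_rng(seed)
    p = np.clip(mean_rating / 3.0, 0.0, 0.9)
    out = []
    for _ in range(n):
        ratings = rng.geometric(1.0 - p, size=len(SSQ_ITEMS)) - 1
        out.append(
            SSQResponse(items={it: int(min(3, r)) for it, r in zip(SSQ_ITEMS, ratings)})
        )
    return tuple(out)
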