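"""Nonparametric repeated-measures statistical battery.

For each psychophysiological feature observed over a participants x
conditions (baseline, easy, medium, hard) matrix:

* a Kolmogorov-Smirnov normality check (against a normal with the sample's
  own mean and sd),
* a Friedman omnibus test, reported as chi-square with df = k - 1 = 3,
* Wilcoxon signed-rank post-hocs (normal approximation, T = min(W+, W-),
  no continuity correction) with Bonferroni adjustment over the four
  planned contrasts: baseline vs each difficulty, and easy vs hard. With
  family alpha 0.05 the per-comparison level is 0.0125.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

CONDITIONS: Tuple[str, ...] = ("baseline", "easy", "medium", "hard")

#: the four planned post-hoc contrasts
PLANNED_CONTRASTS: Tuple[Tuple[str, str], ...] = (
    ("baseline", "easy"),
    ("baseline", "medium"),
    ("baseline", "hard"),
    ("easy", "hard"),
)

FAMILY_ALPHA = 0.05


def bonferroni_level(family_alpha: float = FAMILY_ALPHA, family_size: int = 4) -> float:
    """Per-comparison significance level under Bonferroni adjustment."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return family_alpha / family_size


@dataclass(frozen=True)
class NormalityResult:
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class PosthocResult:
    pair: Tuple[str, str]
    z: float
    p: float
    significant: bool
    n_used: int  # pairs remaining after dropping zero differences


@dataclass(frozen=True)
class StatsReport:
    """Full battery result for one feature."""

    feature: str
    normality: Mapping[str, NormalityResult]
    chi2: float
    df: int
    p: float
    posthoc: Tuple[PosthocResult, ...]
    adjusted_level: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": self.feature,
                "test": "friedman",
                "pair": "",
                "statistic": self.chi2,
                "df": self.df,
                "p": self.p,
                "significant": self.p < FAMILY_ALPHA,
            }
        ]
        for ph in self.posthoc:
            rows.append(
                {
                    "feature": self.feature,
                    "test": "wilcoxon",
                    "pair": f"{ph.pair[0]}-vs-{ph.pair[1]}",
                    "statistic": ph.z,
                    "df": np.nan,
                    "p": ph.p,
                    "significant": ph.significant,
                }
            )
        return pd.DataFrame(rows)


def normality_check(sample: Sequence[float]) -> NormalityResult:
    """KS test of the sample against a normal with its own mean and sd."""
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5 for the normality check")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityResult(p=float("nan"), degenerate=True)
    stat = sps.kstest(x, "norm", args=(x.mean(), sd))
    return NormalityResult(p=float(stat.pvalue), degenerate=False)


def _validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CONDITIONS if c not in m.columns]
    if missing:
        raise ValueError(f"feature matrix missing condition columns: {missing}")
    m = m[list(CONDITIONS)]
    if m.isna().any().any():
        raise ValueError("feature matrix has missing cells")
    if len(m) < 2:
        raise ValueError("need at least 2 participants")
    return m


def friedman_omnibus(m: pd.DataFrame) -> Dict[str, float]:
    """Friedman test over within-participant ranks (mid-ranks for ties).

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1), df = k - 1.
    """
    m = _validate_matrix(m)
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m.to_numpy(dtype=float))
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return {"chi2": float(chi2), "df": df, "p": p}


def wilcoxon_posthoc(
    a: Sequence[float],
    b: Sequence[float],
    family_size: int = 4,
    family_alpha: float = FAMILY_ALPHA,
) -> Dict[str, float]:
    """Wilcoxon signed-rank with the normal approximation.

    Zero differences are dropped (Wilcoxon's original treatment); ranks of
    |d| use mid-ranks for ties; T = min(W+, W-);
    Z = (T - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24), two-sided p, no continuity
    correction. ``significant`` applies the Bonferroni-adjusted level.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need n >= 5 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    t = min(w_plus, w_minus)
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (t - mu) / sigma
    p = float(2.0 * sps.norm.sf(abs(z)))
    level = bonferroni_level(family_alpha, family_size)
    return {
        "z": float(z),
        "p": p,
        "significant": bool(p < level),
        "n_used": n,
        "w_plus": w_plus,
        "w_minus": w_minus,
    }


def characterize(
    features: Mapping[str, pd.DataFrame],
    family_alpha: float = FAMILY_ALPHA,
) -> List[StatsReport]:
    """Run the full battery (normality, Friedman omnibus, four planned
    Wilcoxon post-hocs) on each feature matrix."""
    participants = None
    for name, m in features.items():
        m = _validate_matrix(m)
        idx = tuple(m.index)
        if participants is None:
            participants = idx
        elif idx != participants:
            raise ValueError(f"feature {name!r} has mismatched participants")
    reports: List[StatsReport] = []
    for name, m in features.items():
        m = _validate_matrix(m)
        normality = {c: normality_check(m[c]) for c in CONDITIONS}
        omni = friedman_omnibus(m)
        posthocs = []
        for pair in PLANNED_CONTRASTS:
            r = wilcoxon_posthoc(
                m[pair[0]], m[pair[1]],
                family_size=len(PLANNED_CONTRASTS), family_alpha=family_alpha,
            )
            posthocs.append(
                PosthocResult(
                    pair=pair, z=r["z"], p=r["p"],
                    significant=r["significant"], n_used=r["n_used"],
                )
            )
        reports.append(
            StatsReport(
                feature=name,
                normality=normality,
                chi2=omni["chi2"],
                df=int(omni["df"]),
                p=omni["p"],
                posthoc=tuple(posthocs),
                adjusted_level=bonferroni_level(family_alpha, len(PLANNED_CONTRASTS)),
            )
        )
    return reports
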