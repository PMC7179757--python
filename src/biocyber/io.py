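"""CSV dialects, configuration and the end-to-end study runner.

Interchange formats are deliberately plain CSV: the sensors in this
setting stream simple tabular data.

* RRI CSV: comment header (``# key=value`` lines carrying seed, package
  version, config hash and the unit), columns ``beat_index,rr``; units may
  be ``device_units`` (1/1024 s), ``ms`` or ``s`` and are normalized to
  device units on load.
* EEG CSV: same comment header, columns ``t_s,TP9,Fp1,Fp2,TP10`` (uV);
  the sampling rate is inferred from the median time step and more than
  1% timing jitter is rejected.

``run_full_study`` generates a seeded cohort following the session
protocol, extracts every HRV and EEG feature, runs the statistical
battery, scores synthetic SSQ responses, and writes tidy report tables.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .adaptation import shooting_performance
from .eeg import CHANNELS, EEGRecording, extract_features
from .hrv import DEVICE_UNITS_PER_SECOND, RRISeries, analyze
from .ssq import SSQ_ITEMS, generate_responses, score_ssq
from .stats import characterize
from .synthetic import CONDITIONS, CohortSpec, generate_cohort

RRI_UNITS = ("device_units", "ms", "s")

#: features reported by the full study, in presentation order
STUDY_FEATURES = (
    "frontal_theta", "theta_beta", "engagement", "asymmetry",
    "mean_hr", "sdnn", "rmssd", "vlf", "lf", "hf", "performance",
)

#: hit probabilities used to synthesise shooting performance per condition;
#: the difficulty levels use the characterization study's observed rates
#: and the baseline uses an unchallenged calibration round.
PERFORMANCE_P = {"baseline": 0.85, "easy": 0.64, "medium": 0.46, "hard": 0.24}


def _config_hash(payload: Mapping) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


def _header_lines(seed: int, extra: Optional[Mapping[str, str]] = None) -> List[str]:
    lines = [f"# seed={seed}", f"# version={__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def _parse_header(path: Path) -> Tuple[Dict[str, str], int]:
    """Returns (header key-values, number of leading comment lines)."""
    meta: Dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n


def save_rri_csv(path, rri: RRISeries, seed: int = 0, config: Optional[Mapping] = None) -> None:
    path = Path(path)
    extra = {"unit": "device_units", "config_hash": _config_hash(config or {})}
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(seed, extra)) + "\n")
        fh.write("beat_index,rr\n")
        for i, v in enumerate(rri.intervals):
            fh.write(f"{i},{int(v)}\n")


def load_rri_csv(path) -> RRISeries:
    """Load an RRI CSV, normalizing the declared unit to device units."""
    path = Path(path)
    meta, n_comments = _parse_header(path)
    unit = meta.get("unit")
    if unit not in RRI_UNITS:
        raise ValueError(
            f"{path}: header must declare unit in {RRI_UNITS}, got {unit!r}"
        )
    values = []
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = lines[n_comments:]
    if not data_lines:
        raise ValueError(f"{path}: empty file")
    header = data_lines[0].strip().split(",")
    try:
        rr_col = header.index("rr")
    except ValueError:
        raise ValueError(f"{path}: missing 'rr' column") from None
    for lineno, line in enumerate(data_lines[1:], start=n_comments + 2):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        try:
            values.append(float(parts[rr_col]))
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if not values:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(values, dtype=float)
    if unit == "ms":
        units = np.rint(arr / 1000.0 * DEVICE_UNITS_PER_SECOND)
    elif unit == "s":
        units = np.rint(arr * DEVICE_UNITS_PER_SECOND)
    else:
        units = np.rint(arr)
    return RRISeries(intervals=units.astype(np.int64), origin=str(path))


def save_eeg_csv(path, rec: EEGRecording, seed: int = 0, config: Optional[Mapping] = None) -> None:
    path = Path(path)
    extra = {"config_hash": _config_hash(config or {}), "fs_hz": f"{rec.fs:g}"}
    t = np.arange(rec.n_samples) / rec.fs
    frame = pd.DataFrame({"t_s": t})
    for i, ch in enumerate(rec.channels):
        frame[ch] = rec.data[i]
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(seed, extra)) + "\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def load_eeg_csv(path) -> EEGRecording:
    """Load an EEG CSV; sampling rate is inferred from the median time step."""
    path = Path(path)
    _, n_comments = _parse_header(path)
    frame = pd.read_csv(path, skiprows=n_comments)
    missing = [c for c in ("t_s",) + CHANNELS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    t = frame["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise ValueError(f"{path}: non-uniform sampling (jitter > 1%)")
    data = np.vstack([frame[ch].to_numpy(dtype=float) for ch in CHANNELS])
    return EEGRecording(fs=1.0 / med, data=data, channels=CHANNELS)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the end-to-end study runner."""

    seed: int = 0
    out_dir: Optional[str] = None
    n_participants: int = 10
    block_duration: float = 180.0
    eeg_fs: float = 500.0
    mean_shots: int = 50


@dataclass(frozen=True)
class StudyReport:
    features: pd.DataFrame  # tidy: participant, condition, feature, value
    stats: pd.DataFrame
    ssq: pd.DataFrame
    config_hash: str

    def feature_matrix(self, feature: str) -> pd.DataFrame:
        wide = self.features[self.features["feature"] == feature].pivot(
            index="participant", columns="condition", values="value"
        )
        return wide[list(CONDITIONS)]


def _synth_performance(rng: np.random.Generator, condition: str, mean_shots: int) -> float:
    shots = int(rng.integers(max(2, mean_shots - 10), mean_shots + 11))
    destroyed = int(rng.binomial(shots, PERFORMANCE_P[condition]))
    return shooting_performance(shots, destroyed)


def run_full_study(cfg: RunConfig) -> StudyReport:
    """Generate a cohort, extract features, run the battery, score SSQ.

    Writes ``features.csv``, ``stats_report.csv``, ``ssq_scores.csv`` and
    ``summary.txt`` under ``cfg.out_dir`` when given; all tables embed the
    seed, version and config hash in comment headers.
    """
    chash = _config_hash(cfg.__dict__)
    spec = CohortSpec(
        n_participants=cfg.n_participants,
        block_duration=cfg.block_duration,
        eeg_fs=cfg.eeg_fs,
        seed=cfg.seed,
    )
    records = generate_cohort(spec)
    perf_rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for rec in records:
        hrv = analyze(rec.rri).as_dict()
        eegf = extract_features(rec.eeg)
        values = {**hrv, **eegf}
        values["performance"] = _synth_performance(perf_rng, rec.condition, cfg.mean_shots)
        for feat in STUDY_FEATURES:
            rows.append(
                {
                    "participant": rec.participant,
                    "condition": rec.condition,
                    "feature": feat,
                    "value": values[feat],
                }
            )
    features = pd.DataFrame(rows)
    matrices = {
        feat: features[features["feature"] == feat]
        .pivot(index="participant", columns="condition", values="value")[list(CONDITIONS)]
        for feat in STUDY_FEATURES
    }
    reports = characterize(matrices)
    stats_frame = pd.concat([r.to_frame() for r in reports], ignore_index=True)

    responses = generate_responses(cfg.n_participants, cfg.seed + 2)
    ssq_rows = []
    for p, resp in enumerate(responses):
        s = score_ssq(resp)
        ssq_rows.append(
            {
                "participant": p,
                "nausea": s.nausea,
                "oculomotor": s.oculomotor,
                "disorientation": s.disorientation,
                "total": s.total,
                **{f"flag_{k}": v for k, v in s.flags.items()},
            }
        )
    ssq_frame = pd.DataFrame(ssq_rows)

    report = StudyReport(
        features=features, stats=stats_frame, ssq=ssq_frame, config_hash=chash
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hdr = "\n".join(_header_lines(cfg.seed, {"config_hash": chash})) + "\n"
        for name, frame in (
            ("features.csv", features),
            ("stats_report.csv", stats_frame),
            ("ssq_scores.csv", ssq_frame),
        ):
            with open(out / name, "w") as fh:
                fh.write(hdr)
                frame.to_csv(fh, index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(hdr)
            for r in reports:
                fh.write(
                    f"{r.feature}: chi2({r.df}) = {r.chi2:.2f}, p = {r.p:.4f}\n"
                )
                for ph in r.posthoc:
                    star = "*" if ph.significant else ""
                    fh.write(
                        f"  {ph.pair[0]} vs {ph.pair[1]}: Z = {ph.z:.2f}, "
                        f"p = {ph.p:.4f}{star}\n"
                    )
    return report
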