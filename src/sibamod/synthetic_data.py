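"""Synthetic wearable cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes for a
6-month outpatient study: monthly MADRS visits, baseline severity 20-42,
exponential recovery at a known rate λ_true with AR(1) day-to-day
fluctuation, optional relapse episodes, a planted subset of features that
carry the severity signal through deliberately nonlinear link functions
(identity, negation, saturation, threshold step), decoy features with weekly
rhythm, and device-off gaps of 1-3 days.

Relapses are transient re-elevations (a logistic rise of
``relapse_magnitude`` over a few days) followed by renewed recovery at
λ_true, i.e. relapse then treatment adjustment.  They are on by default at a
moderate rate: a cohort in which every patient recovers monotonically spends
months 4-6 entirely in the healthy class, which neither matches the mixed
class balance of real outpatient cohorts nor exercises the classifier.

Every level is seeded: the same ``SimConfig.seed`` reproduces the cohort
byte-for-byte.  Ground truth (latent severity, planted feature ids, relapse
days) is returned separately and is never read by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .cohort_io import (
    DEFAULT_GROUP_SIZES,
    PatientRecord,
    Visit,
    default_feature_names,
    write_cohort,
)
from .pipeline import stable_seed

LINK_KINDS = ("identity", "negation", "saturating", "step")


@dataclass
class SimConfig:
    """Cohort-generator settings; defaults are the study conditions."""

    n_patients: int = 8
    n_days: int = 180
    visit_days: tuple[int, ...] = (0, 30, 60, 90, 120, 150, 180)
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    signature_size_true: int = 10
    trend_fraction: float = 0.3  # planted features tracking 7-day change, not level
    lam_true: float = 1.6  # percent/day
    baseline_madrs_range: tuple[float, float] = (20.0, 42.0)
    severity_noise_sd: float = 2.0  # AR(1) innovation, MADRS points
    ar_persistence: float = 0.8
    feature_noise_sd: float = 0.1
    missing_rate: float = 0.05
    relapse_prob: float = 0.5
    relapse_magnitude: float = 35.0
    relapse_day_range: tuple[int, int] = (55, 105)
    relapse_sustained_prob: float = 0.25  # fraction of relapses with no re-recovery
    shared_core_fraction: float = 0.5
    visit_noise: int = 2  # integer observation noise in {-2..2}
    seed: int = 0

    @property
    def n_features(self) -> int:
        return sum(self.group_sizes.values())

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (1 <= self.signature_size_true <= self.n_features):
            raise ValueError("signature_size_true out of range")


@dataclass
class GroundTruth:
    """Per-patient latent state; for parameter-recovery tests only."""

    patient_id: str
    severity: np.ndarray  # daily latent s(t)
    planted_ids: list[str]
    links: dict[str, str]
    lam_true: float
    relapse_day: int | None
    baseline_adjusted: bool = False


def simulate_severity(
    config: SimConfig,
    patient_seed: int,
    relapse: bool | None = None,
    sustained: bool | None = None,
    relapse_day: int | None = None,
) -> tuple[np.ndarray, int | None]:
    """Daily latent severity s(t) in [0, 60] and the relapse day (or None).

    s(t) = s0·(1 − λ/100)^t + relapse term + AR(1) noise, clipped to [0, 60].
    ``relapse``/``sustained``/``relapse_day`` override the per-patient draws
    (the cohort generator assigns them as a stratified design so cohort
    composition does not wobble with the seed).
    """
    rng = np.random.default_rng(patient_seed)
    t = np.arange(config.n_days, dtype=float)
    lo, hi = config.baseline_madrs_range
    s0 = rng.uniform(lo, hi)
    rate = 1.0 - config.lam_true / 100.0
    s = s0 * rate**t

    if relapse is None:
        relapse = rng.random() < config.relapse_prob
    if sustained is None:
        sustained = rng.random() < config.relapse_sustained_prob
    if relapse:
        if relapse_day is None:
            d0, d1 = config.relapse_day_range
            relapse_day = int(rng.integers(d0, min(d1, config.n_days - 10) + 1))
    else:
        relapse_day = None
    if relapse:
        rise = config.relapse_magnitude / (1.0 + np.exp(-(t - relapse_day) / 2.0))
        if sustained:  # non-responder: the episode persists
            s = s + rise
        else:
            # renewed recovery at lam_true as soon as the rise completes, so
            # the post-relapse trajectory is again a clean lam_true decay
            redecay = rate ** np.clip(t - relapse_day - 3, 0.0, None)
            s = s + rise * redecay

    if config.severity_noise_sd > 0:
        e = np.zeros(config.n_days)
        innov = rng.normal(0.0, config.severity_noise_sd, size=config.n_days)
        for i in range(1, config.n_days):
            e[i] = config.ar_persistence * e[i - 1] + innov[i]
        s = s + e
    return np.clip(s, 0.0, 60.0), relapse_day


def _apply_link(kind: str, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if kind == "identity":
        return u
    if kind == "negation":
        return 1.0 - u
    if kind == "saturating":
        return 1.0 - np.exp(-3.0 * u)
    if kind == "step":
        theta = rng.uniform(0.25, 0.55)
        return (u > theta).astype(float)
    raise ValueError(f"unknown link kind: {kind}")


def emit_features(
    severity: np.ndarray,
    config: SimConfig,
    patient_seed: int,
    planted_ids: Sequence[str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Daily feature matrix: planted features are (noisy, nonlinearly linked)
    transforms of the severity state; decoys are smoothed noise with weekly
    rhythm.  Device-off gaps blank whole days.  Returns (matrix, link map).

    A ``trend_fraction`` of the planted features track the 7-day severity
    *change* rather than its level — physiology reflects the direction of a
    mood shift as well as its state, and a relapse in progress is a different
    phenotype than an equally severe stable baseline.
    """
    rng = np.random.default_rng(stable_seed(patient_seed, "features"))
    names, _groups = default_feature_names(config.group_sizes)
    n_days = severity.size
    u = severity / 60.0
    delta7 = severity - np.concatenate([np.full(7, severity[0]), severity[:-7]])
    # half level, half 7-day change: keeps the feature severity-dependent
    # (selectable) while encoding whether the state is rising or falling
    u_trend = np.clip(0.5 * u + 0.5 * (0.5 + delta7 / 30.0), 0.0, 1.0)
    planted = set(planted_ids)
    n_trend = int(round(config.trend_fraction * len(planted_ids)))
    trend_set = set(sorted(planted_ids)[:n_trend])  # deterministic assignment
    links: dict[str, str] = {}
    cols = {}
    t = np.arange(n_days, dtype=float)
    for j, name in enumerate(names):
        if name in planted:
            kind = LINK_KINDS[len(links) % len(LINK_KINDS)]
            latent = u_trend if name in trend_set else u
            links[name] = f"{'trend' if name in trend_set else 'level'}:{kind}"
            base = _apply_link(kind, latent, rng)
            base = base + rng.normal(0.0, config.feature_noise_sd, size=n_days)
        else:
            amp = rng.uniform(0.2, 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            noise = np.convolve(rng.normal(0.0, 1.0, size=n_days), np.ones(3) / 3.0, mode="same")
            base = amp * np.sin(2.0 * np.pi * t / 7.0 + phase) + 0.5 * noise
        scale = rng.uniform(0.5, 2.0)
        offset = rng.uniform(-1.0, 1.0)
        cols[name] = scale * base + offset
    df = pd.DataFrame(cols, index=pd.RangeIndex(n_days, name="day"))

    if config.missing_rate > 0:
        gap_rng = np.random.default_rng(stable_seed(patient_seed, "gaps"))
        day = 0
        while day < n_days:
            if gap_rng.random() < config.missing_rate / 2.0:  # mean gap length 2
                length = int(gap_rng.integers(1, 4))
                df.iloc[day : day + length] = np.nan
                day += length
            else:
                day += 1
    return df, links


def emit_visits(
    severity: np.ndarray, config: SimConfig, patient_seed: int
) -> tuple[list[Visit], bool]:
    """Monthly MADRS: round(s) plus small integer observation noise, clipped
    to 0-60; the baseline score is forced to >= 20 (inclusion criterion).
    Returns (visits, baseline_adjusted flag)."""
    rng = np.random.default_rng(stable_seed(patient_seed, "visits"))
    n_days = severity.size
    days = sorted({min(int(d), n_days - 1) for d in config.visit_days if int(d) <= n_days})
    visits = []
    adjusted = False
    for i, d in enumerate(days):
        noise = int(rng.integers(-config.visit_noise, config.visit_noise + 1)) if config.visit_noise else 0
        m = int(np.clip(round(float(severity[d])) + noise, 0, 60))
        if i == 0 and m < 20:
            m = 20
            adjusted = True
        visits.append(Visit(day=d, madrs=m))
    return visits, adjusted


def _planted_sets(config: SimConfig, rng: np.random.Generator) -> list[list[str]]:
    """Per-patient planted feature ids; a fraction of patients shares a
    common core so cohort apparition counts are neither 1 nor n_patients."""
    names, _ = default_feature_names(config.group_sizes)
    k = config.signature_size_true
    core_size = max(1, k // 2)
    core = [str(x) for x in rng.choice(names, size=core_size, replace=False)]
    sets = []
    for _ in range(config.n_patients):
        if rng.random() < config.shared_core_fraction:
            rest = [n for n in names if n not in core]
            extras = [str(x) for x in rng.choice(rest, size=k - core_size, replace=False)]
            sets.append(sorted(core + extras))
        else:
            sets.append(sorted(str(x) for x in rng.choice(names, size=k, replace=False)))
    return sets


def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Simulate ``config.n_patients`` records plus their ground truths."""
    rng = np.random.default_rng(config.seed)
    _names, groups = default_feature_names(config.group_sizes)
    planted_sets = _planted_sets(config, rng)
    records, truths = [], []
    # Stratified relapse design: a fixed count of relapsers (random patient
    # assignment) with onsets spread evenly over the onset range (plus
    # jitter), so every cohort carries the full continuum of relapse timing.
    # The non-responders (sustained episodes) are the relapsers just before
    # the latest onset: their elevation is already visible at month 3 and
    # persists through the test period.
    n = config.n_patients
    n_relapse = int(round(config.relapse_prob * n))
    n_sustained = int(round(config.relapse_sustained_prob * n_relapse))
    relapse_idx = [int(i) for i in rng.choice(n, size=n_relapse, replace=False)] if n_relapse else []
    d0, d1 = config.relapse_day_range
    d1 = min(d1, config.n_days - 10)
    onset_days = {}
    for j, i in enumerate(relapse_idx):
        center = d0 + (d1 - d0) * (j + 0.5) / n_relapse
        onset_days[i] = int(np.clip(round(center + rng.uniform(-4, 4)), d0, d1))
    by_onset = sorted(relapse_idx, key=lambda i: onset_days[i])
    lo_cut = max(0, len(by_onset) - 1 - n_sustained)
    sustained_idx = set(by_onset[lo_cut : len(by_onset) - 1]) if n_sustained else set()

    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        pseed = stable_seed(config.seed, "patient", i)
        severity, relapse_day = simulate_severity(
            config,
            pseed,
            relapse=i in onset_days,
            sustained=i in sustained_idx,
            relapse_day=onset_days.get(i),
        )
        features, links = emit_features(severity, config, pseed, planted_sets[i])
        visits, adjusted = emit_visits(severity, config, pseed)
        rec = PatientRecord(
            patient_id=pid,
            n_days=config.n_days,
            features=features,
            feature_groups=dict(groups),
            visits=visits,
        ).validate()
        records.append(rec)
        truths.append(
            GroundTruth(
                patient_id=pid,
                severity=severity,
                planted_ids=list(planted_sets[i]),
                links=links,
                lam_true=config.lam_true,
                relapse_day=relapse_day,
                baseline_adjusted=adjusted,
            )
        )
    return records, truths


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    """Ground-truth JSON (separate file; the pipeline never reads it)."""
    payload = [
        {
            "patient_id": t.patient_id,
            "severity": [float(v) for v in t.severity],
            "planted_ids": t.planted_ids,
            "links": t.links,
            "lam_true": t.lam_true,
            "relapse_day": t.relapse_day,
            "baseline_adjusted": t.baseline_adjusted,
        }
        for t in truths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_synthetic_cohort(config: SimConfig, directory: str | Path) -> Path:
    """Generate and write a cohort directory plus ``ground_truth.json``."""
    records, truths = generate_cohort(config)
    manifest = write_cohort(records, directory)
    write_ground_truth(truths, Path(directory) / "ground_truth.json")
    return manifest
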