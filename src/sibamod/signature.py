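"""Individual depression biosignature: HSIC feature ranking.

Each physiological feature is scored against the day-aligned MADRS labels
with the biased empirical Hilbert-Schmidt Independence Criterion,

    HSIC(x, y) = (n - 1)^-2 · tr(K H L H),

with Gaussian kernels k(a, b) = exp(−(a − b)² / (2σ²)), per-variable median-
heuristic bandwidths, and H the centering matrix.  HSIC is zero in
expectation iff the variables are independent, and unlike Pearson/Spearman
coefficients it detects non-monotonic dependence.  The ν top-scoring features
form the patient's biosignature.  The (n−1)^-2 constant cancels in ranking.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import FEATURE_GROUPS


def median_heuristic_bandwidth(values: np.ndarray) -> float:
    """Median of pairwise absolute differences over distinct pairs.

    Returns 1.0 for a constant input (median 0), so downstream kernels stay
    defined.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 2:
        raise ValueError("median heuristic needs at least 2 values")
    diffs = np.abs(v[:, None] - v[None, :])[np.triu_indices(n, k=1)]
    med = float(np.median(diffs))
    return med if med > 0 else 1.0


def _gaussian_gram(v: np.ndarray, sigma: float) -> np.ndarray:
    d = v[:, None] - v[None, :]
    return np.exp(-(d * d) / (2.0 * sigma * sigma))


def hsic(x: np.ndarray, y: np.ndarray) -> float:
    """Biased empirical HSIC with Gaussian kernels (median-heuristic σ).

    Non-negative up to numerical error; tiny negative values are floored at 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("hsic needs at least 2 samples")
    K = _gaussian_gram(x, median_heuristic_bandwidth(x))
    L = _gaussian_gram(y, median_heuristic_bandwidth(y))
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    value = np.trace(K @ H @ L @ H) / (n - 1) ** 2
    return max(float(value), 0.0)


@dataclass(frozen=True)
class SignatureEntry:
    feature_name: str
    hsic_score: float
    group: str


@dataclass
class Biosignature:
    """Ordered top-ν features: entries sorted by HSIC score descending, ties
    broken by ascending feature index (deterministic)."""

    nu: int
    entries: list[SignatureEntry]
    fit_day_set: list[int]

    @property
    def feature_names(self) -> list[str]:
        return [e.feature_name for e in self.entries]

    def to_dict(self) -> dict:
        return {
            "nu": self.nu,
            "entries": [
                {"feature_name": e.feature_name, "hsic_score": float(e.hsic_score), "group": e.group}
                for e in self.entries
            ],
            "fit_day_set": [int(d) for d in self.fit_day_set],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Biosignature":
        return cls(
            nu=int(d["nu"]),
            entries=[SignatureEntry(e["feature_name"], float(e["hsic_score"]), e["group"]) for e in d["entries"]],
            fit_day_set=[int(x) for x in d["fit_day_set"]],
        )


def _ranked_entries(scores: np.ndarray, names: Sequence[str], groups: Mapping[str, str]) -> list[SignatureEntry]:
    order = np.lexsort((np.arange(len(names)), -scores))
    return [SignatureEntry(names[i], float(scores[i]), groups[names[i]]) for i in order]


def rank_features_hsic(
    features: pd.DataFrame, labels: np.ndarray, feature_groups: Mapping[str, str]
) -> list[SignatureEntry]:
    """All features ranked by HSIC against the labels (used by selection; the
    top-ν signature for any ν is a prefix of this ranking)."""
    y = np.asarray(labels, dtype=float).ravel()
    if len(features) != y.size:
        raise ValueError("features and labels must align day-wise")
    if y.size < 2:
        raise ValueError("need at least 2 labeled days")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    sigma_y = median_heuristic_bandwidth(y)
    L = _gaussian_gram(y, sigma_y)
    n = y.size
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    HLH = H @ L @ H
    scores = np.empty(len(names))
    for j in range(len(names)):
        K = _gaussian_gram(X[:, j], median_heuristic_bandwidth(X[:, j]))
        scores[j] = max(float(np.sum(K * HLH.T)) / (n - 1) ** 2, 0.0)
    return _ranked_entries(scores, names, feature_groups)


def select_biosignature(
    features: pd.DataFrame,
    labels: np.ndarray,
    nu: int,
    feature_groups: Mapping[str, str],
) -> Biosignature:
    """Top-ν HSIC-ranked features over the labeled train+validation days."""
    if not (1 <= nu <= features.shape[1]):
        raise ValueError(f"nu must be in [1, {features.shape[1]}], got {nu}")
    ranked = rank_features_hsic(features, labels, feature_groups)
    return Biosignature(nu=nu, entries=ranked[:nu], fit_day_set=[int(d) for d in features.index])


def select_by_pearson(
    features: pd.DataFrame,
    labels: np.ndarray,
    nu: int,
    feature_groups: Mapping[str, str],
) -> Biosignature:
    """Comparison selector: top-ν by absolute Pearson correlation.

    Used in ablations/benchmarks against the HSIC selector; constant features
    score 0.
    """
    if not (1 <= nu <= features.shape[1]):
        raise ValueError(f"nu must be in [1, {features.shape[1]}], got {nu}")
    y = np.asarray(labels, dtype=float).ravel()
    X = features.to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs((xc * yc[:, None]).sum(axis=0) / denom)
    r = np.nan_to_num(r, nan=0.0)
    entries = _ranked_entries(r, list(features.columns), feature_groups)
    return Biosignature(nu=nu, entries=entries[:nu], fit_day_set=[int(d) for d in features.index])


def group_counts(sig: Biosignature) -> dict[str, int]:
    """Features per physiological group; every group reported, empty ones as 0."""
    counts = {g: 0 for g in FEATURE_GROUPS}
    for e in sig.entries:
        counts[e.group] = counts.get(e.group, 0) + 1
    return counts


def apparition_histogram(signatures: Iterable[Biosignature]) -> dict[str, int]:
    """How many patients' signatures each feature appears in."""
    sigs = list(signatures)
    if not sigs:
        raise ValueError("need at least one signature")
    counter: Counter[str] = Counter()
    for sig in sigs:
        counter.update(sig.feature_names)
    return dict(counter)
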