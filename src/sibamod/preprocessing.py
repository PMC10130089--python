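"""Daily feature preprocessing: mean-filter smoothing, interpolation imputation
and per-feature min-max normalization.

The pipeline order is fixed: filter -> impute -> normalize.  Normalization
parameters are fitted on a caller-supplied day set (by default the training
period only) and applied with clipping, so test days can never push values
outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


def mean_filter(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over available values; window must be odd.

    The value at day t is the mean of the non-missing values in
    ``[t - window//2, t + window//2]`` truncated at the series boundaries.
    A day whose whole window is missing stays missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be a non-empty 1-d array")
    if window == 1:
        return x.copy()
    present = np.isfinite(x)
    kernel = np.ones(window)
    half = window // 2
    # center slice of the full convolution ('same' misbehaves for series
    # shorter than the window)
    sums = np.convolve(np.where(present, x, 0.0), kernel, mode="full")[half : half + x.size]
    counts = np.convolve(present.astype(float), kernel, mode="full")[half : half + x.size]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def impute_missing(series: np.ndarray, name: str = "feature") -> np.ndarray:
    """Fill gaps: linear interpolation inside, nearest-value fill at the edges."""
    x = np.asarray(series, dtype=float)
    obs = np.flatnonzero(np.isfinite(x))
    if obs.size == 0:
        raise ValueError(f"{name} has no observations")
    # np.interp is linear between observed points and clamps at the edges,
    # which is exactly the stated rule.
    return np.interp(np.arange(x.size), obs, x[obs])


@dataclass
class NormalizationParams:
    """Per-feature min/max fitted on ``fit_days``; ``max >= min`` everywhere.

    Features with ``max == min`` are degenerate and map to 0 under
    :func:`apply_normalization`.
    """

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    fit_days: list[int] = field(default_factory=list)

    @property
    def degenerate(self) -> np.ndarray:
        return self.maxs <= self.mins

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
            "fit_days": [int(d) for d in self.fit_days],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            feature_names=list(d["feature_names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            fit_days=[int(x) for x in d["fit_days"]],
        )


def fit_normalization(features: pd.DataFrame, fit_days: Sequence[int]) -> NormalizationParams:
    """Fit per-feature min/max over ``fit_days`` only (imputation already done)."""
    fit_days = [int(d) for d in fit_days]
    if len(fit_days) == 0:
        raise ValueError("fit_days must be non-empty")
    sub = features.loc[fit_days]
    vals = sub.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("fit_normalization requires imputed (complete) features")
    return NormalizationParams(
        feature_names=list(features.columns),
        mins=vals.min(axis=0),
        maxs=vals.max(axis=0),
        fit_days=fit_days,
    )


def apply_normalization(features: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Map each feature to ``(x - min) / (max - min)``, clipped to [0, 1].

    Degenerate (constant) features map to 0 everywhere.
    """
    if list(features.columns) != list(params.feature_names):
        raise ValueError("feature names do not match normalization params")
    x = features.to_numpy(dtype=float)
    span = params.maxs - params.mins
    deg = params.degenerate
    safe_span = np.where(deg, 1.0, span)
    out = (x - params.mins) / safe_span
    out[:, deg] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def preprocess(features: pd.DataFrame, smoothing_window: int = 3) -> pd.DataFrame:
    """Smooth and impute every feature column (no normalization)."""
    out = {}
    for name in features.columns:
        smoothed = mean_filter(features[name].to_numpy(dtype=float), smoothing_window)
        out[name] = impute_missing(smoothed, name=name)
    return pd.DataFrame(out, index=features.index, columns=features.columns)
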