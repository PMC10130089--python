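"""Label extension and optimistic detrending.

MADRS is observed only at monthly visits.  Two steps turn the sparse visits
into a daily regression target:

* **extension** copies each visit's score to the ±window days around it
  (default ±5), justified by the scale's short-term test-retest reliability;
* **detrending** subtracts an "optimistic" zero-training-parameter disease
  model, M̂(t) = M_v · (1 − λ/100)^(t − t_v), anchored at the most recent
  clinical evaluation, leaving the *residual MADRS* as the learning target.

λ is a recovery rate in percent per day (λ = 1.6 means a 1.6 %/day
multiplicative improvement).  Retrending adds the optimistic prediction back
to a residual and clips to the MADRS range [0, 60].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort_io import MADRS_MAX, MADRS_MIN, Visit


@dataclass(frozen=True)
class OptimisticModel:
    """Recovery disease model with rate ``lam`` (percent/day).

    ``form`` selects the decay shape: ``"exponential"`` (default; daily
    multiplicative improvement toward ``decay_target``) or ``"linear"``
    (fixed fraction of the anchor score shed per day, floored at the
    target).
    """

    lam: float
    decay_target: float = 0.0  # asymptote of the recovery, in MADRS points
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.lam / 100.0 >= 1.0:
            raise ValueError(f"lam/100 must be < 1, got lam={self.lam}")
        if self.form not in ("exponential", "linear"):
            raise ValueError(f"unknown decay form: {self.form}")


@dataclass(frozen=True)
class LabeledDay:
    day: int
    madrs: int
    source_visit: Visit


@dataclass
class ExtendedLabels:
    """Day-indexed MADRS labels produced by window extension."""

    entries: dict[int, LabeledDay]

    @property
    def days(self) -> list[int]:
        return sorted(self.entries)

    def values(self) -> np.ndarray:
        return np.array([self.entries[d].madrs for d in self.days], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ResidualDay:
    day: int
    residual: float
    anchor: Visit
    source_visit: Visit


@dataclass
class ResidualLabels:
    """Residual MADRS per day; each entry keeps its optimistic anchor so the
    detrend -> retrend round trip is exact."""

    entries: dict[int, ResidualDay]

    @property
    def days(self) -> list[int]:
        return sorted(self.entries)

    def values(self) -> np.ndarray:
        return np.array([self.entries[d].residual for d in self.days], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


def extend_labels(visits: Sequence[Visit], n_days: int, window: int) -> ExtendedLabels:
    """Label each day within ``window`` of a visit with that visit's MADRS.

    Overlapping windows are resolved to the nearest visit; exact distance ties
    go to the earlier visit.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    entries: dict[int, LabeledDay] = {}
    best_dist: dict[int, int] = {}
    for v in visits:  # visits are strictly increasing, so earlier wins ties
        lo = max(0, v.day - window)
        hi = min(n_days - 1, v.day + window)
        for day in range(lo, hi + 1):
            dist = abs(day - v.day)
            if day not in entries or dist < best_dist[day]:
                entries[day] = LabeledDay(day=day, madrs=v.madrs, source_visit=v)
                best_dist[day] = dist
    return ExtendedLabels(entries=entries)


def optimistic_predict(model: OptimisticModel, last_visit: Visit, day: int) -> float:
    """Optimistic MADRS estimate for ``day`` given the most recent visit.

    ``M_v · (1 − λ/100)^(day − t_v)`` (decaying toward ``decay_target``),
    clipped to [0, 60].
    """
    dt = day - last_visit.day
    if dt < 0:
        raise ValueError(f"day {day} is before the anchor visit at {last_visit.day}")
    target = model.decay_target
    if model.form == "linear":
        pred = last_visit.madrs - last_visit.madrs * model.lam / 100.0 * dt
        pred = max(pred, target)
    else:
        rate = 1.0 - model.lam / 100.0
        pred = target + (last_visit.madrs - target) * rate**dt
    return float(np.clip(pred, MADRS_MIN, MADRS_MAX))


def _anchor_for_source(visits: Sequence[Visit], source: Visit) -> Visit:
    """Latest visit strictly before ``source``; the baseline anchors itself."""
    anchor = None
    for v in visits:
        if v.day < source.day:
            anchor = v
    return anchor if anchor is not None else source


def detrend(extended: ExtendedLabels, visits: Sequence[Visit], model: OptimisticModel) -> ResidualLabels:
    """Residual MADRS: extended label minus the optimistic prediction.

    For a day in visit v's window the anchor is the latest visit strictly
    before v (v itself for the baseline visit), so residuals around each
    follow-up measure the departure from the recovery predicted at the
    *previous* evaluation.  Δt is clamped at 0 for days before the anchor.
    """
    if not visits:
        raise ValueError("detrend requires at least one visit")
    entries: dict[int, ResidualDay] = {}
    for day, lab in extended.entries.items():
        anchor = _anchor_for_source(visits, lab.source_visit)
        pred = optimistic_predict(model, anchor, max(day, anchor.day))
        entries[day] = ResidualDay(day=day, residual=lab.madrs - pred, anchor=anchor, source_visit=lab.source_visit)
    return ResidualLabels(entries=entries)


def retrend_labels(residuals: ResidualLabels, model: OptimisticModel) -> dict[int, float]:
    """Exact inverse of :func:`detrend` (uses each entry's stored anchor)."""
    out: dict[int, float] = {}
    for day, e in residuals.entries.items():
        pred = optimistic_predict(model, e.anchor, max(day, e.anchor.day))
        out[day] = float(np.clip(e.residual + pred, MADRS_MIN, MADRS_MAX))
    return out


def retrend(
    residual_predictions: Mapping[int, float],
    visits: Sequence[Visit],
    model: OptimisticModel,
) -> dict[int, float]:
    """Absolute MADRS prediction: optimistic anchor + predicted residual.

    The anchor for day d is the most recent visit in ``visits`` with
    ``day <= d`` (the first visit, with Δt clamped to 0, for earlier days).
    At test time pass only the training-period visits so no future clinical
    information is consumed.
    """
    if not visits:
        raise ValueError("retrend requires at least one visit")
    out: dict[int, float] = {}
    for day, res in residual_predictions.items():
        anchor = visits[0]
        for v in visits:
            if v.day <= day:
                anchor = v
        pred = optimistic_predict(model, anchor, max(day, anchor.day))
        out[int(day)] = float(np.clip(pred + res, MADRS_MIN, MADRS_MAX))
    return out


def optimistic_curve(visits: Sequence[Visit], model: OptimisticModel, days: Iterable[int]) -> dict[int, float]:
    """Optimistic prediction alone for each requested day (residual ≡ 0)."""
    return retrend({int(d): 0.0 for d in days}, visits, model)
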