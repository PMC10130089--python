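"""Patient/cohort data model and on-disk formats.

A patient is stored as two text files:

* a wide CSV of daily features (``day,<feat1>,...,<featK>``), one row per day,
  missing measurements as empty cells (an explicit ``NA`` token is also read);
* a JSON file with the visit list (``{"day": int, "madrs": int}``), the
  feature-group map, and the study length.

The calendar is an integer day index from enrollment (day 0); there are no
wall-clock dates anywhere.  A cohort directory holds one file pair per patient
plus a ``cohort.json`` manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sibamod")

#: Canonical feature groups and their default sizes (12+25+39+12+13 = 101).
FEATURE_GROUPS: tuple[str, ...] = ("activity", "heart_rate", "hrv", "breathing", "sleep")
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "activity": 12,
    "heart_rate": 25,
    "hrv": 39,
    "breathing": 12,
    "sleep": 13,
}

MADRS_MIN, MADRS_MAX = 0, 60


def default_feature_names(group_sizes: Mapping[str, int] | None = None) -> tuple[list[str], dict[str, str]]:
    """Generate feature names (``activity_00`` ...) and their group map."""
    sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    names: list[str] = []
    groups: dict[str, str] = {}
    for g in FEATURE_GROUPS:
        for i in range(sizes.get(g, 0)):
            name = f"{g}_{i:02d}"
            names.append(name)
            groups[name] = g
    return names, groups


@dataclass(frozen=True)
class Visit:
    """One clinical visit: study day and the MADRS total score (integer 0-60)."""

    day: int
    madrs: int

    def __post_init__(self) -> None:
        if not (MADRS_MIN <= self.madrs <= MADRS_MAX):
            raise ValueError(f"madrs out of range at day {self.day}: {self.madrs}")
        if self.day < 0:
            raise ValueError(f"visit day must be >= 0, got {self.day}")


@dataclass
class PatientRecord:
    """One patient's daily feature matrix, visit list and study calendar.

    ``features`` is a DataFrame indexed by day 0..n_days-1 with one column per
    feature; missing measurements are NaN.  The day index is the single source
    of time ordering.
    """

    patient_id: str
    n_days: int
    features: pd.DataFrame
    feature_groups: dict[str, str]
    visits: list[Visit]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def validate(self) -> "PatientRecord":
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        idx = self.features.index.to_numpy()
        if len(idx) != self.n_days or not np.array_equal(idx, np.arange(self.n_days)):
            raise ValueError("features must have one row per day 0..n_days-1")
        days = [v.day for v in self.visits]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("visit days must be strictly increasing")
        if days and (days[0] < 0 or days[-1] >= self.n_days):
            raise ValueError("visit days must lie in [0, n_days)")
        for name in self.features.columns:
            g = self.feature_groups.get(name)
            if g is None:
                raise ValueError(f"feature missing from group map: {name}")
            if g not in FEATURE_GROUPS:
                raise ValueError(f"unknown feature group for {name}: {g}")
        return self


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters for one patient.

    ``train_end_day`` is the day of the last training visit (month 3);
    labels within ``extension_window`` days of a training visit are training
    labels, everything after is test.  ``val_fraction`` of the labeled
    training days forms the validation set for early stopping and is fixed per
    patient (identical across ensemble repeats).
    """

    train_end_day: int
    extension_window: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extension_window < 0:
            raise ValueError("extension_window must be >= 0")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_patient(features_path: str | Path, visits_path: str | Path) -> PatientRecord:
    """Read one patient from a wide feature CSV and a visits JSON."""
    df = pd.read_csv(features_path, na_values=["NA"], keep_default_na=True)
    if "day" not in df.columns:
        raise ValueError(f"{features_path}: first column must be 'day'")
    if df["day"].duplicated().any():
        dup = int(df.loc[df["day"].duplicated(), "day"].iloc[0])
        raise ValueError(f"duplicate day in {features_path}: day={dup}")
    df = df.sort_values("day").set_index("day")
    df.index = df.index.astype(int)

    with open(visits_path) as fh:
        meta = json.load(fh)
    visits = [Visit(day=int(v["day"]), madrs=int(v["madrs"])) for v in meta["visits"]]
    groups = dict(meta["feature_groups"])
    n_days = int(meta.get("n_days", df.index.max() + 1))

    full = df.reindex(np.arange(n_days))
    full.index.name = "day"
    rec = PatientRecord(
        patient_id=str(meta.get("patient_id", Path(visits_path).stem)),
        n_days=n_days,
        features=full.astype(float),
        feature_groups=groups,
        visits=visits,
    )
    return rec.validate()


def write_patient(record: PatientRecord, features_path: str | Path, visits_path: str | Path) -> None:
    """Write a patient record in the format :func:`read_patient` reads."""
    record.validate()
    out = record.features.copy()
    out.insert(0, "day", out.index)
    out.to_csv(features_path, index=False)
    meta = {
        "patient_id": record.patient_id,
        "n_days": record.n_days,
        "visits": [{"day": v.day, "madrs": v.madrs} for v in record.visits],
        "feature_groups": record.feature_groups,
    }
    with open(visits_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def write_cohort(records: Sequence[PatientRecord], directory: str | Path) -> Path:
    """Write a cohort directory (per-patient file pairs + manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for rec in records:
        fcsv = f"{rec.patient_id}_features.csv"
        vjson = f"{rec.patient_id}_visits.json"
        write_patient(rec, directory / fcsv, directory / vjson)
        manifest["patients"].append({"patient_id": rec.patient_id, "features": fcsv, "visits": vjson})
    with open(directory / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return directory / "cohort.json"


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read every patient listed in a cohort directory's manifest."""
    directory = Path(directory)
    with open(directory / "cohort.json") as fh:
        manifest = json.load(fh)
    return [
        read_patient(directory / p["features"], directory / p["visits"])
        for p in manifest["patients"]
    ]


def write_report(report, path: str | Path) -> None:
    """Write an EvalReport: ``<path>.json`` metrics + ``<path>_curves.csv``.

    Round-trips losslessly through :func:`read_report`.
    """
    path = Path(path)
    payload = report.to_dict()
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    curves = report.curves_frame()
    curves.to_csv(path.parent / (path.stem + "_curves.csv"), index=False)


def read_report(path: str | Path):
    """Read an EvalReport written by :func:`write_report`."""
    from .evaluation import EvalReport

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        payload = json.load(fh)
    curves_path = path.parent / (path.stem + "_curves.csv")
    curves = pd.read_csv(curves_path) if curves_path.exists() else None
    return EvalReport.from_dict(payload, curves)


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration (grids, windows, seeds) as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg
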