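"""Per-gland and per-dog measurement records and their tabular CSV form.

A cohort is exchanged as a long-format CSV, one row per gland, with the
columns::

    id, breed, sex, neutered, age_years, weight_kg, side, volume_cm3,
    mean_hu, length_mm, cranial_h_mm, cranial_w_mm, caudal_h_mm,
    caudal_w_mm, isthmus_h_mm, isthmus_w_mm, aorta_dv_mm, homogeneous

Isthmus fields apply to the left gland only (the right gland has no
measured isthmus) and are empty on right-side rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GlandMeasurement",
    "DogRecord",
    "COHORT_COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = [
    "id", "breed", "sex", "neutered", "age_years", "weight_kg", "side",
    "volume_cm3", "mean_hu", "length_mm", "cranial_h_mm", "cranial_w_mm",
    "caudal_h_mm", "caudal_w_mm", "isthmus_h_mm", "isthmus_w_mm",
    "aorta_dv_mm", "homogeneous",
]


@dataclass
class GlandMeasurement:
    """All measured quantities of one adrenal gland."""

    side: str
    volume_cm3: float
    mean_hu: float
    length_mm: float
    cranial_height_mm: float
    cranial_width_mm: float
    caudal_height_mm: float
    caudal_width_mm: float
    isthmus_height_mm: float | None = None
    isthmus_width_mm: float | None = None
    homogeneous: bool = True

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in ("volume_cm3", "length_mm", "cranial_height_mm",
                     "cranial_width_mm", "caudal_height_mm", "caudal_width_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cranial_height_mm", "cranial_width_mm",
                     "caudal_height_mm", "caudal_width_mm"):
            if getattr(self, name) > self.length_mm + 1e-9:
                raise ValueError(f"{name} exceeds gland length")
        has_isthmus = self.isthmus_height_mm is not None or self.isthmus_width_mm is not None
        if self.side == "right" and has_isthmus:
            raise ValueError("isthmus measurements are defined for the left gland only")
        if self.side == "left" and (
            self.isthmus_height_mm is None or self.isthmus_width_mm is None
        ):
            raise ValueError("left gland requires isthmus height and width")


@dataclass
class DogRecord:
    """One animal: covariates plus left/right gland measurements."""

    id: str
    breed: str
    sex: str
    neutered: bool
    age_years: float
    body_weight_kg: float
    aortic_diameter_mm: float
    left: GlandMeasurement | None = None
    right: GlandMeasurement | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")
        if not self.body_weight_kg > 0:
            raise ValueError("body_weight_kg must be positive")
        if not self.aortic_diameter_mm > 0:
            raise ValueError("aortic_diameter_mm must be positive")

    @property
    def complete(self) -> bool:
        """Both glands measured (the study's assessability requirement)."""
        return self.left is not None and self.right is not None

    def gland(self, side: str) -> GlandMeasurement | None:
        return self.left if side == "left" else self.right


def _gland_row(rec: DogRecord, g: GlandMeasurement) -> dict:
    return {
        "id": rec.id, "breed": rec.breed, "sex": rec.sex,
        "neutered": rec.neutered, "age_years": rec.age_years,
        "weight_kg": rec.body_weight_kg, "side": g.side,
        "volume_cm3": g.volume_cm3, "mean_hu": g.mean_hu,
        "length_mm": g.length_mm,
        "cranial_h_mm": g.cranial_height_mm, "cranial_w_mm": g.cranial_width_mm,
        "caudal_h_mm": g.caudal_height_mm, "caudal_w_mm": g.caudal_width_mm,
        "isthmus_h_mm": g.isthmus_height_mm, "isthmus_w_mm": g.isthmus_width_mm,
        "aorta_dv_mm": rec.aortic_diameter_mm, "homogeneous": g.homogeneous,
    }


def records_to_frame(records: Iterable[DogRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for g in (rec.left, rec.right):
            if g is not None:
                rows.append(_gland_row(rec, g))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[DogRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    records = []
    for dog_id, sub in frame.groupby("id", sort=False):
        first = sub.iloc[0]
        rec = DogRecord(
            id=str(dog_id), breed=str(first["breed"]), sex=str(first["sex"]),
            neutered=bool(first["neutered"]),
            age_years=float(first["age_years"]),
            body_weight_kg=float(first["weight_kg"]),
            aortic_diameter_mm=float(first["aorta_dv_mm"]),
        )
        for _, row in sub.iterrows():
            side = str(row["side"])
            isth_h = row["isthmus_h_mm"]
            isth_w = row["isthmus_w_mm"]
            g = GlandMeasurement(
                side=side,
                volume_cm3=float(row["volume_cm3"]),
                mean_hu=float(row["mean_hu"]),
                length_mm=float(row["length_mm"]),
                cranial_height_mm=float(row["cranial_h_mm"]),
                cranial_width_mm=float(row["cranial_w_mm"]),
                caudal_height_mm=float(row["caudal_h_mm"]),
                caudal_width_mm=float(row["caudal_w_mm"]),
                isthmus_height_mm=None if pd.isna(isth_h) else float(isth_h),
                isthmus_width_mm=None if pd.isna(isth_w) else float(isth_w),
                homogeneous=bool(row["homogeneous"]),
            )
            setattr(rec, side, g)
        records.append(rec)
    return records


def write_cohort_csv(records: Iterable[DogRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[DogRecord]:
    return frame_to_records(pd.read_csv(path))
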