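"""Cohort-level report tables: breed comparison, reference intervals,
variation coefficients and side differences.

The four tables mirror how multi-breed morphometry cohorts are reported:
per-breed means with multiple-range letters and paired side tests for the
volumes; percentile reference intervals per weight class; breed means with
coefficients of variation and weight correlations for the linear metrics;
and per-breed attenuation summaries with signed-rank side tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import REFERENCE_METRICS, build_reference_table, compute_cv
from .records import DogRecord
from .stats import (
    DEFAULT_ALPHA,
    compare_breeds,
    correlate_with_weight,
    side_difference,
)

__all__ = [
    "breed_volume_table",
    "linear_metrics_table",
    "attenuation_table",
    "cohort_report",
    "write_cohort_report",
]

_LINEAR_METRICS = [
    ("length_mm", "left"), ("length_mm", "right"),
    ("cranial_h_mm", "left"), ("cranial_h_mm", "right"),
    ("cranial_w_mm", "left"), ("cranial_w_mm", "right"),
    ("caudal_h_mm", "left"), ("caudal_h_mm", "right"),
    ("caudal_w_mm", "left"), ("caudal_w_mm", "right"),
    ("isthmus_h_mm", "left"), ("isthmus_w_mm", "left"),
]


def _breed_order(records: list[DogRecord]) -> list[str]:
    seen: list[str] = []
    for r in records:
        if r.breed not in seen:
            seen.append(r.breed)
    return seen


def _per_breed(records, metric, side):
    out = {}
    for r in records:
        g = r.gland(side)
        if g is None:
            continue
        from .indices import _metric_value

        v = _metric_value(r, g, metric)
        if v is not None:
            out.setdefault(r.breed, []).append(v)
    return {b: np.asarray(v) for b, v in out.items()}


def breed_volume_table(
    records: list[DogRecord], alpha: float = DEFAULT_ALPHA
) -> tuple[pd.DataFrame, dict]:
    """Per-breed left/right volume means with multiple-range letters and a
    per-breed paired side test."""
    rows = []
    reports = {}
    letters = {}
    for side in ("left", "right"):
        rep, grouping = compare_breeds(records, "volume_cm3", side=side, alpha=alpha)
        reports[side] = rep
        letters[side] = grouping.letters
    for breed in _breed_order(records):
        sub = [r for r in records if r.breed == breed and r.complete]
        lv = np.array([r.left.volume_cm3 for r in sub])
        rv = np.array([r.right.volume_cm3 for r in sub])
        side_p = side_difference(sub, "volume_cm3").p_value if len(sub) >= 3 else np.nan
        rows.append({
            "breed": breed, "n": len(sub),
            "mean_left_cm3": lv.mean(), "sd_left_cm3": lv.std(ddof=1),
            "letters_left": "".join(sorted(letters["left"][breed])),
            "mean_right_cm3": rv.mean(), "sd_right_cm3": rv.std(ddof=1),
            "letters_right": "".join(sorted(letters["right"][breed])),
            "paired_p": side_p,
        })
    meta = {
        side: {"test": reports[side].test, "statistic": reports[side].statistic,
               "p_value": reports[side].p_value}
        for side in ("left", "right")
    }
    return pd.DataFrame(rows), meta


def linear_metrics_table(records: list[DogRecord]) -> pd.DataFrame:
    """Breed means ± SD per linear metric with the breed-level coefficient of
    variation and the Pearson correlation with body weight."""
    breeds = _breed_order(records)
    rows = []
    for metric, side in _LINEAR_METRICS:
        grouped = _per_breed(records, metric, side)
        row: dict = {"metric": metric, "side": side}
        means = []
        for b in breeds:
            v = grouped.get(b)
            row[f"mean_{b}"] = v.mean() if v is not None else np.nan
            row[f"sd_{b}"] = v.std(ddof=1) if v is not None and v.size > 1 else np.nan
            if v is not None:
                means.append(v.mean())
        row["cv"] = compute_cv(means) if len(means) >= 2 else np.nan
        try:
            r, p, band = correlate_with_weight(records, metric, side)
        except ValueError:
            r, p, band = np.nan, np.nan, ""
        row.update({"pearson_r": r, "pearson_p": p, "band": band})
        rows.append(row)
    return pd.DataFrame(rows)


def attenuation_table(records: list[DogRecord]) -> pd.DataFrame:
    """Per-breed attenuation: mean ± SD plus median and quartiles per side,
    and the per-breed signed-rank side test."""
    rows = []
    for breed in _breed_order(records):
        sub = [r for r in records if r.breed == breed and r.complete]
        row: dict = {"breed": breed, "n": len(sub)}
        for side in ("left", "right"):
            v = np.array([getattr(r, side).mean_hu for r in sub])
            row[f"mean_{side}_hu"] = v.mean()
            row[f"sd_{side}_hu"] = v.std(ddof=1)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            row[f"median_{side}_hu"] = med
            row[f"q1_{side}_hu"] = q1
            row[f"q3_{side}_hu"] = q3
        row["side_test_p"] = (
            side_difference(sub, "mean_hu").p_value if len(sub) >= 3 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(
    records: list[DogRecord], alpha: float = DEFAULT_ALPHA
) -> dict:
    """All cohort tables in one pass.

    Returns a dict with keys ``breed_volumes`` (+ ``breed_volume_tests``),
    ``reference`` (a :class:`~adrenoct.indices.ReferenceTable`),
    ``linear_metrics`` and ``attenuation``.  With fewer than two breeds the
    breed comparison is omitted.
    """
    out: dict = {}
    breeds = _breed_order(records)
    if len(breeds) >= 2:
        tab, meta = breed_volume_table(records, alpha=alpha)
        out["breed_volumes"] = tab
        out["breed_volume_tests"] = meta
    else:
        import warnings

        warnings.warn("fewer than two breeds: breed comparison omitted", stacklevel=2)
    out["reference"] = build_reference_table(records, metrics=REFERENCE_METRICS)
    out["linear_metrics"] = linear_metrics_table(records)
    out["attenuation"] = attenuation_table(records)
    return out


def write_cohort_report(report: dict, outdir: str | Path) -> list[Path]:
    """Serialise a cohort report to CSV/JSON files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "breed_volumes" in report:
        p = outdir / "breed_volumes.csv"
        report["breed_volumes"].to_csv(p, index=False)
        written.append(p)
        p = outdir / "breed_volume_tests.json"
        p.write_text(json.dumps(report["breed_volume_tests"], indent=2))
        written.append(p)
    p = outdir / "reference_table.csv"
    report["reference"].to_csv(p)
    written.append(p)
    for key in ("linear_metrics", "attenuation"):
        p = outdir / f"{key}.csv"
        report[key].to_csv(p, index=False)
        written.append(p)
    return written
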