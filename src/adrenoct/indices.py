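"""Size indices, variation coefficients and percentile reference intervals.

The central index is the ratio volume-aorta (RVA),

    RVA = (adrenal volume in mm^3)^(1/3) / (dorsoventral aortic diameter in mm),

a dimensionless, body-size-normalised measure of gland size: both the cube
root of an organ volume and a great-vessel diameter scale linearly with
body size, so the ratio is invariant under uniform scaling and comparable
across breeds.  Reference intervals (10th/90th percentiles with quartiles)
are tabulated per weight class (under/over 20 kg), side and metric, and a
gland can be screened against them as well as against the conventional
weight-independent 7.4 mm upper threshold for the left caudal-pole height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DogRecord, GlandMeasurement

__all__ = [
    "WEIGHT_CLASS_BOUNDARY_KG",
    "UNIVERSAL_LEFT_CAUDAL_HEIGHT_MM",
    "CORRELATION_BANDS",
    "compute_rva",
    "compute_cv",
    "classify_correlation",
    "classify_weight",
    "ReferenceTable",
    "build_reference_table",
    "assess_against_reference",
    "REFERENCE_METRICS",
]

#: Dogs lighter than this are "light"; exactly 20 kg is classed heavy.
WEIGHT_CLASS_BOUNDARY_KG = 20.0

#: Conventional breed- and weight-independent upper threshold for the
#: maximal (caudal-pole) height of the left adrenal gland.
UNIVERSAL_LEFT_CAUDAL_HEIGHT_MM = 7.4

#: |r| bands: [0, 0.2) very weak ... [0.8, 1] very strong.
CORRELATION_BANDS = [
    (0.0, 0.2, "very weak"),
    (0.2, 0.4, "weak"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "strong"),
    (0.8, 1.0 + 1e-12, "very strong"),
]

#: Metrics tabulated in the reference table, in cohort-CSV column terms.
REFERENCE_METRICS = ["volume_cm3", "rva", "caudal_h_mm"]


def compute_rva(volume_cm3: float, aortic_diameter_mm: float) -> float:
    """Ratio volume-aorta: cube root of the volume (mm^3) over the aortic
    dorsoventral diameter (mm)."""
    if not volume_cm3 > 0:
        raise ValueError("volume must be positive")
    if not aortic_diameter_mm > 0:
        raise ValueError("aortic diameter must be positive")
    return float(np.cbrt(1000.0 * volume_cm3) / aortic_diameter_mm)


def compute_cv(group_means: "list[float] | np.ndarray") -> float:
    """Coefficient of variation of group (breed) mean values.

    Sample standard deviation (n-1 denominator) of the means divided by
    their arithmetic mean.  Display rounding to 2 decimals is the caller's
    concern; the unrounded value is returned.
    """
    means = np.asarray(group_means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 group means")
    m = means.mean()
    if m == 0:
        raise ValueError("mean of group means is zero")
    return float(means.std(ddof=1) / m)


def classify_correlation(r: float) -> str:
    """Verbal strength band of a correlation coefficient (on |r|)."""
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    a = abs(r)
    for lo, hi, label in CORRELATION_BANDS:
        if lo <= a < hi:
            return label
    return "very strong"  # a == 1 exactly


def classify_weight(weight_kg: float, boundary_kg: float = WEIGHT_CLASS_BOUNDARY_KG) -> str:
    """'light' strictly below the boundary, else 'heavy' (20.0 kg -> heavy)."""
    if not weight_kg > 0:
        raise ValueError("weight must be positive")
    return "light" if weight_kg < boundary_kg else "heavy"


@dataclass(frozen=True)
class ReferenceTable:
    """Percentile reference intervals per (weight class, side, metric).

    ``table`` has one row per stratum with columns ``weight_class``,
    ``side``, ``metric``, ``n``, ``p10``, ``q1``, ``median``, ``q3``,
    ``p90``; quantiles are non-decreasing within every row.
    """

    table: pd.DataFrame
    quantile_method: str = "linear"

    def lookup(self, weight_class: str, side: str, metric: str) -> pd.Series:
        sel = self.table[
            (self.table.weight_class == weight_class)
            & (self.table.side == side)
            & (self.table.metric == metric)
        ]
        if sel.empty:
            raise KeyError(f"no reference stratum ({weight_class}, {side}, {metric})")
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_value(rec: DogRecord, g: GlandMeasurement, metric: str) -> float | None:
    if metric == "rva":
        return compute_rva(g.volume_cm3, rec.aortic_diameter_mm)
    mapping = {
        "volume_cm3": g.volume_cm3, "mean_hu": g.mean_hu, "length_mm": g.length_mm,
        "cranial_h_mm": g.cranial_height_mm, "cranial_w_mm": g.cranial_width_mm,
        "caudal_h_mm": g.caudal_height_mm, "caudal_w_mm": g.caudal_width_mm,
        "isthmus_h_mm": g.isthmus_height_mm, "isthmus_w_mm": g.isthmus_width_mm,
    }
    if metric not in mapping:
        raise KeyError(f"unknown metric {metric!r}")
    return mapping[metric]


def build_reference_table(
    records: "list[DogRecord]",
    metrics: "list[str] | None" = None,
    min_n: int = 5,
    quantile_method: str = "linear",
    boundary_kg: float = WEIGHT_CLASS_BOUNDARY_KG,
) -> ReferenceTable:
    """10th/90th percentile reference intervals with quartiles, stratified by
    weight class and side.

    Quantiles use linear interpolation between order statistics by default
    (``quantile_method`` is passed to :func:`numpy.quantile`).  Strata with
    fewer than *min_n* observations are omitted with a warning.
    """
    metrics = list(metrics) if metrics is not None else list(REFERENCE_METRICS)
    rows = []
    for wc in ("light", "heavy"):
        cohort = [r for r in records if classify_weight(r.body_weight_kg, boundary_kg) == wc]
        for side in ("left", "right"):
            for metric in metrics:
                vals = []
                for rec in cohort:
                    g = rec.gland(side)
                    if g is None:
                        continue
                    v = _metric_value(rec, g, metric)
                    if v is not None:
                        vals.append(v)
                if len(vals) < min_n:
                    warnings.warn(
                        f"stratum ({wc}, {side}, {metric}) has n={len(vals)} < "
                        f"{min_n}; omitted",
                        stacklevel=2,
                    )
                    continue
                v = np.asarray(vals, dtype=float)
                q = np.quantile(v, [0.10, 0.25, 0.50, 0.75, 0.90], method=quantile_method)
                rows.append({
                    "weight_class": wc, "side": side, "metric": metric,
                    "n": len(vals), "p10": q[0], "q1": q[1], "median": q[2],
                    "q3": q[3], "p90": q[4],
                })
    table = pd.DataFrame(rows, columns=[
        "weight_class", "side", "metric", "n", "p10", "q1", "median", "q3", "p90"
    ])
    return ReferenceTable(table=table, quantile_method=quantile_method)


def assess_against_reference(
    measurement: GlandMeasurement,
    weight_class: str,
    table: ReferenceTable,
    aortic_diameter_mm: float | None = None,
) -> dict:
    """Flag a gland's metrics against the weight-class reference intervals.

    Returns per-metric flags ``below_p10`` / ``within`` / ``above_p90`` for
    every metric tabulated for the gland's stratum, plus
    ``exceeds_universal_threshold`` comparing the left caudal-pole height to
    the conventional 7.4 mm cut-off (None for right glands).
    """
    flags: dict = {"metrics": {}, "exceeds_universal_threshold": None}
    strata = table.table[
        (table.table.weight_class == weight_class)
        & (table.table.side == measurement.side)
    ]
    if strata.empty:
        raise KeyError(f"reference table lacks stratum ({weight_class}, {measurement.side})")
    rec_stub = None
    for _, row in strata.iterrows():
        metric = row["metric"]
        if metric == "rva":
            if aortic_diameter_mm is None:
                continue
            value = compute_rva(measurement.volume_cm3, aortic_diameter_mm)
        else:
            value = _metric_value(rec_stub, measurement, metric)  # type: ignore[arg-type]
        if value is None:
            continue
        if value < row["p10"]:
            flag = "below_p10"
        elif value > row["p90"]:
            flag = "above_p90"
        else:
            flag = "within"
        flags["metrics"][metric] = {"value": float(value), "flag": flag}
    if measurement.side == "left":
        flags["exceeds_universal_threshold"] = bool(
            measurement.caudal_height_mm > UNIVERSAL_LEFT_CAUDAL_HEIGHT_MM
        )
    return flags
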