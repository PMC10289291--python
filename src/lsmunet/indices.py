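"""Regional skeletal-muscle indices, sarcopenia diagnosis and ROC analysis.

From a multi-region segmentation the mean cross-sectional area of each
muscle region over the L3 slab is divided by the squared body height,
giving SMI-style indices in cm²/m²:

* RAI — Rectus Abdominis index
* RPI / LPI — Right / Left Psoas indices
* PI — Paravertebral index
* TPI — total psoas index (right + left areas summed before dividing)
* L3SMI — total skeletal-muscle index over all four regions

Sarcopenia is diagnosed from L3SMI with the standard sex-specific
cut-offs (50 cm²/m² male, 39 cm²/m² female); an index exactly at the
cut-off counts as non-sarcopenic.  ROC analysis derives analogous
cut-offs for the regional indices by maximizing Youden's J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ioprep import (
    CLASS_LEFT_PSOAS,
    CLASS_PARAVERTEBRAL,
    CLASS_RECTUS_ABDOMINIS,
    CLASS_RIGHT_PSOAS,
    MUSCLE_CLASSES,
)

#: Sex-specific L3SMI diagnostic cut-offs, cm²/m².
L3SMI_CUTOFFS = {"male": 50.0, "female": 39.0}

INDEX_COLUMNS = ("rai", "rpi", "lpi", "pi", "tpi")


def mean_cross_sectional_area(labels, spacing_mm=None, n_true_slices=None) -> dict[int, float]:
    """Mean per-slice area of each muscle region over the true slices, cm².

    ``(voxel count over true slices / n_true_slices) * sy * sx / 100``;
    padded slices are excluded.
    """
    arr = np.asarray(getattr(labels, "labels", labels))
    if spacing_mm is None:
        spacing_mm = labels.spacing_mm
    if n_true_slices is None:
        n_true_slices = getattr(labels, "n_true_slices", arr.shape[0])
    if n_true_slices < 1:
        raise ValueError("need at least one true slice")
    _, sy, sx = spacing_mm
    true = arr[:n_true_slices]
    px_cm2 = (sy * sx) / 100.0
    return {
        int(c): float(np.count_nonzero(true == c) / n_true_slices * px_cm2)
        for c in MUSCLE_CLASSES
    }


def smi(area_cm2: float, height_m: float) -> float:
    """Skeletal-muscle index: area divided by squared height, cm²/m²."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    if area_cm2 < 0:
        raise ValueError("area must be non-negative")
    return area_cm2 / height_m**2


def diagnose_l3smi(l3smi: float, sex: str) -> str:
    """'sarcopenia' iff L3SMI is strictly below the sex-specific cut-off."""
    if sex not in L3SMI_CUTOFFS:
        raise ValueError(f"unknown sex {sex!r}")
    if l3smi < 0:
        raise ValueError("L3SMI must be non-negative")
    return "sarcopenia" if l3smi < L3SMI_CUTOFFS[sex] else "non-sarcopenia"


def find_diagnostic_boundary(sex: str, lo: float = 0.0, hi: float = 100.0,
                             tol: float = 1e-9) -> float:
    """Recover the diagnostic boundary by bisection on the diagnosis."""
    if diagnose_l3smi(lo, sex) != "sarcopenia" or diagnose_l3smi(hi, sex) == "sarcopenia":
        raise ValueError("bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if diagnose_l3smi(mid, sex) == "sarcopenia":
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_index_table(segmentations, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-patient areas, indices and diagnosis.

    ``segmentations`` maps patient_id -> LabelVolume; ``manifest`` supplies
    height and sex.  L3SMI uses the summed area of all four regions.
    """
    rows = []
    for _, m in manifest.iterrows():
        pid = m["patient_id"]
        labels = segmentations[pid]
        areas = mean_cross_sectional_area(labels)
        h = float(m["height_m"])
        a_ra = areas[CLASS_RECTUS_ABDOMINIS]
        a_rp = areas[CLASS_RIGHT_PSOAS]
        a_lp = areas[CLASS_LEFT_PSOAS]
        a_pv = areas[CLASS_PARAVERTEBRAL]
        total = a_ra + a_rp + a_lp + a_pv
        l3smi = smi(total, h)
        rows.append(
            {
                "patient_id": pid,
                "sex": m["sex"],
                "height_m": h,
                "area_cm2_ra": a_ra,
                "area_cm2_rp": a_rp,
                "area_cm2_lp": a_lp,
                "area_cm2_pv": a_pv,
                "area_cm2_total": total,
                "rai": smi(a_ra, h),
                "rpi": smi(a_rp, h),
                "lpi": smi(a_lp, h),
                "pi": smi(a_pv, h),
                "tpi": smi(a_rp + a_lp, h),
                "l3smi": l3smi,
                "diagnosis": diagnose_l3smi(l3smi, m["sex"]),
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Pearson correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    return float(stats.pearsonr(x, y).statistic)


def correlate(table: pd.DataFrame, index_columns=INDEX_COLUMNS) -> pd.DataFrame:
    """Pearson correlation of each regional index against L3SMI, per group.

    Groups mirror the standard reporting layout: sarcopenia status, sex,
    and the full cohort.  Cells with fewer than 3 patients or zero
    variance report NaN rather than aborting the table.
    """
    groups = {
        "sarcopenia": table["diagnosis"] == "sarcopenia",
        "non-sarcopenia": table["diagnosis"] == "non-sarcopenia",
        "female": table["sex"] == "female",
        "male": table["sex"] == "male",
        "all": pd.Series(True, index=table.index),
    }
    rows = []
    for name, mask in groups.items():
        sub = table[mask]
        row = {"group": name, "n": int(len(sub))}
        for col in index_columns:
            try:
                row[col] = pearson_r(sub[col], sub["l3smi"])
            except ValueError:
                row[col] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CutoffResult:
    index_name: str
    sex: str
    cutoff: float
    accuracy: float
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.auc <= 1.0):
            raise ValueError("accuracy and AUC must be in [0, 1]")


def derive_cutoff(index_values, sarcopenia_labels, index_name: str = "",
                  sex: str = "") -> CutoffResult:
    """ROC-derived diagnostic cut-off for a low-is-diseased index.

    Candidate thresholds are midpoints between sorted unique values; a
    patient is called sarcopenic when the index is strictly below the
    threshold.  The cut-off maximizes Youden's J (ties toward the lower
    cut-off); AUC is the trapezoidal area under the ROC curve.
    """
    v = np.asarray(index_values, dtype=float)
    y = np.asarray(sarcopenia_labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("need 1-D values and labels of equal length")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    pos = v[y]  # sarcopenic (low values expected)
    neg = v[~y]
    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.array([(pos < t).mean() for t in thresholds])
    spec = np.array([(neg >= t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) threshold on ties
    cutoff = float(thresholds[best])
    acc = float(((pos < cutoff).sum() + (neg >= cutoff).sum()) / v.size)
    # trapezoidal AUC over the ROC curve traced by all thresholds
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return CutoffResult(index_name=index_name, sex=sex, cutoff=cutoff,
                        accuracy=acc, auc=auc)


def cutoff_table(table: pd.DataFrame, index_columns=INDEX_COLUMNS) -> pd.DataFrame:
    """Sex-stratified cut-off/accuracy/AUC table for the regional indices."""
    rows = []
    for sex in ("female", "male"):
        sub = table[table["sex"] == sex]
        y = (sub["diagnosis"] == "sarcopenia").to_numpy()
        for col in index_columns:
            res = derive_cutoff(sub[col].to_numpy(), y, index_name=col, sex=sex)
            rows.append(
                {
                    "sex": sex,
                    "index": col,
                    "cutoff": res.cutoff,
                    "accuracy": res.accuracy,
                    "auc": res.auc,
                }
            )
    return pd.DataFrame(rows)
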