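"""Segmentation evaluation: DSC, Sensitivity and ASSD in millimetres.

All metrics are computed per muscle class over the genuine slices only
(padded slices are an artefact of the fixed network depth).  ASSD uses
border voxels under 6-connectivity as the surface definition and
anisotropic physical distances, since slice thickness (5 mm) greatly
exceeds in-plane spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, distance_transform_edt, generate_binary_structure

from .ioprep import CLASS_NAMES, MUSCLE_CLASSES, N_CLASSES


def confusion_counts(pred, gt, n_true_slices: int | None = None) -> dict[int, tuple[int, int, int, int]]:
    """Per-class (TP, FP, FN, TN) pixel counts.

    ``pred`` and ``gt`` may be label arrays or LabelVolume objects;
    evaluation is restricted to the first ``n_true_slices`` slices.
    """
    p = np.asarray(getattr(pred, "labels", pred))
    g = np.asarray(getattr(gt, "labels", gt))
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    if n_true_slices is None:
        n_true_slices = getattr(gt, "n_true_slices", g.shape[0])
    p = p[:n_true_slices]
    g = g[:n_true_slices]
    cm = np.bincount(
        (N_CLASSES * g.ravel() + p.ravel()).astype(np.int64), minlength=N_CLASSES**2
    ).reshape(N_CLASSES, N_CLASSES)
    total = cm.sum()
    out = {}
    for c in range(N_CLASSES):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        tn = int(total - tp - fn - fp)
        out[c] = (tp, fp, fn, tn)
    return out


def dsc(counts: tuple[int, int, int, int]) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN).

    A class empty in both masks (TP = FP = FN = 0) scores 1.0.
    """
    tp, fp, fn, _ = counts
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def sensitivity(counts: tuple[int, int, int, int]) -> float:
    """TP / (TP + FN); a class absent from the ground truth scores 1.0
    when the prediction is also empty, else 0.0."""
    tp, fp, fn, _ = counts
    if tp + fn == 0:
        return 1.0 if fp == 0 else 0.0
    return tp / (tp + fn)


_STRUCT = generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean surface: mask voxels with >= 1 face-adjacent non-mask
    neighbour (voxels at the array border count as surface)."""
    m = np.asarray(mask, dtype=bool)
    return m & ~binary_erosion(m, structure=_STRUCT, border_value=0)


def assd(pred, gt, class_id: int, spacing_mm, n_true_slices: int | None = None) -> float | None:
    """Average symmetric surface distance for one class, in millimetres.

    Both directed nearest-neighbour distance sums are divided by the total
    surface voxel count ``N_S + N_G``.  Voxel index offsets are scaled by
    the spacing before the Euclidean norm.  Returns ``None`` with a
    warning when the class is missing from exactly one mask (the
    segmentation failed for that class); returns 0.0 when missing from
    both.
    """
    p = np.asarray(getattr(pred, "labels", pred))
    g = np.asarray(getattr(gt, "labels", gt))
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    if n_true_slices is None:
        n_true_slices = getattr(gt, "n_true_slices", g.shape[0])
    pm = p[:n_true_slices] == class_id
    gm = g[:n_true_slices] == class_id
    if not pm.any() and not gm.any():
        return 0.0
    if not pm.any() or not gm.any():
        warnings.warn(
            f"class {class_id} absent from one mask; ASSD undefined", stacklevel=2
        )
        return None
    sp = surface_voxels(pm)
    sg = surface_voxels(gm)
    # exact Euclidean distance maps to each surface, with physical spacing
    d_to_g = distance_transform_edt(~sg, sampling=spacing_mm)
    d_to_s = distance_transform_edt(~sp, sampling=spacing_mm)
    total = d_to_g[sp].sum() + d_to_s[sg].sum()
    return float(total / (sp.sum() + sg.sum()))


@dataclass
class MetricsReport:
    """Per-class and 4-class-average metrics for one volume."""

    patient_id: str
    per_class: dict[int, dict[str, float | None]]
    counts: dict[int, tuple[int, int, int, int]]

    @property
    def average(self) -> dict[str, float]:
        out = {}
        for key in ("dsc", "sensitivity", "assd_mm"):
            vals = [
                self.per_class[c][key]
                for c in MUSCLE_CLASSES
                if self.per_class[c][key] is not None
            ]
            out[key] = float(np.mean(vals)) if vals else float("nan")
        return out


def evaluate_volume(pred, gt, slab=None, spacing_mm=None) -> MetricsReport:
    """Full per-class metrics for one predicted/ground-truth mask pair.

    Spacing and true slice count come from ``slab`` when given, else from
    the ground-truth label volume.
    """
    src = slab if slab is not None else gt
    spacing = spacing_mm if spacing_mm is not None else src.spacing_mm
    n_true = getattr(src, "n_true_slices", None)
    counts = confusion_counts(pred, gt, n_true)
    per_class = {}
    for c in MUSCLE_CLASSES:
        per_class[c] = {
            "dsc": dsc(counts[c]),
            "sensitivity": sensitivity(counts[c]),
            "assd_mm": assd(pred, gt, c, spacing, n_true),
        }
    pid = getattr(gt, "patient_id", "")
    return MetricsReport(patient_id=pid, per_class=per_class, counts=counts)


def aggregate(reports: list[MetricsReport]) -> pd.DataFrame:
    """Cohort mean ± sd per class and for the 4-class average.

    Returns a tidy frame with one row per region (plus ``average``) and
    ``<metric>_mean`` / ``<metric>_sd`` columns.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    rows = []
    keys = ("dsc", "sensitivity", "assd_mm")
    for c in MUSCLE_CLASSES:
        row = {"region": CLASS_NAMES[c]}
        for key in keys:
            vals = [r.per_class[c][key] for r in reports if r.per_class[c][key] is not None]
            row[f"{key}_mean"] = float(np.mean(vals)) if vals else float("nan")
            row[f"{key}_sd"] = float(np.std(vals)) if vals else float("nan")
        rows.append(row)
    row = {"region": "average"}
    for key in keys:
        vals = [r.average[key] for r in reports]
        row[f"{key}_mean"] = float(np.mean(vals))
        row[f"{key}_sd"] = float(np.std(vals))
    rows.append(row)
    return pd.DataFrame(rows)
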