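"""Volume containers, NIfTI I/O and preprocessing for L3-level CT slabs.

A *slab* is the stack of axial CT slices associated with the L3 vertebra
(between 4 and 8 slices in the acquisition protocol emulated here).  Before
entering the segmentation network every slab is intensity-normalized to
[0, 1] over its full dynamic range and zero-padded along the axial direction
to a fixed depth of 8 slices.  The number of genuine (pre-padding) slices is
carried through as ``n_true_slices`` so that evaluation metrics and the
muscle indices can exclude padded slices.

Array convention: rank-3 arrays indexed ``(depth, row, col)`` with spacing
``(sz, sy, sx)`` in millimetres.  On disk, NIfTI files store ``(x, y, z)``;
the reader/writer transposes accordingly and trusts the affine for spacing
only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Fixed axial depth of the network input.
TARGET_DEPTH = 8

#: Segmentation class ids.
CLASS_BACKGROUND = 0
CLASS_RECTUS_ABDOMINIS = 1
CLASS_RIGHT_PSOAS = 2
CLASS_LEFT_PSOAS = 3
CLASS_PARAVERTEBRAL = 4

N_CLASSES = 5

#: Muscle class ids (excludes background), in reporting order.
MUSCLE_CLASSES = (
    CLASS_RECTUS_ABDOMINIS,
    CLASS_RIGHT_PSOAS,
    CLASS_LEFT_PSOAS,
    CLASS_PARAVERTEBRAL,
)

CLASS_NAMES = {
    CLASS_BACKGROUND: "background",
    CLASS_RECTUS_ABDOMINIS: "rectus_abdominis",
    CLASS_RIGHT_PSOAS: "right_psoas",
    CLASS_LEFT_PSOAS: "left_psoas",
    CLASS_PARAVERTEBRAL: "paravertebral",
}


@dataclass
class CTSlab:
    """One patient's L3-related image volume.

    Parameters
    ----------
    voxels
        Rank-3 float array ``(depth, height, width)`` of intensities, either
        raw HU-like values or, after :func:`normalize_intensity`, values in
        [0, 1].
    spacing_mm
        Voxel spacing ``(sz, sy, sx)`` in millimetres; in-plane spacing is
        isotropic (``sy == sx``).
    n_true_slices
        Number of genuine axial slices; slices beyond this index are padding.
    patient_id
        Free-form identifier.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_true_slices: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("expected 3-D volume")
        if not (1 <= self.n_true_slices <= self.voxels.shape[0]):
            raise ValueError(
                f"n_true_slices={self.n_true_slices} outside [1, depth={self.voxels.shape[0]}]"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"non-positive spacing {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def in_plane_spacing(self) -> float:
        return float(self.spacing_mm[1])


@dataclass
class LabelVolume:
    """Integer mask aligned to a :class:`CTSlab`.

    Class ids: 0 background, 1 Rectus Abdominis, 2 Right Psoas,
    3 Left Psoas, 4 Paravertebral.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    n_true_slices: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("expected 3-D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if self.labels.min() < 0 or self.labels.max() >= N_CLASSES:
            raise ValueError("label values outside {0,...,4}")
        if not (1 <= self.n_true_slices <= self.labels.shape[0]):
            raise ValueError("n_true_slices outside [1, depth]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def normalize_intensity(slab: CTSlab) -> CTSlab:
    """Map the full intensity range of the volume to [0, 1].

    The minimum voxel maps to 0 and the maximum to 1; ordering is preserved.
    A constant volume (zero dynamic range) is mapped to all zeros with a
    warning, since it carries no contrast.
    """
    v = np.asarray(slab.voxels, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty volume")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        warnings.warn(
            f"volume {slab.patient_id!r} has constant intensity; normalized to zeros",
            stacklevel=2,
        )
        out = np.zeros_like(v)
    else:
        out = (v - vmin) / (vmax - vmin)
    return replace(slab, voxels=out)


def pad_depth(
    slab: CTSlab,
    labels: LabelVolume | None = None,
    target_depth: int = TARGET_DEPTH,
) -> tuple[CTSlab, LabelVolume | None]:
    """Zero-pad the axial direction to ``target_depth`` slices.

    Appended slices have zero intensity and background label.  Padding is
    appended at the end of the stack so slice 0 stays anchored to the top of
    the slab.  ``n_true_slices`` is preserved.
    """
    d = slab.voxels.shape[0]
    if d > target_depth:
        raise ValueError(
            f"slab depth {d} exceeds target depth {target_depth}; "
            "restrict the volume to the L3-related slices first"
        )
    if labels is not None and labels.labels.shape != slab.voxels.shape:
        raise ValueError("label volume shape does not match slab")
    pad = target_depth - d
    if pad == 0:
        return slab, labels
    widths = ((0, pad), (0, 0), (0, 0))
    out_slab = replace(slab, voxels=np.pad(slab.voxels, widths))
    out_labels = None
    if labels is not None:
        out_labels = replace(labels, labels=np.pad(labels.labels, widths))
    return out_slab, out_labels


def crop_true_slices(obj: CTSlab | LabelVolume) -> np.ndarray:
    """Return the array restricted to the genuine (non-padded) slices."""
    arr = obj.voxels if isinstance(obj, CTSlab) else obj.labels
    return arr[: obj.n_true_slices]


# --- NIfTI round trip -------------------------------------------------------

_DESCRIP_RE = re.compile(rb"n_true_slices=(\d+)")


def _to_disk(arr: np.ndarray) -> np.ndarray:
    # (depth, row, col) -> on-disk (x=col, y=row, z=depth)
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))


def _from_disk(arr: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))


def write_volume(obj: CTSlab | LabelVolume, path: str | Path) -> Path:
    """Write a slab or label volume as NIfTI with spacing in the header."""
    path = Path(path)
    if isinstance(obj, CTSlab):
        data = _to_disk(np.asarray(obj.voxels, dtype=np.float32))
    elif isinstance(obj, LabelVolume):
        data = _to_disk(np.asarray(obj.labels, dtype=np.int16))
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    sz, sy, sx = obj.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = f"n_true_slices={obj.n_true_slices}".encode()
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> CTSlab | LabelVolume:
    """Read a NIfTI volume; integer dtypes load as label volumes.

    Spacing is taken from the header zooms; ``n_true_slices`` from the
    ``descrip`` field when present (defaults to the full depth).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"invalid voxel spacing {zooms} in {path}")
    sx, sy, sz = (float(z) for z in zooms)
    data = _from_disk(np.asanyarray(img.dataobj))
    m = _DESCRIP_RE.search(bytes(img.header["descrip"].tobytes()))
    n_true = int(m.group(1)) if m else data.shape[0]
    pid = path.name.split(".")[0]
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(
            labels=data.astype(np.int64),
            spacing_mm=(sz, sy, sx),
            n_true_slices=n_true,
            patient_id=pid,
        )
    return CTSlab(
        voxels=data.astype(np.float64),
        spacing_mm=(sz, sy, sx),
        n_true_slices=n_true,
        patient_id=pid,
    )


def preprocess(slab: CTSlab, labels: LabelVolume | None = None):
    """Normalize then pad to the network depth (the standard pipeline order).

    Padded voxels therefore hold 0, the post-normalization minimum.
    """
    return pad_depth(normalize_intensity(slab), labels)
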