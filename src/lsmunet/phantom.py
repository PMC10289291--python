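"""Synthetic L3-level abdominal CT phantoms with four-region muscle labels.

Each phantom emulates the stack of axial slices associated with the L3
vertebra: an elliptical torso with a subcutaneous fat rim, a bright
vertebral body at the posterior centre, and the four skeletal-muscle
regions used for cirrhotic-sarcopenia analysis:

* class 1 — Rectus Abdominis group: an anterior annular band (rectus plus
  oblique/transversus wall muscles).  Ascites compression is modelled by
  ``squeeze_factor``, which thins this band.
* classes 2/3 — Right/Left Psoas: elliptical bodies flanking the vertebra
  (patient right = image left).
* class 4 — Paravertebral: the posterior erector-spinae mass behind the
  vertebra.

Geometry is a deterministic function of the parameters: region centres
drift linearly through the slice stack (so sagittal/coronal context carries
genuine 3-D structure) and the psoas/paravertebral bodies taper slightly.
The random seed drives image intensities only (tissue texture plus
acquisition noise), never the label geometry — two phantoms with identical
geometric parameters share their label volumes exactly.

Intensities live on an HU-like scale (air ≈ -1000, fat ≈ -100, soft organ
tissue ≈ +20, muscle ≈ +48, cortical/trabecular vertebra ≈ +350) with a
slight in-plane blur to soften tissue edges (partial-volume effect) before
additive acquisition noise.  The model is a test scaffold for the
segmentation and index pipeline, not a claim about any clinical scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .ioprep import (
    CLASS_LEFT_PSOAS,
    CLASS_PARAVERTEBRAL,
    CLASS_RECTUS_ABDOMINIS,
    CLASS_RIGHT_PSOAS,
    CTSlab,
    LabelVolume,
    MUSCLE_CLASSES,
)

TISSUES = ("air", "fat", "organ", "muscle", "bone")

DEFAULT_HU_MEANS = {"air": -1000.0, "fat": -100.0, "organ": 20.0, "muscle": 48.0, "bone": 350.0}
DEFAULT_HU_SDS = {"air": 5.0, "fat": 8.0, "organ": 8.0, "muscle": 6.0, "bone": 30.0}

#: Per-region (dy, dx) centre drift in voxels per slice, as fractions of the
#: image width; order RA, RP, LP, PV.  Fixed so label geometry is a pure
#: function of the parameters.
DEFAULT_DRIFT = ((0.0020, 0.0015), (0.0018, -0.0022), (-0.0018, 0.0022), (-0.0022, -0.0012))


@dataclass
class PhantomParams:
    """Generation parameters for one phantom; see the module docstring."""

    grid_size: tuple[int, int, int] = (8, 512, 512)
    spacing_mm: tuple[float, float, float] = (5.0, 0.7, 0.7)
    n_true_slices: int = 6
    torso_radii: tuple[float, float] | None = None  # (ay, ax) voxels; None -> 0.40H, 0.45W
    region_scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    squeeze_factor: float = 0.0
    hu_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU_SDS))
    noise_sd: float = 10.0
    blur_sigma: float = 0.6
    drift: tuple[tuple[float, float], ...] = DEFAULT_DRIFT
    taper_per_slice: float = 0.015
    height_m: float = 1.70
    sex: str = "male"
    seed: int = 0

    def __post_init__(self) -> None:
        d, h, w = self.grid_size
        if not (4 <= self.n_true_slices <= 8):
            raise ValueError("n_true_slices must be in [4, 8]")
        if self.n_true_slices > d:
            raise ValueError("n_true_slices exceeds grid depth")
        if not (0.0 <= self.squeeze_factor <= 1.0):
            raise ValueError("squeeze_factor must be in [0, 1]")
        if any(s <= 0 for s in self.region_scale):
            raise ValueError("region_scale entries must be positive")
        if self.torso_radii is not None and any(r <= 0 for r in self.torso_radii):
            raise ValueError("torso radii must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.height_m <= 0:
            raise ValueError("height must be positive")

    def resolved_torso_radii(self) -> tuple[float, float]:
        if self.torso_radii is not None:
            return self.torso_radii
        _, h, w = self.grid_size
        return (0.40 * h, 0.45 * w)


@dataclass
class PatientMeta:
    """Ground-truth bookkeeping for a generated phantom."""

    patient_id: str
    height_m: float
    sex: str
    cirrhotic: bool
    n_true_slices: int
    true_region_areas_cm2: dict[int, float]

    @property
    def total_area_cm2(self) -> float:
        return float(sum(self.true_region_areas_cm2.values()))


def _ellipse(yy, xx, cy, cx, ay, ax):
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def region_areas_cm2(labels: LabelVolume) -> dict[int, float]:
    """Mean cross-sectional area per muscle class over the true slices, cm²."""
    sz, sy, sx = labels.spacing_mm
    true = labels.labels[: labels.n_true_slices]
    px_cm2 = (sy * sx) / 100.0
    return {
        int(c): float(np.count_nonzero(true == c) / labels.n_true_slices * px_cm2)
        for c in MUSCLE_CLASSES
    }


def _slice_geometry(params: PhantomParams, k: int):
    """Label + tissue masks for axial slice ``k`` (0-based)."""
    d, h, w = params.grid_size
    ay, ax = params.resolved_torso_radii()
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    mid = (params.n_true_slices - 1) / 2.0
    dk = k - mid
    taper = max(0.2, 1.0 - params.taper_per_slice * dk)
    sc = params.region_scale
    drifts = [(dy * w * dk, dx * w * dk) for dy, dx in params.drift]

    body = _ellipse(yy, xx, cy, cx, ay, ax)
    inner = _ellipse(yy, xx, cy, cx, 0.88 * ay, 0.88 * ax)

    # vertebral body (bone, stays background class)
    vy, vx = cy + 0.35 * ay, cx
    vert = _ellipse(yy, xx, vy, vx, 0.14 * ay, 0.12 * ax)
    vert_margin = _ellipse(yy, xx, vy, vx, 0.19 * ay, 0.17 * ax)

    # class 1: anterior muscle-wall ring, thinned by squeeze_factor
    thick = 0.10 * (1.0 - params.squeeze_factor) * sc[0]
    outer_f, inner_f = 0.86, max(0.86 - thick, 0.05)
    dy0, dx0 = drifts[0]
    ring = _ellipse(yy, xx, cy + dy0, cx + dx0, outer_f * ay, outer_f * ax) & ~_ellipse(
        yy, xx, cy + dy0, cx + dx0, inner_f * ay, inner_f * ax
    )
    phi = np.arctan2(np.abs(xx - cx), -(yy - cy))  # angle from anterior direction
    ra = ring & (phi <= 2.0) & body

    # classes 2/3: psoas ellipses flanking the vertebra
    psy, psx = 0.16 * ay * taper, 0.13 * ax * taper
    dy2, dx2 = drifts[1]
    rp = _ellipse(yy, xx, cy + 0.30 * ay + dy2, cx - 0.40 * ax + dx2, psy * sc[1], psx * sc[1])
    dy3, dx3 = drifts[2]
    lp = _ellipse(yy, xx, cy + 0.30 * ay + dy3, cx + 0.40 * ax + dx3, psy * sc[2], psx * sc[2])
    rp &= inner & ~vert_margin
    lp &= inner & ~vert_margin

    # class 4: posterior paravertebral mass
    dy4, dx4 = drifts[3]
    pv = _ellipse(
        yy, xx, cy + 0.55 * ay + dy4, cx + dx4, 0.30 * ay * taper * sc[3], 0.42 * ax * taper * sc[3]
    )
    pv &= inner & ~vert_margin & ~rp & ~lp & ~ra

    labels = np.zeros((h, w), dtype=np.int64)
    labels[ra] = CLASS_RECTUS_ABDOMINIS
    labels[rp] = CLASS_RIGHT_PSOAS
    labels[lp] = CLASS_LEFT_PSOAS
    labels[pv] = CLASS_PARAVERTEBRAL

    tissue = np.zeros((h, w), dtype=np.int8)  # air
    tissue[body] = TISSUES.index("fat")  # subcutaneous rim (body minus interior)
    tissue[inner] = TISSUES.index("organ")
    tissue[labels > 0] = TISSUES.index("muscle")
    tissue[vert] = TISSUES.index("bone")
    return labels, tissue


def generate_phantom(
    params: PhantomParams,
    patient_id: str = "p000",
    cirrhotic: bool = False,
) -> tuple[CTSlab, LabelVolume, PatientMeta]:
    """Generate one phantom slab with ground-truth labels and metadata.

    Raises ``ValueError`` when the grid is too small to hold all five
    structures (some class missing from a true slice).
    """
    d, h, w = params.grid_size
    ay, ax = params.resolved_torso_radii()
    sc = params.region_scale
    # minimum footprint: every structure needs at least ~1 voxel of extent
    footprint = {
        "right psoas": min(0.16 * ay * sc[1], 0.13 * ax * sc[1]),
        "left psoas": min(0.16 * ay * sc[2], 0.13 * ax * sc[2]),
        "vertebra": min(0.14 * ay, 0.12 * ax),
        "rectus ring": 0.10 * sc[0] * ay * 1.25,
        "paravertebral": min(0.30 * ay * sc[3], 0.42 * ax * sc[3]) / 2.0,
    }
    too_small = [name for name, extent in footprint.items() if extent < 1.0]
    if too_small:
        raise ValueError(
            f"unbuildable geometry: grid {params.grid_size} too small for "
            f"structure(s) {too_small}"
        )
    rng = np.random.default_rng(params.seed)
    image = np.zeros((d, h, w), dtype=np.float64)
    labels = np.zeros((d, h, w), dtype=np.int64)
    hu = np.array([params.hu_means[t] for t in TISSUES])
    sds = np.array([params.hu_sds[t] for t in TISSUES])

    for k in range(params.n_true_slices):
        lab_k, tis_k = _slice_geometry(params, k)
        present = set(np.unique(lab_k))
        missing = [c for c in MUSCLE_CLASSES if c not in present]
        if missing:
            raise ValueError(
                f"unbuildable geometry: class(es) {missing} empty in slice {k}; "
                "grid too small or region scales too extreme"
            )
        clean = hu[tis_k] + rng.normal(0.0, sds[tis_k])
        if params.blur_sigma > 0:
            clean = gaussian_filter(clean, params.blur_sigma)
        image[k] = clean + rng.normal(0.0, params.noise_sd, size=(h, w))
        labels[k] = lab_k

    slab = CTSlab(
        voxels=image,
        spacing_mm=params.spacing_mm,
        n_true_slices=params.n_true_slices,
        patient_id=patient_id,
    )
    label_vol = LabelVolume(
        labels=labels,
        spacing_mm=params.spacing_mm,
        n_true_slices=params.n_true_slices,
        patient_id=patient_id,
    )
    meta = PatientMeta(
        patient_id=patient_id,
        height_m=params.height_m,
        sex=params.sex,
        cirrhotic=cirrhotic,
        n_true_slices=params.n_true_slices,
        true_region_areas_cm2=region_areas_cm2(label_vol),
    )
    return slab, label_vol, meta


@dataclass
class CohortVariation:
    """Per-parameter jitter for cohort generation.

    Multiplicative jitters are half-widths: a value ``j`` draws a factor
    uniformly from ``[1-j, 1+j]``.  Cirrhotic patients draw their
    Rectus-Abdominis squeeze from ``squeeze_range_cirrhotic`` (ascites
    compression), non-cirrhotic patients from ``squeeze_range_control``.
    """

    region_scale_jitter: float = 0.12
    torso_jitter: float = 0.06
    squeeze_range_cirrhotic: tuple[float, float] = (0.15, 0.55)
    squeeze_range_control: tuple[float, float] = (0.0, 0.10)
    height_range_m: tuple[float, float] = (1.50, 1.90)
    slice_range: tuple[int, int] = (4, 8)
    cirrhotic_proportion: float = 0.5
    female_proportion: float = 0.5

    def __post_init__(self) -> None:
        for name in ("region_scale_jitter", "torso_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("squeeze_range_cirrhotic", "squeeze_range_control", "height_range_m", "slice_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} has negative width")
        if not (0.0 <= self.cirrhotic_proportion <= 1.0 and 0.0 <= self.female_proportion <= 1.0):
            raise ValueError("proportions must be in [0, 1]")

    @classmethod
    def none(cls, base: PhantomParams) -> "CohortVariation":
        """Degenerate variation: every patient inherits the base geometry."""
        sq = (base.squeeze_factor, base.squeeze_factor)
        n = (base.n_true_slices, base.n_true_slices)
        return cls(
            region_scale_jitter=0.0,
            torso_jitter=0.0,
            squeeze_range_cirrhotic=sq,
            squeeze_range_control=sq,
            height_range_m=(base.height_m, base.height_m),
            slice_range=n,
        )


def generate_cohort(
    n_patients: int,
    base_params: PhantomParams | None = None,
    variation: CohortVariation | None = None,
    seed: int = 0,
):
    """Generate a jittered cohort of phantoms plus a manifest.

    Per-patient seeds are ``seed + index``; the cirrhotic and sex flags are
    allocated to exact counts (``round(n * proportion)``) via a seeded
    permutation, so stratified splitting downstream is exercisable.

    Returns ``(cases, manifest)`` where ``cases`` is a list of
    ``(CTSlab, LabelVolume, PatientMeta)`` and ``manifest`` a DataFrame.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = base_params if base_params is not None else PhantomParams()
    var = variation if variation is not None else CohortVariation()

    alloc_rng = np.random.default_rng(seed)
    n_cirr = int(round(n_patients * var.cirrhotic_proportion))
    cirr_idx = set(alloc_rng.permutation(n_patients)[:n_cirr].tolist())
    n_fem = int(round(n_patients * var.female_proportion))
    fem_idx = set(alloc_rng.permutation(n_patients)[:n_fem].tolist())

    d0, h0, w0 = base.grid_size
    ay0, ax0 = base.resolved_torso_radii()
    cases = []
    rows = []
    for i in range(n_patients):
        rng = np.random.default_rng(seed + i + 1)
        cirrhotic = i in cirr_idx
        sex = "female" if i in fem_idx else "male"
        jit = lambda j: float(rng.uniform(1.0 - j, 1.0 + j))
        sq_lo, sq_hi = (
            var.squeeze_range_cirrhotic if cirrhotic else var.squeeze_range_control
        )
        n_true = int(rng.integers(var.slice_range[0], var.slice_range[1] + 1))
        params = PhantomParams(
            grid_size=(max(d0, n_true), h0, w0),
            spacing_mm=base.spacing_mm,
            n_true_slices=n_true,
            torso_radii=(ay0 * jit(var.torso_jitter), ax0 * jit(var.torso_jitter)),
            region_scale=tuple(s * jit(var.region_scale_jitter) for s in base.region_scale),
            squeeze_factor=float(rng.uniform(sq_lo, sq_hi)),
            hu_means=dict(base.hu_means),
            hu_sds=dict(base.hu_sds),
            noise_sd=base.noise_sd,
            blur_sigma=base.blur_sigma,
            drift=base.drift,
            taper_per_slice=base.taper_per_slice,
            height_m=float(rng.uniform(*var.height_range_m)),
            sex=sex,
            seed=seed + i,
        )
        pid = f"p{i:03d}"
        slab, labels, meta = generate_phantom(params, patient_id=pid, cirrhotic=cirrhotic)
        cases.append((slab, labels, meta))
        row = {
            "patient_id": pid,
            "seed": seed + i,
            "height_m": meta.height_m,
            "sex": sex,
            "cirrhotic": cirrhotic,
            "n_true_slices": n_true,
            "squeeze_factor": params.squeeze_factor,
        }
        for c, area in meta.true_region_areas_cm2.items():
            row[f"area_cm2_class{c}"] = area
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return cases, manifest
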