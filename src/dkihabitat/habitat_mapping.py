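"""Dual-parameter habitat mapping of diffusion kurtosis parametric maps.

A tumor ROI is partitioned into four subhabitats by thresholding the mean
diffusivity (MD, units of 1e-3 mm^2/s) and mean kurtosis (MK, dimensionless)
maps with Otsu thresholds computed on voxels pooled over the whole cohort.
The four quadrants of the joint (MD, MK) threshold space are named by the
convention first letter = MD level, second letter = MK level:

* ``LL`` — restricted diffusion, low density (MD < t_md, MK < t_mk)
* ``LH`` — restricted diffusion, high density (MD < t_md, MK >= t_mk)
* ``HL`` — unrestricted diffusion, low density (MD >= t_md, MK < t_mk)
* ``HH`` — unrestricted diffusion, high density (MD >= t_md, MK >= t_mk)

Each subject then yields 16 quantitative habitat features: per subhabitat the
mean MD, mean MK, absolute volume (mL) and percentage of the ROI volume.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, GeometryError

__all__ = [
    "HABITAT_LABELS",
    "LABEL_CODES",
    "FEATURE_KINDS",
    "FEATURE_NAMES",
    "STUDY_THRESHOLDS",
    "ParametricVolume",
    "SubjectImaging",
    "HabitatThresholds",
    "HabitatLabelMap",
    "HabitatFeatures",
    "compute_otsu_threshold",
    "compute_cohort_thresholds",
    "partition_habitats",
    "extract_habitat_features",
    "features_to_frame",
    "icc_agreement",
]

#: Subhabitat names in canonical order.
HABITAT_LABELS: tuple[str, ...] = ("LL", "LH", "HL", "HH")

#: Integer codes used in label volumes (0 is background).
LABEL_CODES: dict[str, int] = {"background": 0, "LL": 1, "LH": 2, "HL": 3, "HH": 4}

#: Per-habitat feature kinds in canonical order.
FEATURE_KINDS: tuple[str, ...] = ("MD", "MK", "volume", "percent")

#: The 16 habitat feature names, ordered (LL, LH, HL, HH) x (MD, MK, volume, percent).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{label}_{kind}" for label in HABITAT_LABELS for kind in FEATURE_KINDS
)


@dataclass(frozen=True)
class HabitatThresholds:
    """The two cohort-level Otsu thresholds defining the habitat quadrants."""

    t_md: float  #: MD threshold, 1e-3 mm^2/s
    t_mk: float  #: MK threshold, dimensionless

    def __post_init__(self) -> None:
        for name, value in (("t_md", self.t_md), ("t_mk", self.t_mk)):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value!r}")


#: Thresholds reported by the source study (MD 1.71e-3 mm^2/s, MK 0.58).
#: Packaged as a documented reference for scoring without a cohort; they are
#: not reproducible without the original images.
STUDY_THRESHOLDS = HabitatThresholds(t_md=1.71, t_mk=0.58)


@dataclass
class ParametricVolume:
    """A single 3D parametric map with its spatial affine."""

    values: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("parametric volume must be 3D")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine spatial part must be invertible")


@dataclass
class SubjectImaging:
    """Co-registered MD and MK maps plus the binary tumor ROI for one subject."""

    subject_id: str
    md: ParametricVolume
    mk: ParametricVolume
    roi: np.ndarray

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi).astype(bool)
        if not (self.md.values.shape == self.mk.values.shape == self.roi.shape):
            raise GeometryError("MD, MK and ROI must share one shape")
        if not np.allclose(self.md.affine, self.mk.affine):
            raise GeometryError("MD and MK affines differ")
        if not self.roi.any():
            raise GeometryError("ROI is empty")
        inside = self.roi
        if not (np.isfinite(self.md.values[inside]).all() and np.isfinite(self.mk.values[inside]).all()):
            raise ValueError("non-finite parametric values inside the ROI")

    @property
    def affine(self) -> np.ndarray:
        return self.md.affine

    def roi_voxel_count(self) -> int:
        return int(self.roi.sum())


@dataclass
class HabitatLabelMap:
    """Per-voxel habitat labels (integer coded) and the thresholds that made them."""

    labels: np.ndarray
    thresholds_used: HabitatThresholds

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, list(LABEL_CODES.values())).all():
            raise ValueError("label map contains codes outside 0..4")

    def mask(self, label: str) -> np.ndarray:
        return self.labels == LABEL_CODES[label]

    def counts(self) -> dict[str, int]:
        return {label: int(self.mask(label).sum()) for label in HABITAT_LABELS}


@dataclass
class HabitatFeatures:
    """The 16 per-subject habitat features.

    ``MD``/``MK`` means are NaN exactly when the subhabitat is absent
    (zero volume); ``volume`` (mL) and ``percent`` are then 0.
    """

    subject_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def to_series(self) -> pd.Series:
        return pd.Series({name: self.values[name] for name in FEATURE_NAMES}, name=self.subject_id)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of a 1D sample.

    The data range is split into ``n_bins`` equal-width bins and each interior
    bin boundary is scored by the between-class variance of the exact data
    split (values strictly below the boundary versus the rest); the boundary
    maximizing it is returned, ties broken toward the lowest threshold.
    Minimizing within-class variance would select the same boundary since the
    two sum to the total variance.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    if x[0] == x[-1]:
        raise DegenerateInputError("constant input has no Otsu threshold")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    edges = np.linspace(x[0], x[-1], n_bins + 1)
    candidates = edges[1:-1]
    n = x.size
    n_below = np.searchsorted(x, candidates, side="left")
    valid = (n_below > 0) & (n_below < n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum[n_below] / n_below
        mu1 = (csum[n] - csum[n_below]) / (n - n_below)
        w0 = n_below / n
        sigma_b = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    if not np.isfinite(sigma_b).any():
        # every candidate leaves one side empty (all mass in the extreme bins)
        raise DegenerateInputError("no valid split found")
    return float(candidates[int(np.argmax(sigma_b))])


def compute_cohort_thresholds(
    subjects: Sequence[SubjectImaging], n_bins: int = 256
) -> HabitatThresholds:
    """Otsu thresholds on MD and MK voxels pooled over every subject's ROI."""
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    md = np.concatenate([s.md.values[s.roi] for s in subjects])
    mk = np.concatenate([s.mk.values[s.roi] for s in subjects])
    return HabitatThresholds(
        t_md=compute_otsu_threshold(md, n_bins=n_bins),
        t_mk=compute_otsu_threshold(mk, n_bins=n_bins),
    )


def partition_habitats(
    subject: SubjectImaging, thresholds: HabitatThresholds
) -> HabitatLabelMap:
    """Assign each ROI voxel to one of the four (MD, MK) quadrants.

    Values exactly equal to a threshold go to the "high" class.
    """
    md, mk, roi = subject.md.values, subject.mk.values, subject.roi
    labels = np.zeros(roi.shape, dtype=np.uint8)
    md_high = md >= thresholds.t_md
    mk_high = mk >= thresholds.t_mk
    labels[roi & ~md_high & ~mk_high] = LABEL_CODES["LL"]
    labels[roi & ~md_high & mk_high] = LABEL_CODES["LH"]
    labels[roi & md_high & ~mk_high] = LABEL_CODES["HL"]
    labels[roi & md_high & mk_high] = LABEL_CODES["HH"]
    return HabitatLabelMap(labels=labels, thresholds_used=thresholds)


def _voxel_volume_ml(affine: np.ndarray) -> float:
    # affine maps voxel indices to mm; 1 mL = 1000 mm^3
    return float(abs(np.linalg.det(affine[:3, :3])) / 1000.0)


def extract_habitat_features(
    labelmap: HabitatLabelMap, subject: SubjectImaging
) -> HabitatFeatures:
    """Per-subhabitat mean MD, mean MK, volume (mL) and percent of ROI volume."""
    if labelmap.labels.shape != subject.roi.shape:
        raise GeometryError("label map and subject volumes differ in shape")
    n_roi = subject.roi_voxel_count()
    vox_ml = _voxel_volume_ml(subject.affine)
    values: dict[str, float] = {}
    for label in HABITAT_LABELS:
        mask = labelmap.mask(label)
        n = int(mask.sum())
        if n:
            values[f"{label}_MD"] = float(subject.md.values[mask].mean())
            values[f"{label}_MK"] = float(subject.mk.values[mask].mean())
        else:
            values[f"{label}_MD"] = np.nan
            values[f"{label}_MK"] = np.nan
        values[f"{label}_volume"] = n * vox_ml
        values[f"{label}_percent"] = 100.0 * n / n_roi
    return HabitatFeatures(subject_id=subject.subject_id, values=values)


def features_to_frame(features: Iterable[HabitatFeatures]) -> pd.DataFrame:
    """Stack per-subject features into a (subjects x 16) DataFrame."""
    frame = pd.DataFrame([f.to_series() for f in features])
    frame.index.name = "subject_id"
    return frame[list(FEATURE_NAMES)]


def icc_agreement(
    features_rater_a: Sequence[HabitatFeatures],
    features_rater_b: Sequence[HabitatFeatures],
    variant: str = "absolute",
    floor: float = 0.60,
) -> pd.DataFrame:
    """Two-rater intraclass correlation per habitat feature.

    ``variant="absolute"`` is the two-way random-effects absolute-agreement
    single-measure ICC (ICC2); ``variant="consistency"`` is the two-way mixed
    consistency single-measure ICC (ICC3), which ignores a constant rater
    offset. Subjects with a missing value (absent subhabitat) under either
    rater are dropped feature-wise. Returns one row per feature with the
    coefficient and a pass flag at the retention ``floor``.
    """
    import pingouin as pg

    if len(features_rater_a) != len(features_rater_b):
        raise ValueError("raters scored different numbers of subjects")
    if len(features_rater_a) < 3:
        raise ValueError("need at least 3 subjects")
    ids_a = [f.subject_id for f in features_rater_a]
    ids_b = [f.subject_id for f in features_rater_b]
    if ids_a != ids_b:
        raise ValueError("subject order differs between raters")
    icc_name = {"absolute": "ICC(A,1)", "consistency": "ICC(C,1)"}.get(variant)
    if icc_name is None:
        raise ValueError(f"unknown variant {variant!r}")

    frame_a = features_to_frame(features_rater_a)
    frame_b = features_to_frame(features_rater_b)
    rows = []
    for name in FEATURE_NAMES:
        pair = pd.DataFrame({"A": frame_a[name], "B": frame_b[name]}).dropna()
        if len(pair) < 3:
            rows.append({"feature": name, "icc": np.nan, "n_subjects": len(pair), "passes": False})
            continue
        if np.allclose(pair["A"].var(ddof=1), 0) and np.allclose(pair["B"].var(ddof=1), 0):
            raise DegenerateInputError(f"zero between-subject variance for {name}")
        long = pair.reset_index().melt(
            id_vars="subject_id", var_name="rater", value_name="rating"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pg.intraclass_corr(
                data=long, targets="subject_id", raters="rater", ratings="rating"
            )
        icc = float(table.set_index("Type").loc[icc_name, "ICC"])
        rows.append(
            {"feature": name, "icc": icc, "n_subjects": len(pair), "passes": bool(icc >= floor)}
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_subject(
    subject_id: str, md_path, mk_path, roi_path
) -> SubjectImaging:
    """Read one subject's MD/MK/ROI volumes from NIfTI files."""
    import nibabel as nib

    md_img = nib.load(str(md_path))
    mk_img = nib.load(str(mk_path))
    roi_img = nib.load(str(roi_path))
    return SubjectImaging(
        subject_id=subject_id,
        md=ParametricVolume(md_img.get_fdata(), md_img.affine, units="1e-3 mm^2/s"),
        mk=ParametricVolume(mk_img.get_fdata(), mk_img.affine, units="dimensionless"),
        roi=roi_img.get_fdata() > 0,
    )


def save_labelmap(labelmap: HabitatLabelMap, affine: np.ndarray, path) -> None:
    """Write a label map as integer-coded NIfTI ({0..4} = background, LL, LH, HL, HH)."""
    import nibabel as nib

    img = nib.Nifti1Image(labelmap.labels.astype(np.uint8), np.asarray(affine))
    nib.save(img, str(path))
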