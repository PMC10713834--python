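"""Seeded synthetic glioma cohorts: parametric maps, habitat truth, clinical table.

No public image cohort accompanies the habitat method, so this module
generates one with the statistical structure the analysis assumes:

* Per-subject co-registered MD and MK volumes in which each ground-truth
  subhabitat's voxels are drawn from a configurable bivariate normal.  The
  default means straddle the reference thresholds (MD 1.71e-3 mm^2/s,
  MK 0.58) and the default per-habitat MD-MK correlations follow the signs
  and magnitudes reported for glioma subhabitats (LL ~0, LH negative,
  HL positive, HH near 1).
* A spatial model of nested ellipsoids: an LH core (cellular tumor), an LL
  shell (infiltrative margin), an HL outer shell (edema/cystic change) and a
  small off-center HH pocket (hypoxic/necrotic zone).  A class-dependent
  fraction of subjects lacks the HH pocket and/or the HL shell, so absent
  subhabitats occur as they do in real cohorts.
* A clinical/morphology table whose class-conditional prevalences default to
  the empirical proportions of a 103-subject glioma cohort (47 IDH-mutant /
  56 IDH wild-type), plus an exact fixture reproducing those categorical
  counts to the subject.

Everything is deterministic given the seed; each subject consumes an
independent RNG stream derived from (seed, subject index), so cohorts are
order-independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .habitat_mapping import (
    HABITAT_LABELS,
    LABEL_CODES,
    HabitatLabelMap,
    HabitatThresholds,
    ParametricVolume,
    SubjectImaging,
)

__all__ = [
    "CLINICAL_COLUMNS",
    "TABLE1_COUNTS",
    "ClinicalRecord",
    "HabitatIntensity",
    "SimulationConfig",
    "SyntheticSubject",
    "generate_clinical_record",
    "generate_clinical_cohort",
    "generate_subject_maps",
    "generate_cohort",
    "table1_fixture",
    "cohort_to_frame",
    "save_subject",
    "save_cohort",
]


# ---------------------------------------------------------------------------
# Clinical records

#: Categorical levels for each clinical/morphological variable.
CLINICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "necrosis": ("present", "absent"),
    "hemorrhage": ("present", "absent"),
    "calcification": ("present", "absent"),
    "cyst": ("present", "absent"),
    "edema": ("yes", "no"),  # shortest tumor-to-white-matter distance <= 1.5 cm
    "borders": ("sharp", "blurry"),
    "location": ("frontal_insula", "other", "basal_callosum"),
    "side": ("left", "right"),
    "enhancement": ("patchy", "ringlike", "nonenhancing"),
}

#: Class-conditional counts of the reference 103-subject cohort.  The first
#: entry of each tuple corresponds to the first level in CLINICAL_COLUMNS;
#: counts within a variable sum to the class total.
TABLE1_COUNTS: dict[str, dict[str, object]] = {
    "mutant": {
        "n": 47,
        "age_mean": 46.83,
        "age_sd": 10.70,
        "sex": (27, 20),
        "necrosis": (26, 21),
        "hemorrhage": (28, 19),
        "calcification": (16, 31),
        "cyst": (40, 7),
        "edema": (32, 15),
        "borders": (23, 24),
        "location": (37, 3, 7),
        "side": (22, 25),
        "enhancement": (20, 16, 11),
        "hh_absent": 15,
        "hl_absent": 0,
    },
    "wildtype": {
        "n": 56,
        "age_mean": 57.29,
        "age_sd": 10.70,
        "sex": (27, 29),
        "necrosis": (49, 7),
        "hemorrhage": (47, 9),
        "calcification": (7, 49),
        "cyst": (51, 5),
        "edema": (26, 30),
        "borders": (29, 27),
        "location": (16, 5, 35),
        "side": (30, 26),
        "enhancement": (5, 49, 2),
        "hh_absent": 8,
        "hl_absent": 5,
    },
}


def _class_probabilities(idh: str) -> dict[str, np.ndarray]:
    counts = TABLE1_COUNTS[idh]
    return {
        var: np.asarray(counts[var], dtype=float) / counts["n"]  # type: ignore[index]
        for var in CLINICAL_COLUMNS
    }


@dataclass
class ClinicalRecord:
    """Age, sex, eight conventional-MRI morphology signs, and IDH status."""

    subject_id: str
    age: float
    sex: str
    necrosis: str
    hemorrhage: str
    calcification: str
    cyst: str
    edema: str
    borders: str
    location: str
    side: str
    enhancement: str
    idh: str  # "mutant" or "wildtype"

    def __post_init__(self) -> None:
        for var, levels in CLINICAL_COLUMNS.items():
            if getattr(self, var) not in levels:
                raise ValueError(f"{var}={getattr(self, var)!r} not in {levels}")
        if self.idh not in ("mutant", "wildtype"):
            raise ValueError(f"idh must be 'mutant' or 'wildtype', got {self.idh!r}")


def cohort_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return frame.set_index("subject_id")


# ---------------------------------------------------------------------------
# Simulation configuration


@dataclass(frozen=True)
class HabitatIntensity:
    """Bivariate (MD, MK) distribution for one subhabitat's voxels."""

    md_mean: float
    mk_mean: float
    md_sd: float = 0.15
    mk_sd: float = 0.07
    correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.md_sd <= 0 or self.mk_sd <= 0:
            raise ConfigurationError("standard deviations must be > 0")
        if abs(self.correlation) > 1:
            raise ConfigurationError("|correlation| must be <= 1")

    def covariance(self) -> np.ndarray:
        c = self.correlation * self.md_sd * self.mk_sd
        return np.array([[self.md_sd**2, c], [c, self.mk_sd**2]])


def _default_intensity() -> dict[str, HabitatIntensity]:
    # Means symmetric about the reference boundaries MD 1.71, MK 0.58;
    # correlations follow the reported per-subhabitat signs/magnitudes.
    return {
        "LL": HabitatIntensity(md_mean=1.15, mk_mean=0.35, correlation=0.05),
        "LH": HabitatIntensity(md_mean=1.15, mk_mean=0.81, correlation=-0.666),
        "HL": HabitatIntensity(md_mean=2.27, mk_mean=0.35, correlation=0.665),
        "HH": HabitatIntensity(md_mean=2.27, mk_mean=0.81, correlation=0.999),
    }


def _default_geometry() -> dict[str, tuple[float, float, float]]:
    return {
        "LH": (6.0, 6.0, 6.0),
        "LL": (10.0, 10.0, 10.0),
        "HL": (14.0, 14.0, 14.0),
        "HH": (3.0, 3.0, 3.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The defaults are the study conditions: 103 subjects with a 47/103
    IDH-mutant fraction, habitat means straddling MD 1.71 / MK 0.58, and
    class-dependent absence of the HH pocket (15/47 mutant, 8/56 wild-type)
    and the HL shell (0/47, 5/56).  ``wildtype_mk_shift`` raises the
    high-density (LH/HH) MK means in wild-type subjects, giving the imaging
    features a modest class signal consistent with wild-type tumors being
    more cell-dense.
    """

    n_subjects: int = 103
    idh_mut_fraction: float = 47 / 103
    habitat_intensity: Mapping[str, HabitatIntensity] = field(default_factory=_default_intensity)
    geometry: Mapping[str, tuple[float, float, float]] = field(default_factory=_default_geometry)
    hh_offset: tuple[float, float, float] = (7.0, 0.0, 0.0)
    volume_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    absence_fraction: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HH": {"mutant": 15 / 47, "wildtype": 8 / 56},
            "HL": {"mutant": 0.0, "wildtype": 5 / 56},
        }
    )
    wildtype_mk_shift: float = 0.06
    between_md_shared_sd: float = 0.06
    between_md_habitat_sd: float = 0.05
    between_mk_shared_sd: float = 0.04
    between_mk_habitat_sd: float = 0.04
    md_units: str = "1e-3 mm^2/s"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.idh_mut_fraction <= 1:
            raise ConfigurationError("idh_mut_fraction must be in [0, 1]")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        missing = set(self.habitat_intensity) ^ set(HABITAT_LABELS)
        if missing:
            raise ConfigurationError(f"habitat_intensity must cover {HABITAT_LABELS}")
        present = [lab for lab in ("LH", "LL", "HL") if lab in self.geometry]
        radii = [np.asarray(self.geometry[lab], dtype=float) for lab in present]
        for r in radii:
            if (r <= 0).any():
                raise ConfigurationError("ellipsoid radii must be positive")
        for inner, outer in zip(radii, radii[1:]):
            if not (inner < outer).all():
                raise ConfigurationError("shell radii must be strictly nested (LH < LL < HL)")
        if "HH" in self.geometry:
            r_hh = np.asarray(self.geometry["HH"], dtype=float)
            host = radii[-1] if radii else None
            if host is None:
                raise ConfigurationError("HH pocket needs at least one enclosing shell")
            if ((np.abs(np.asarray(self.hh_offset)) + r_hh) > host).any():
                raise ConfigurationError("HH pocket must lie inside the outermost shell")
        for frac_by_class in self.absence_fraction.values():
            for frac in frac_by_class.values():
                if not 0 <= frac <= 1:
                    raise ConfigurationError("absence fractions must be in [0, 1]")
        shape = np.asarray(self.volume_shape)
        if shape.shape != (3,) or (shape < 4).any():
            raise ConfigurationError("volume_shape must be 3 positive integers")

    def expected_boundaries(self) -> HabitatThresholds:
        """Midpoints of the configured low/high class means on each axis."""
        inten = self.habitat_intensity
        md_low = np.mean([inten["LL"].md_mean, inten["LH"].md_mean])
        md_high = np.mean([inten["HL"].md_mean, inten["HH"].md_mean])
        mk_low = np.mean([inten["LL"].mk_mean, inten["HL"].mk_mean])
        mk_high = np.mean([inten["LH"].mk_mean, inten["HH"].mk_mean])
        return HabitatThresholds(
            t_md=(md_low + md_high) / 2.0, t_mk=(mk_low + mk_high) / 2.0
        )

    def affine(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = np.diag(self.voxel_size)
        return out


@dataclass
class SyntheticSubject:
    """One simulated subject: imaging, ground-truth habitat labels, clinical record."""

    imaging: SubjectImaging
    truth_labels: HabitatLabelMap
    clinical: ClinicalRecord


# ---------------------------------------------------------------------------
# Generation


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject_index, stream])


def generate_clinical_record(config: SimulationConfig, subject_index: int) -> ClinicalRecord:
    """Clinical record for one subject, deterministic given (seed, index)."""
    if subject_index >= config.n_subjects:
        raise ConfigurationError("subject_index out of range")
    rng = _subject_rng(config.seed, subject_index, 0)
    idh = "mutant" if rng.random() < config.idh_mut_fraction else "wildtype"
    counts = TABLE1_COUNTS[idh]
    probs = _class_probabilities(idh)
    fields: dict[str, str] = {}
    for var, levels in CLINICAL_COLUMNS.items():
        fields[var] = str(rng.choice(levels, p=probs[var]))
    age = float(rng.normal(counts["age_mean"], counts["age_sd"]))
    return ClinicalRecord(
        subject_id=f"sub-{subject_index:04d}", age=age, idh=idh, **fields
    )


def generate_clinical_cohort(config: SimulationConfig) -> list[ClinicalRecord]:
    """The full clinical table; per-subject streams make it order-independent."""
    if config.n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects for a cohort")
    return [generate_clinical_record(config, i) for i in range(config.n_subjects)]


def _ellipsoid_mask(
    shape: np.ndarray, center: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    grids = np.indices(tuple(shape), dtype=float)
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist2 <= 1.0


def generate_subject_maps(config: SimulationConfig, subject_index: int) -> SyntheticSubject:
    """Simulate one subject's MD/MK volumes with ground-truth habitat labels.

    The spatial layout is an LH ellipsoidal core, an LL shell, an HL outer
    shell and an HH pocket stamped over whatever it covers; absence of the
    HH pocket and HL shell is drawn per subject with class-dependent
    probability.  Voxel intensities are bivariate normal per ground-truth
    label.  Deterministic given (config.seed, subject_index).
    """
    clinical = generate_clinical_record(config, subject_index)
    rng = _subject_rng(config.seed, subject_index, 1)

    hh_absent = "HH" not in config.geometry or (
        rng.random() < config.absence_fraction.get("HH", {}).get(clinical.idh, 0.0)
    )
    hl_absent = "HL" not in config.geometry or (
        rng.random() < config.absence_fraction.get("HL", {}).get(clinical.idh, 0.0)
    )

    shape = np.asarray(config.volume_shape)
    center = (shape - 1) / 2.0
    labels = np.zeros(tuple(shape), dtype=np.uint8)

    shells: list[tuple[str, np.ndarray]] = []
    for lab in ("LH", "LL", "HL"):
        if lab not in config.geometry or (lab == "HL" and hl_absent):
            continue
        shells.append((lab, np.asarray(config.geometry[lab], dtype=float)))
    if not shells:
        raise ConfigurationError("geometry defines no shells")
    # outermost shell defines the ROI
    roi = _ellipsoid_mask(shape, center, shells[-1][1])
    covered = np.zeros_like(roi)
    for lab, radii in shells:
        mask = _ellipsoid_mask(shape, center, radii) & ~covered
        labels[mask] = LABEL_CODES[lab]
        covered |= mask
    if not hh_absent:
        pocket = _ellipsoid_mask(
            shape, center + np.asarray(config.hh_offset), np.asarray(config.geometry["HH"], dtype=float)
        )
        labels[pocket & roi] = LABEL_CODES["HH"]
    if not roi.any():
        raise ConfigurationError("zero-volume ROI")

    md = np.zeros(tuple(shape))
    mk = np.zeros(tuple(shape))
    # between-subject variation of habitat means: one tumor-wide offset shared
    # by all habitats (so related habitats co-vary across subjects) plus an
    # independent per-habitat component
    shared = np.array(
        [
            rng.normal(0.0, config.between_md_shared_sd),
            rng.normal(0.0, config.between_mk_shared_sd),
        ]
    )
    habitat_offsets = {
        lab: shared
        + np.array(
            [
                rng.normal(0.0, config.between_md_habitat_sd),
                rng.normal(0.0, config.between_mk_habitat_sd),
            ]
        )
        for lab in HABITAT_LABELS
    }
    for lab in HABITAT_LABELS:
        mask = labels == LABEL_CODES[lab]
        n = int(mask.sum())
        if n == 0:
            continue
        inten = config.habitat_intensity[lab]
        mean = np.array([inten.md_mean, inten.mk_mean]) + habitat_offsets[lab]
        if clinical.idh == "wildtype" and lab in ("LH", "HH"):
            mean = mean + np.array([0.0, config.wildtype_mk_shift])
        draws = rng.multivariate_normal(mean, inten.covariance(), size=n, method="cholesky")
        md[mask] = draws[:, 0]
        mk[mask] = draws[:, 1]

    affine = config.affine()
    imaging = SubjectImaging(
        subject_id=clinical.subject_id,
        md=ParametricVolume(md, affine, units=config.md_units),
        mk=ParametricVolume(mk, affine, units="dimensionless"),
        roi=roi,
    )
    truth = HabitatLabelMap(labels=labels, thresholds_used=config.expected_boundaries())
    return SyntheticSubject(imaging=imaging, truth_labels=truth, clinical=clinical)


def generate_cohort(config: SimulationConfig) -> list[SyntheticSubject]:
    """All subjects of the configured cohort (imaging + truth + clinical)."""
    return [generate_subject_maps(config, i) for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# Exact characteristics-table fixture


def table1_fixture(seed: int = 0) -> list[ClinicalRecord]:
    """A 103-subject cohort reproducing the reference categorical counts exactly.

    Every cross-tabulation of a categorical variable against IDH class equals
    the reference cohort's printed counts to the subject (e.g. calcification
    16/31 in the 47 mutants, 7/49 in the 56 wild-types).  Ages are synthetic:
    they are drawn from the printed class mean +/- SD and affinely adjusted so
    the sample moments match exactly; only the categorical counts are exact
    subject-for-subject.  Variables are assigned independently — the printed
    table constrains only the margins, not the joint distribution.
    """
    rng = np.random.default_rng([seed, 1103])
    records: list[ClinicalRecord] = []
    index = 0
    for idh in ("mutant", "wildtype"):
        counts = TABLE1_COUNTS[idh]
        n = int(counts["n"])  # type: ignore[arg-type]
        columns: dict[str, list[str]] = {}
        for var, levels in CLINICAL_COLUMNS.items():
            per_level = counts[var]
            values = [
                level for level, k in zip(levels, per_level) for _ in range(int(k))  # type: ignore[arg-type]
            ]
            assert len(values) == n
            rng.shuffle(values)
            columns[var] = values
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        ages = counts["age_mean"] + counts["age_sd"] * z  # type: ignore[operator]
        for i in range(n):
            records.append(
                ClinicalRecord(
                    subject_id=f"sub-{index:04d}",
                    age=float(ages[i]),
                    idh=idh,
                    **{var: columns[var][i] for var in CLINICAL_COLUMNS},
                )
            )
            index += 1
    return records


# ---------------------------------------------------------------------------
# On-disk export


def save_subject(subject: SyntheticSubject, out_dir) -> None:
    """Write one subject's MD/MK/ROI/truth volumes as .nii.gz under out_dir."""
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir) / subject.clinical.subject_id
    out.mkdir(parents=True, exist_ok=True)
    affine = subject.imaging.affine
    nib.save(nib.Nifti1Image(subject.imaging.md.values, affine), out / "md.nii.gz")
    nib.save(nib.Nifti1Image(subject.imaging.mk.values, affine), out / "mk.nii.gz")
    nib.save(
        nib.Nifti1Image(subject.imaging.roi.astype(np.uint8), affine), out / "roi.nii.gz"
    )
    nib.save(
        nib.Nifti1Image(subject.truth_labels.labels.astype(np.uint8), affine),
        out / "truth_labels.nii.gz",
    )


def save_cohort(config: SimulationConfig, out_dir, fixture_table1: bool = False) -> None:
    """Write the whole cohort: per-subject volumes plus clinical.csv.

    With ``fixture_table1`` the clinical table is the exact-count fixture
    (no imaging is written for it, as it carries no imaging ground truth).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fixture_table1:
        records = table1_fixture(seed=config.seed)
    else:
        subjects = generate_cohort(config)
        for subject in subjects:
            save_subject(subject, out)
        records = [s.clinical for s in subjects]
    cohort_to_frame(records).to_csv(out / "clinical.csv")
    with open(out / "clinical_columns.json", "w") as fh:
        import json

        json.dump(
            {var: list(levels) for var, levels in CLINICAL_COLUMNS.items()}
            | {"age": "years", "idh": ["mutant", "wildtype"]},
            fh,
            indent=2,
        )
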