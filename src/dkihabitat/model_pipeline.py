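"""IDH-prediction model harness and the HANDINESS logistic score.

The harness enumerates 32 modelling pipelines — 2 dimensionality-reduction
steps (principal components at 95% cumulative variance, or pairwise Pearson
decorrelation at |r| > 0.85) x 4 feature selectors (one-way ANOVA F,
recursive feature elimination, Kruskal-Wallis H, ReliefF with 5 neighbours)
x 4 linear classifiers (logistic, L1 logistic, linear discriminant, linear
SVM) — and scores each with leave-one-out cross-validation (LOOCV), every
fold re-fitting scaler, reducer, selector and classifier on the training
subjects only.  The positive class is IDH wild-type throughout.

Three models are built on top of the harness:

* ``ClinicRad`` — best pipeline on the clinical + morphology covariates;
* ``H-MRI``   — best pipeline on the 16 habitat features;
* ``HANDINESS`` — a logistic model on {age, necrosis, hemorrhage, tumor
  location, calcification, H-MRI probability, edema}, where the H-MRI input
  is each subject's held-out LOOCV probability, never an in-fold fit.

The published HANDINESS coefficients are packaged as reference constants:
L = 0.03*age - 0.65*necrosis - 0.54*hemorrhage + 0.73*location
+ 1.65*calcification + 2.35*H-MRI + 0.48*edema - 6.14, with probability
1/(1+e^-L) and decision cutoff 0.38.  The covariate coding behind the
published fit was not reported; the coding table below is an explicit,
configurable default, not an inference of intent.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.feature_selection import RFE, SelectorMixin, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import roc_auc
from .synthetic_cohort import ClinicalRecord

__all__ = [
    "REDUCERS",
    "SELECTORS",
    "CLASSIFIERS",
    "HANDINESS_CODING",
    "STUDY_HANDINESS",
    "FeatureMatrix",
    "PipelineSpec",
    "PipelineResult",
    "HandinessCoefficients",
    "HandinessModel",
    "ThreeModels",
    "enumerate_pipelines",
    "build_pipeline",
    "run_loocv",
    "run_pipeline_search",
    "select_best_pipeline",
    "fit_three_models",
    "encode_clinical",
    "encode_handiness_covariates",
    "handiness_logodds",
    "logodds_to_probability",
    "youden_cutoff",
    "simulate_handiness_cohort",
    "refit_handiness",
]

REDUCERS = ("pca", "correlation")
SELECTORS = ("anova", "rfe", "kruskal", "relief")
CLASSIFIERS = ("logistic", "l1-logistic", "lda", "linear-svm")


# ---------------------------------------------------------------------------
# Feature container


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with 0/1 labels (1 = IDH wild-type)."""

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    imputed: np.ndarray | None = None  # True where a missing value was filled

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values after imputation")
        if min((self.labels == 0).sum(), (self.labels == 1).sum()) < 2:
            raise ValueError("need at least 2 subjects per class")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, labels, fill_value: float = 0.0):
        """Build from a features DataFrame, imputing missing cells.

        Absent subhabitats leave NaN means; they are imputed with
        ``fill_value`` (default 0, i.e. "no such tissue") and recorded in the
        imputation mask.
        """
        values = frame.to_numpy(dtype=float)
        imputed = ~np.isfinite(values)
        values = np.where(imputed, fill_value, values)
        return cls(
            subject_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=values,
            labels=np.asarray(labels, dtype=int),
            imputed=imputed,
        )


#: Numeric coding of clinical/morphological covariates used for modelling.
#: Binary signs: present/yes = 1; location is ordinal by wild-type enrichment;
#: enhancement is ordinal patchy < ringlike < nonenhancing as printed.
CLINICAL_CODING: dict[str, dict[str, float]] = {
    "sex": {"male": 1, "female": 0},
    "necrosis": {"present": 1, "absent": 0},
    "hemorrhage": {"present": 1, "absent": 0},
    "calcification": {"present": 1, "absent": 0},
    "cyst": {"present": 1, "absent": 0},
    "edema": {"yes": 1, "no": 0},
    "borders": {"blurry": 1, "sharp": 0},
    "location": {"frontal_insula": 0, "other": 1, "basal_callosum": 2},
    "side": {"right": 1, "left": 0},
    "enhancement": {"patchy": 0, "ringlike": 1, "nonenhancing": 2},
}

CLINICAL_FEATURE_NAMES = ["age"] + list(CLINICAL_CODING)


def encode_clinical(records: Sequence[ClinicalRecord]) -> FeatureMatrix:
    """Encode clinical records numerically; labels are 1 for IDH wild-type."""
    rows = []
    for rec in records:
        row = [rec.age] + [
            CLINICAL_CODING[var][getattr(rec, var)] for var in CLINICAL_CODING
        ]
        rows.append(row)
    return FeatureMatrix(
        subject_ids=[r.subject_id for r in records],
        feature_names=list(CLINICAL_FEATURE_NAMES),
        values=np.asarray(rows, dtype=float),
        labels=np.array([1 if r.idh == "wildtype" else 0 for r in records]),
    )


# ---------------------------------------------------------------------------
# Pipeline building blocks


class CorrelationFilter(SelectorMixin, BaseEstimator):
    """Drop the later feature of any pair with |Pearson r| above a threshold.

    Features are scanned in their given (canonical) order, so the earlier
    member of a highly collinear pair is always the one retained.
    """

    def __init__(self, threshold: float = 0.85):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        keep = np.ones(p, dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        for i in range(p):
            if not keep[i]:
                continue
            for j in range(i + 1, p):
                if keep[j] and abs(corr[i, j]) > self.threshold:
                    keep[j] = False
        self.support_ = keep
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        return self.support_


def _kruskal_scores(X, y) -> np.ndarray:
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        groups = [X[y == c, j] for c in np.unique(y)]
        try:
            scores[j] = stats.kruskal(*groups).statistic
        except ValueError:  # all values identical
            scores[j] = 0.0
    return scores


def _anova_scores(X, y) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        f, _ = f_classif(X, y)
    return np.nan_to_num(f, nan=0.0)


def _relief_scores(X, y, n_neighbors: int = 5) -> np.ndarray:
    """ReliefF feature weights (k-nearest-neighbour variant, k=5).

    For each sample, features are rewarded for separating it from its
    nearest misses (other class) and penalised for separating it from its
    nearest hits (same class); distances use range-normalised Manhattan
    differences as in the classic formulation.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = X / span
    weights = np.zeros(p)
    classes = np.unique(y)
    priors = {c: (y == c).mean() for c in classes}
    for i in range(n):
        diff = np.abs(Xn - Xn[i])
        dist = diff.sum(axis=1)
        dist[i] = np.inf
        for c in classes:
            members = np.flatnonzero((y == c) & (dist < np.inf))
            if members.size == 0:
                continue
            k = min(n_neighbors, members.size)
            nearest = members[np.argsort(dist[members])[:k]]
            contrib = diff[nearest].mean(axis=0)
            if c == y[i]:
                weights -= contrib / n
            else:
                scale = priors[c] / max(1.0 - priors[y[i]], 1e-12)
                weights += scale * contrib / n
    return weights


class TopKSelector(SelectorMixin, BaseEstimator):
    """Keep the k highest-scoring features; k is capped at the feature count."""

    def __init__(self, method: str = "anova", k: int = 5):
        self.method = method
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        scorer = {
            "anova": _anova_scores,
            "kruskal": _kruskal_scores,
            "relief": _relief_scores,
        }[self.method]
        scores = scorer(X, y)
        k = min(self.k, X.shape[1])
        order = np.argsort(-scores, kind="stable")
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[:k]] = True
        self.scores_ = scores
        self.support_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


class CappedRFE(BaseEstimator):
    """Recursive feature elimination whose target size adapts to the input width."""

    def __init__(self, estimator, k: int = 5):
        self.estimator = estimator
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        k = min(self.k, X.shape[1])
        self.rfe_ = RFE(clone(self.estimator), n_features_to_select=k)
        self.rfe_.fit(X, y)
        return self

    def transform(self, X):
        return self.rfe_.transform(X)

    def get_support(self, indices=False):
        return self.rfe_.get_support(indices=indices)


# ---------------------------------------------------------------------------
# Pipeline spec and evaluation


@dataclass(frozen=True)
class PipelineSpec:
    """One of the harness's modelling recipes."""

    reducer: str
    selector: str
    classifier: str
    n_selected: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reducer not in REDUCERS:
            raise ValueError(f"reducer must be one of {REDUCERS}")
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.n_selected < 1:
            raise ValueError("n_selected must be >= 1")


@dataclass
class PipelineResult:
    """LOOCV outcome of one spec: held-out probabilities and AUCs."""

    spec: PipelineSpec
    loo_predictions: np.ndarray
    train_auc: float
    validation_auc: float
    fitted_model: Pipeline
    order: int = 0  # enumeration index, used for deterministic tie-breaks

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class (IDH wild-type) probability from the full-data fit."""
        proba = self.fitted_model.predict_proba(np.asarray(X, dtype=float))
        pos = list(self.fitted_model.classes_).index(1)
        return proba[:, pos]


def enumerate_pipelines(
    reducers: Sequence[str] = REDUCERS,
    selectors: Sequence[str] = SELECTORS,
    classifiers: Sequence[str] = CLASSIFIERS,
    n_selected: int = 5,
    seed: int = 0,
) -> list[PipelineSpec]:
    """The full reducer x selector x classifier cross-product, in a fixed order."""
    return [
        PipelineSpec(reducer=r, selector=s, classifier=c, n_selected=n_selected, seed=seed)
        for r, s, c in itertools.product(reducers, selectors, classifiers)
    ]


def _make_classifier(name: str, seed: int):
    if name == "logistic":
        return LogisticRegression(max_iter=2000)
    if name == "l1-logistic":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "linear-svm":
        return SVC(kernel="linear", probability=True, random_state=seed)
    raise ValueError(name)


def build_pipeline(spec: PipelineSpec) -> Pipeline:
    """Scaler -> reducer -> selector -> classifier, all refit per fold."""
    if spec.reducer == "pca":
        reducer = PCA(n_components=0.95, svd_solver="full", random_state=spec.seed)
    else:
        reducer = CorrelationFilter(threshold=0.85)
    clf = _make_classifier(spec.classifier, spec.seed)
    if spec.selector == "rfe":
        selector = CappedRFE(_make_classifier(spec.classifier, spec.seed), k=spec.n_selected)
    else:
        selector = TopKSelector(method=spec.selector, k=spec.n_selected)
    return Pipeline(
        [("scale", StandardScaler()), ("reduce", reducer), ("select", selector), ("clf", clf)]
    )


def _positive_proba(model: Pipeline, X) -> np.ndarray:
    proba = model.predict_proba(X)
    pos = list(model.named_steps["clf"].classes_).index(1)
    return proba[:, pos]


def run_loocv(features: FeatureMatrix, spec: PipelineSpec) -> PipelineResult:
    """Leave-one-out evaluation of one pipeline spec.

    Each subject's probability comes from a model fit on the other subjects
    only; training metrics come from the full-data fit.  Folds whose training
    set lacks a class are skipped with a warning (NaN prediction).
    """
    X, y = features.values, features.labels
    n = X.shape[0]
    preds = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            warnings.warn(f"fold {i} skipped: single-class training set")
            continue
        model = build_pipeline(spec)
        model.fit(X[mask], y[mask])
        preds[i] = _positive_proba(model, X[i : i + 1])[0]
    full = build_pipeline(spec)
    full.fit(X, y)
    train_auc = roc_auc(_positive_proba(full, X), y)
    ok = np.isfinite(preds)
    validation_auc = roc_auc(preds[ok], y[ok])
    return PipelineResult(
        spec=spec,
        loo_predictions=preds,
        train_auc=train_auc,
        validation_auc=validation_auc,
        fitted_model=full,
    )


def select_best_pipeline(results: Sequence[PipelineResult]) -> PipelineResult:
    """Highest validation AUC; ties go to fewer selected features, then order."""
    if not results:
        raise ValueError("no pipeline results to choose from")
    return min(
        results, key=lambda r: (-r.validation_auc, r.spec.n_selected, r.order)
    )


def run_pipeline_search(
    features: FeatureMatrix,
    specs: Sequence[PipelineSpec] | None = None,
    n_selected_grid: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[PipelineResult, list[PipelineResult]]:
    """Evaluate every spec (optionally sweeping n_selected) and pick the best.

    The default grid sweeps the number of retained features from 1 to
    min(p, 20); pass a smaller grid to trade resolution for runtime.
    """
    if specs is None:
        specs = enumerate_pipelines(seed=seed)
    if n_selected_grid is None:
        p = len(features.feature_names)
        n_selected_grid = range(1, min(p, 20) + 1)
    results: list[PipelineResult] = []
    order = 0
    for spec in specs:
        for k in n_selected_grid:
            res = run_loocv(features, dataclasses.replace(spec, n_selected=int(k)))
            res.order = order
            order += 1
            results.append(res)
    return select_best_pipeline(results), results


# ---------------------------------------------------------------------------
# HANDINESS


@dataclass(frozen=True)
class HandinessCoefficients:
    """Log-odds coefficients of the HANDINESS integrated prediction model."""

    beta_age: float = 0.03
    beta_necrosis: float = -0.65
    beta_hemorrhage: float = -0.54
    beta_location: float = 0.73
    beta_calcification: float = 1.65
    beta_hmri: float = 2.35
    beta_edema: float = 0.48
    intercept: float = -6.14
    cutoff: float = 0.38

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "age": self.beta_age,
                "necrosis": self.beta_necrosis,
                "hemorrhage": self.beta_hemorrhage,
                "location": self.beta_location,
                "calcification": self.beta_calcification,
                "hmri": self.beta_hmri,
                "edema": self.beta_edema,
                "intercept": self.intercept,
            }
        )


#: The published coefficient set, packaged as immutable reference constants.
STUDY_HANDINESS = HandinessCoefficients()

#: Covariates entering the HANDINESS linear predictor, in formula order.
HANDINESS_COVARIATES = (
    "age",
    "necrosis",
    "hemorrhage",
    "location",
    "calcification",
    "hmri",
    "edema",
)

#: Default numeric coding for the HANDINESS covariates (see module docstring).
HANDINESS_CODING: dict[str, dict[str, float]] = {
    "necrosis": CLINICAL_CODING["necrosis"],
    "hemorrhage": CLINICAL_CODING["hemorrhage"],
    "calcification": CLINICAL_CODING["calcification"],
    "edema": CLINICAL_CODING["edema"],
    "location": CLINICAL_CODING["location"],
}


def encode_handiness_covariates(
    record: ClinicalRecord, coding: Mapping[str, Mapping[str, float]] | None = None
) -> dict[str, float]:
    """Numeric covariate dict (without the H-MRI term) for one record."""
    coding = HANDINESS_CODING if coding is None else coding
    out = {"age": float(record.age)}
    for var in ("necrosis", "hemorrhage", "location", "calcification", "edema"):
        out[var] = float(coding[var][getattr(record, var)])
    return out


def handiness_logodds(
    record,
    hmri_prob: float,
    coeffs: HandinessCoefficients = STUDY_HANDINESS,
) -> float:
    """The HANDINESS linear predictor L for one subject.

    ``record`` may be a :class:`ClinicalRecord` or a pre-coded mapping with
    keys age, necrosis, hemorrhage, location, calcification, edema.
    """
    if isinstance(record, ClinicalRecord):
        cov = encode_handiness_covariates(record)
    else:
        cov = dict(record)
    missing = {"age", "necrosis", "hemorrhage", "location", "calcification", "edema"} - set(cov)
    if missing:
        raise ValueError(f"missing covariates: {sorted(missing)}")
    return float(
        coeffs.beta_age * cov["age"]
        + coeffs.beta_necrosis * cov["necrosis"]
        + coeffs.beta_hemorrhage * cov["hemorrhage"]
        + coeffs.beta_location * cov["location"]
        + coeffs.beta_calcification * cov["calcification"]
        + coeffs.beta_hmri * float(hmri_prob)
        + coeffs.beta_edema * cov["edema"]
        + coeffs.intercept
    )


def logodds_to_probability(L) -> float | np.ndarray:
    """Inverse logit 1 / (1 + e^-L), the probability of IDH wild-type."""
    from scipy.special import expit

    out = expit(np.asarray(L, dtype=float))
    return float(out) if np.isscalar(L) or np.ndim(L) == 0 else out


def youden_cutoff(probs, labels) -> float:
    """Observed probability maximizing sensitivity + specificity - 1.

    Positive calls are prob >= threshold; ties on the Youden index are broken
    toward the lowest qualifying threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    n1 = labels.sum()
    n0 = labels.size - n1
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(probs)):
        call = probs >= t
        sens = (call & (labels == 1)).sum() / n1
        spec = (~call & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j:  # strict: first (lowest) threshold wins ties
            best_j, best_t = j, float(t)
    return best_t


# ---------------------------------------------------------------------------
# The three models


@dataclass
class HandinessModel:
    """Fitted HANDINESS logistic model with its held-out probabilities."""

    coefficients: pd.Series
    loo_probabilities: np.ndarray
    validation_auc: float
    train_auc: float

    def predict_proba(self, record, hmri_prob: float) -> float:
        cov = (
            encode_handiness_covariates(record)
            if isinstance(record, ClinicalRecord)
            else dict(record)
        )
        x = np.array([cov[v] if v != "hmri" else float(hmri_prob) for v in HANDINESS_COVARIATES])
        L = float(self.coefficients[list(HANDINESS_COVARIATES)].to_numpy() @ x + self.coefficients["intercept"])
        return logodds_to_probability(L)


@dataclass
class ThreeModels:
    clinicrad: PipelineResult
    hmri: PipelineResult
    handiness: HandinessModel


def _handiness_design(records, hmri_probs) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for rec, h in zip(records, hmri_probs):
        cov = encode_handiness_covariates(rec)
        rows.append([cov[v] if v != "hmri" else float(h) for v in HANDINESS_COVARIATES])
    X = np.asarray(rows, dtype=float)
    y = np.array([1 if r.idh == "wildtype" else 0 for r in records])
    return X, y


def fit_three_models(
    habitat_features: FeatureMatrix,
    clinical: Sequence[ClinicalRecord],
    specs: Sequence[PipelineSpec] | None = None,
    n_selected_grid: Sequence[int] | None = None,
    seed: int = 0,
) -> ThreeModels:
    """Fit ClinicRad, H-MRI and HANDINESS on aligned subjects.

    The H-MRI probabilities entering HANDINESS are the held-out LOOCV values
    so no subject's label leaks into its own integrated prediction; the
    HANDINESS logistic itself is also scored by LOOCV (refit per fold on the
    fixed held-out H-MRI inputs).
    """
    ids = [r.subject_id for r in clinical]
    if ids != list(habitat_features.subject_ids):
        raise ValueError("clinical records and habitat features are misaligned")
    clinical_matrix = encode_clinical(clinical)
    if not np.array_equal(clinical_matrix.labels, habitat_features.labels):
        raise ValueError("IDH labels disagree between inputs")

    clinicrad, _ = run_pipeline_search(clinical_matrix, specs, n_selected_grid, seed=seed)
    hmri, _ = run_pipeline_search(habitat_features, specs, n_selected_grid, seed=seed)

    X, y = _handiness_design(clinical, hmri.loo_predictions)
    ok = np.isfinite(X).all(axis=1)
    lr = LogisticRegression(C=1e6, max_iter=5000)
    lr.fit(X[ok], y[ok])
    coef = pd.Series(lr.coef_[0], index=list(HANDINESS_COVARIATES))
    coef["intercept"] = float(lr.intercept_[0])
    train_probs = lr.predict_proba(X[ok])[:, list(lr.classes_).index(1)]

    loo = np.full(len(y), np.nan)
    for i in np.flatnonzero(ok):
        mask = ok.copy()
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            warnings.warn(f"fold {i} skipped: single-class training set")
            continue
        fold = LogisticRegression(C=1e6, max_iter=5000)
        fold.fit(X[mask], y[mask])
        loo[i] = fold.predict_proba(X[i : i + 1])[0, list(fold.classes_).index(1)]
    okp = np.isfinite(loo)
    handiness = HandinessModel(
        coefficients=coef,
        loo_probabilities=loo,
        validation_auc=roc_auc(loo[okp], y[okp]),
        train_auc=roc_auc(train_probs, y[ok]),
    )
    return ThreeModels(clinicrad=clinicrad, hmri=hmri, handiness=handiness)


# ---------------------------------------------------------------------------
# Coefficient-recovery simulation


def simulate_handiness_cohort(
    n: int, seed: int = 0, coeffs: HandinessCoefficients = STUDY_HANDINESS
) -> pd.DataFrame:
    """Draw a cohort from the HANDINESS formula itself.

    Covariates follow the reference cohort's marginal distributions (age
    normal around the pooled mean, binary signs at their pooled prevalences,
    location at its pooled category frequencies, H-MRI uniform on [0, 1]);
    outcomes are Bernoulli with probability expit(L).  Used for
    coefficient-recovery checks.
    """
    rng = np.random.default_rng(seed)
    age = rng.normal(52.0, 11.0, size=n)
    necrosis = rng.binomial(1, 75 / 103, size=n)
    hemorrhage = rng.binomial(1, 75 / 103, size=n)
    calcification = rng.binomial(1, 23 / 103, size=n)
    edema = rng.binomial(1, 58 / 103, size=n)
    location = rng.choice([0, 1, 2], p=np.array([53, 8, 42]) / 103.0, size=n)
    hmri = rng.uniform(0.0, 1.0, size=n)
    frame = pd.DataFrame(
        {
            "age": age,
            "necrosis": necrosis,
            "hemorrhage": hemorrhage,
            "location": location,
            "calcification": calcification,
            "hmri": hmri,
            "edema": edema,
        }
    )
    L = (
        coeffs.beta_age * age
        + coeffs.beta_necrosis * necrosis
        + coeffs.beta_hemorrhage * hemorrhage
        + coeffs.beta_location * location
        + coeffs.beta_calcification * calcification
        + coeffs.beta_hmri * hmri
        + coeffs.beta_edema * edema
        + coeffs.intercept
    )
    frame["idh_wildtype"] = rng.binomial(1, logodds_to_probability(L))
    return frame


def refit_handiness(frame: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Maximum-likelihood logistic refit of the HANDINESS linear predictor.

    Returns (coefficients, standard errors) indexed by covariate name plus
    ``intercept``.
    """
    import statsmodels.api as sm

    X = sm.add_constant(frame[list(HANDINESS_COVARIATES)])
    model = sm.Logit(frame["idh_wildtype"], X).fit(disp=0)
    params = model.params.rename({"const": "intercept"})
    bse = model.bse.rename({"const": "intercept"})
    return params, bse
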