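"""Model-assessment battery for binary probability models.

Discrimination (ROC AUC via the rank formulation, precision-recall AUC),
stratified bootstrap confidence intervals, confusion metrics reported as
fractions, the DeLong test for paired AUCs, integrated discrimination
improvement (IDI), net reclassification improvement (NRI), calibration with
the Brier score, and decision-curve analysis.  Labels are 0/1 with 1 the
positive class (IDH wild-type in this package's models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

__all__ = [
    "Fraction",
    "EvalReport",
    "ComparisonReport",
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "confusion_metrics",
    "delong_test",
    "idi",
    "nri",
    "calibration",
    "decision_curve",
    "evaluate_model",
    "compare_models",
]


def _check_scores_labels(scores, labels, require_both_classes=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1D arrays")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    labels = labels.astype(int)
    if require_both_classes and (labels.min() == labels.max()):
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Empirical AUC by the rank (Mann-Whitney) formulation, ties get 0.5 credit."""
    scores, labels = _check_scores_labels(scores, labels)
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve, traversed from the highest score."""
    scores, labels = _check_scores_labels(scores, labels, require_both_classes=False)
    if labels.sum() == 0:
        raise ValueError("need at least one positive")
    return float(average_precision_score(labels, scores))


def bootstrap_ci(
    scores,
    labels,
    metric=roc_auc,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Stratified percentile bootstrap interval for a score/label metric.

    Resampling is with replacement within each class, so every replicate
    keeps both classes.  Returns (point estimate, lower, upper).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores, labels = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    point = float(metric(scores, labels))
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=idx_pos.size, replace=True),
                rng.choice(idx_neg, size=idx_neg.size, replace=True),
            ]
        )
        reps[b] = metric(scores[take], labels[take])
    lower, upper = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return point, float(lower), float(upper)


@dataclass(frozen=True)
class Fraction:
    """A rate together with the counts it came from, e.g. 0.911 (51/56)."""

    value: float
    numerator: int
    denominator: int

    def __str__(self) -> str:
        return f"{self.value:.3f} ({self.numerator}/{self.denominator})"


def confusion_metrics(probs, labels, threshold: float) -> dict[str, Fraction]:
    """Sensitivity, specificity, PPV, NPV and accuracy at prob >= threshold."""
    probs, labels = _check_scores_labels(probs, labels)
    call = probs >= threshold
    tp = int((call & (labels == 1)).sum())
    fp = int((call & (labels == 0)).sum())
    fn = int((~call & (labels == 1)).sum())
    tn = int((~call & (labels == 0)).sum())

    def frac(num, den):
        return Fraction(num / den if den else np.nan, num, den)

    return {
        "sensitivity": frac(tp, tp + fn),
        "specificity": frac(tn, tn + fp),
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
        "accuracy": frac(tp + tn, labels.size),
    }


def _delong_structural_components(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)  # one per positive
    v01 = cmp.mean(axis=0)  # one per negative
    return cmp.mean(), v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong comparison of two correlated AUCs on the same subjects.

    Uses the structural-components covariance estimate; returns
    (auc_a, auc_b, two-sided p) from a normal reference for the AUC
    difference.  Identical scores give p = 1.
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, _ = _check_scores_labels(scores_b, labels)
    auc_a, v10_a, v01_a = _delong_structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def _discrimination_slope(probs, labels) -> float:
    return float(probs[labels == 1].mean() - probs[labels == 0].mean())


def idi(
    probs_new, probs_old, labels, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Integrated discrimination improvement with a stratified bootstrap CI.

    The difference between the discrimination slopes (mean probability in
    events minus non-events) of the new and old models.
    """
    probs_new, labels = _check_scores_labels(probs_new, labels)
    probs_old, _ = _check_scores_labels(probs_old, labels)

    def metric(paired, lab):
        return _discrimination_slope(paired[:, 0], lab) - _discrimination_slope(
            paired[:, 1], lab
        )

    return _paired_bootstrap(probs_new, probs_old, labels, metric, n_boot, seed)


def nri(
    probs_new, probs_old, labels, categories=None, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float, float]:
    """Net reclassification improvement with a stratified bootstrap CI.

    By default the continuous (category-free) NRI: any increase in predicted
    probability counts as upward movement.  With ``categories`` (interior cut
    points), movement means crossing a category boundary.  Range [-2, 2].
    """
    probs_new, labels = _check_scores_labels(probs_new, labels)
    probs_old, _ = _check_scores_labels(probs_old, labels)
    if categories is not None:
        cuts = np.asarray(categories, dtype=float)

    def metric(paired, lab):
        new, old = paired[:, 0], paired[:, 1]
        if categories is None:
            up = new > old
            down = new < old
        else:
            cat_new = np.searchsorted(cuts, new, side="right")
            cat_old = np.searchsorted(cuts, old, side="right")
            up = cat_new > cat_old
            down = cat_new < cat_old
        ev, ne = lab == 1, lab == 0
        return float(
            up[ev].mean() - down[ev].mean() + down[ne].mean() - up[ne].mean()
        )

    return _paired_bootstrap(probs_new, probs_old, labels, metric, n_boot, seed)


def _paired_bootstrap(probs_new, probs_old, labels, metric, n_boot, seed):
    paired = np.column_stack([probs_new, probs_old])
    point = metric(paired, labels)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=idx_pos.size, replace=True),
                rng.choice(idx_neg, size=idx_neg.size, replace=True),
            ]
        )
        reps[b] = metric(paired[take], labels[take])
    lower, upper = np.quantile(reps, [0.025, 0.975])
    return float(point), float(lower), float(upper)


def calibration(probs, labels, n_bins: int = 10) -> tuple[pd.DataFrame, float]:
    """Equal-frequency calibration bins and the Brier score.

    Returns a DataFrame of (mean_predicted, observed_rate, n) per decile bin
    (duplicate quantile edges merged) and Brier = mean (p - y)^2.
    """
    probs, labels = _check_scores_labels(probs, labels, require_both_classes=False)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    brier = float(np.mean((probs - labels) ** 2))
    bins = pd.qcut(probs, q=n_bins, duplicates="drop")
    frame = (
        pd.DataFrame({"prob": probs, "label": labels, "bin": bins})
        .groupby("bin", observed=True)
        .agg(mean_predicted=("prob", "mean"), observed_rate=("label", "mean"), n=("label", "size"))
        .reset_index(drop=True)
    )
    return frame, brier


def decision_curve(probs, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt) over threshold probabilities.

    Includes treat-all and treat-none reference policies.  Default grid is
    0.01 to 0.99 in steps of 0.01.
    """
    probs, labels = _check_scores_labels(probs, labels)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.995, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must be in (0, 1)")
    n = labels.size
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        call = probs >= pt
        tp = (call & (labels == 1)).sum() / n
        fp = (call & (labels == 0)).sum() / n
        odds = pt / (1.0 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp - fp * odds,
                "treat_all": prevalence - (1 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Full single-model assessment at one operating threshold."""

    auc: float
    auc_ci: tuple[float, float]
    pr_auc: float
    threshold: float
    sensitivity: Fraction
    specificity: Fraction
    ppv: Fraction
    npv: Fraction
    accuracy: Fraction
    brier: float
    calibration_bins: pd.DataFrame = field(repr=False)
    net_benefit: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        def frac(f: Fraction):
            return {"value": f.value, "numerator": f.numerator, "denominator": f.denominator}

        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "pr_auc": self.pr_auc,
            "threshold": self.threshold,
            "sensitivity": frac(self.sensitivity),
            "specificity": frac(self.specificity),
            "ppv": frac(self.ppv),
            "npv": frac(self.npv),
            "accuracy": frac(self.accuracy),
            "brier": self.brier,
            "calibration_bins": self.calibration_bins.to_dict(orient="records"),
            "net_benefit": self.net_benefit.to_dict(orient="records"),
        }


@dataclass
class ComparisonReport:
    """Pairwise model comparison: DeLong p, IDI and NRI with bootstrap CIs."""

    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    delong_p: float
    idi: tuple[float, float, float]
    nri: tuple[float, float, float]


def evaluate_model(
    probs,
    labels,
    threshold: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    n_calibration_bins: int = 10,
) -> EvalReport:
    """Assemble the full report; threshold defaults to the maximum-Youden cut."""
    probs, labels = _check_scores_labels(probs, labels)
    if threshold is None:
        from .model_pipeline import youden_cutoff

        threshold = youden_cutoff(probs, labels)
    auc, lo, hi = bootstrap_ci(probs, labels, roc_auc, n_boot=n_boot, seed=seed)
    conf = confusion_metrics(probs, labels, threshold)
    bins, brier = calibration(probs, labels, n_bins=n_calibration_bins)
    return EvalReport(
        auc=auc,
        auc_ci=(lo, hi),
        pr_auc=pr_auc(probs, labels),
        threshold=float(threshold),
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        ppv=conf["ppv"],
        npv=conf["npv"],
        accuracy=conf["accuracy"],
        brier=brier,
        calibration_bins=bins,
        net_benefit=decision_curve(probs, labels),
    )


def compare_models(
    probs_a, probs_b, labels, name_a: str = "A", name_b: str = "B", n_boot: int = 1000, seed: int = 0
) -> ComparisonReport:
    """DeLong + IDI + NRI comparison of two paired probability models."""
    auc_a, auc_b, p = delong_test(probs_a, probs_b, labels)
    return ComparisonReport(
        model_a=name_a,
        model_b=name_b,
        auc_a=auc_a,
        auc_b=auc_b,
        delong_p=p,
        idi=idi(probs_a, probs_b, labels, n_boot=n_boot, seed=seed),
        nri=nri(probs_a, probs_b, labels, n_boot=n_boot, seed=seed),
    )
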