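"""Pearson correlation structure of the 16 habitat features.

Absent subhabitats make some features missing for some subjects, so every
cell of the matrix is computed on pairwise-complete observations and carries
its own effective sample size.  Correlations with |r| above a cutoff
(default 0.6) are flagged "high"; non-significant cells are flagged "none".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "classify_high_correlations",
    "plot_heatmap",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson coefficients with per-cell p-values and sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return list(self.r.columns)

    def to_csv(self, path) -> None:
        self.r.to_csv(path)


def pearson_matrix(features, min_pairs: int = 3) -> CorrelationMatrix:
    """Product-moment correlation of every feature pair, pairwise complete.

    ``features`` is a subjects x features DataFrame or a list of
    :class:`~dkihabitat.habitat_mapping.HabitatFeatures`.  Cells with fewer
    than ``min_pairs`` complete observations, or with a zero-variance margin,
    are NaN (the latter with a warning).
    """
    if not isinstance(features, pd.DataFrame):
        from .habitat_mapping import features_to_frame

        features = features_to_frame(features)
    names = list(features.columns)
    k = len(names)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    cols = {name: features[name].to_numpy(dtype=float) for name in names}
    for i, a in enumerate(names):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, int(np.isfinite(cols[a]).sum())
        for j in range(i + 1, k):
            b = names[j]
            ok = np.isfinite(cols[a]) & np.isfinite(cols[b])
            n[i, j] = n[j, i] = int(ok.sum())
            if n[i, j] < min_pairs:
                continue
            xa, xb = cols[a][ok], cols[b][ok]
            if np.var(xa) == 0 or np.var(xb) == 0:
                warnings.warn(f"zero variance in pair ({a}, {b}); cell marked missing")
                continue
            res = stats.pearsonr(xa, xb)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    wrap = lambda m: pd.DataFrame(m, index=names, columns=names)
    return CorrelationMatrix(r=wrap(r), p=wrap(p), n_pairs=wrap(n))


def classify_high_correlations(
    matrix: CorrelationMatrix, cutoff: float = 0.6, alpha: float = 0.05
) -> pd.DataFrame:
    """Label each off-diagonal pair "high" (|r| > cutoff), "low" or "none".

    "none" marks cells that are missing or not significant at ``alpha``.
    The magnitude |r| is compared to the cutoff, so strong negative
    correlations are flagged high as well.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    names = matrix.feature_names
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            r = matrix.r.iat[i, j]
            p = matrix.p.iat[i, j]
            if not np.isfinite(r) or not np.isfinite(p) or p >= alpha:
                cls = "none"
            elif abs(r) > cutoff:
                cls = "high"
            else:
                cls = "low"
            rows.append(
                {
                    "feature_a": a,
                    "feature_b": b,
                    "r": r,
                    "p": p,
                    "n": int(matrix.n_pairs.iat[i, j]),
                    "class": cls,
                }
            )
    return pd.DataFrame(rows)


def plot_heatmap(matrix: CorrelationMatrix, path=None):
    """Render the correlation heatmap (optional figure export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = matrix.feature_names
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
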