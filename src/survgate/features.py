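"""Chi-square gene screening against the binary survival label, with BH-FDR.

The statistic is the machine-learning "frequency" chi-square computed on
continuous nonnegative expression (per-class sums as observed counts,
class-size-proportional expectations), not a binned contingency test — the
same definition as scikit-learn's ``chi2`` scorer, which is used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import chi2 as _sklearn_chi2
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass(frozen=True)
class FeatureScore:
    gene_id: str
    chi2: float
    p_value: float
    fdr: float = float("nan")


@dataclass
class FeatureSet:
    """Selected genes with scores and their 2-group assignment."""

    scores: list[FeatureScore]
    group_of: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [s.gene_id for s in self.scores]

    def genes_in_group(self, group: int) -> list[str]:
        """Genes of one group, in canonical (selection) order."""
        return [g for g in self.gene_ids if self.group_of.get(g) == group]

    def to_dict(self) -> dict:
        return {
            "scores": [
                {"gene_id": s.gene_id, "chi2": s.chi2, "p_value": s.p_value, "fdr": s.fdr}
                for s in self.scores
            ],
            "group_of": dict(self.group_of),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        scores = [FeatureScore(**row) for row in d["scores"]]
        return cls(scores, {k: int(v) for k, v in d["group_of"].items()})


def chi2_scores(expr: ExpressionMatrix, labels: np.ndarray) -> list[FeatureScore]:
    """Score every gene against a binary label by the frequency chi-square.

    For gene values x_i and class c: observed_c = sum of x_i in c,
    expected_c = (total sum) * n_c / n; the statistic is the usual
    sum (O-E)^2/E with 1 df for two classes.  Genes with total sum 0 get
    statistic 0 and p-value 1.  FDR is filled in by :func:`bh_adjust`.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be binary {0,1}")
    if len(labels) != expr.n_samples:
        raise ValueError("labels length does not match sample count")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    if np.any(expr.values < 0):
        raise ValueError("chi-square screening requires nonnegative values")

    X = expr.values.T  # samples x genes, as the scorer expects
    zero_sum = X.sum(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = _sklearn_chi2(X, labels)
    stat = np.where(zero_sum, 0.0, stat)
    p = np.where(zero_sum, 1.0, p)
    # a gene with equal per-class means yields stat 0 -> p must be 1, not nan
    stat = np.nan_to_num(stat, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    return [
        FeatureScore(g, float(stat[i]), float(p[i]), float(fdr[i]))
        for i, g in enumerate(expr.gene_ids)
    ]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order, clipped to [0,1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_features(
    scores: list[FeatureScore], fdr_threshold: float = 0.05
) -> list[FeatureScore]:
    """Keep genes with FDR strictly below the threshold.

    Deterministic order: descending chi-square, gene ID as tie-break.
    """
    kept = [s for s in scores if s.fdr < fdr_threshold]
    return sorted(kept, key=lambda s: (-s.chi2, s.gene_id))
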