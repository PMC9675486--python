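"""Composite signature scores and classification statistics.

A signature path turns into one number per sample: each gene is
centered on its step threshold and scaled ((x - t) / scale, scale = 3
log2 units by default so typical bimodal genes land near [-1, 1]), the
normalized values of a cluster's members are averaged, and the cluster
means are combined with the path's signed integer weights.  Scores are
evaluated with the Mann-Whitney ROC-AUC (ties count 1/2) and the
two-tailed Welch's t test, with Benjamini-Hochberg adjustment across
batches of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClassificationReport",
    "normalize_gene",
    "normalize_matrix",
    "composite_score",
    "ternary_composite_score",
    "roc_auc",
    "welch_t",
    "bh_adjust",
    "classification_report",
]

#: smallest p reported when a zero-variance comparison underflows
_P_FLOOR = 5e-324


@dataclass(frozen=True)
class ClassificationReport:
    """Two-class performance of a composite score."""

    roc_auc: float
    welch_t: float
    p_value: float
    n_case: int
    n_control: int


def normalize_gene(values, fit, scale: float = 3.0) -> np.ndarray:
    """Center one gene on its step threshold: z = (x - t) / scale.

    Degenerate fits (no step) normalize to all zeros; missing values
    stay NaN.
    """
    x = np.asarray(values, dtype=float)
    if fit.is_degenerate:
        z = np.zeros_like(x)
        z[~np.isfinite(x)] = np.nan
        return z
    return (x - fit.threshold) / scale


def normalize_matrix(matrix: pd.DataFrame, fits: pd.DataFrame, scale: float = 3.0) -> pd.DataFrame:
    """Threshold-center every gene of an expression matrix.

    ``fits`` is the per-gene table from :class:`~implinet.stepminer.TernaryMatrix`;
    genes without a usable fit (NaN threshold) or with a degenerate
    step normalize to zero.
    """
    thr = fits["threshold"].reindex(matrix.index)
    height = (fits["high_mean"] - fits["low_mean"]).reindex(matrix.index)
    z = matrix.sub(thr, axis=0).div(scale)
    flat = thr.isna() | (height == 0)
    z.loc[flat] = matrix.loc[flat].notna().astype(float) * 0.0
    z[matrix.isna()] = np.nan
    return z


def composite_score(
    path,
    matrix: pd.DataFrame,
    fits: pd.DataFrame,
    members_by_id: dict[str, list[str]],
    scale: float = 3.0,
) -> pd.Series:
    """Per-sample weighted sum of cluster-mean normalized expression.

    Missing genes are dropped from each cluster mean; a sample whose
    entire cluster is missing gets a NaN score (reported via warning).
    """
    z = normalize_matrix(matrix, fits, scale=scale)
    total = pd.Series(0.0, index=matrix.columns)
    valid = pd.Series(True, index=matrix.columns)
    for cid, weight in zip(path.cluster_ids, path.weights):
        members = [g for g in members_by_id[cid] if g in z.index]
        if not members:
            raise ValueError(f"cluster {cid} has no members present in the matrix")
        cluster_mean = z.loc[members].mean(axis=0, skipna=True)
        valid &= cluster_mean.notna()
        total = total + weight * cluster_mean.fillna(0.0)
    if not valid.all():
        dropped = list(valid[~valid].index)
        warnings.warn(
            f"{len(dropped)} sample(s) missing an entire cluster; scores set to NaN: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        total[~valid] = np.nan
    total.name = "composite_score"
    return total


def ternary_composite_score(
    path,
    ternary,
    members_by_id: dict[str, list[str]],
) -> pd.Series:
    """Composite score averaging ternary codes instead of continuous values.

    LOW maps to -1, HIGH to +1, INTERMEDIATE to 0; MISSING is dropped
    from the cluster mean.  Same weighting as :func:`composite_score`.
    """
    codes = ternary.codes.to_numpy(dtype=float)
    value = np.full_like(codes, np.nan)
    value[codes == 0] = -1.0  # LOW
    value[codes == 1] = 1.0   # HIGH
    value[codes == 2] = 0.0   # INTERMEDIATE
    z = pd.DataFrame(value, index=ternary.codes.index, columns=ternary.codes.columns)
    total = pd.Series(0.0, index=z.columns)
    for cid, weight in zip(path.cluster_ids, path.weights):
        members = [g for g in members_by_id[cid] if g in z.index]
        total = total + weight * z.loc[members].mean(axis=0, skipna=True).fillna(0.0)
    total.name = "composite_score"
    return total


def roc_auc(scores, labels) -> float:
    """Probability a random case outscores a random control (ties 1/2)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def welch_t(group1, group2) -> tuple[float, float]:
    """Two-tailed Welch's t test (unequal variances, Welch-Satterthwaite df).

    Degenerate inputs: two zero-variance groups with equal means give
    (0, 1); zero-variance groups with unequal means give an infinite t
    and a p clamped to the smallest positive float (flagged by a
    warning).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return (0.0, 1.0)
        warnings.warn("zero-variance groups with unequal means; p clamped", stacklevel=2)
        return (np.inf if np.mean(x) > np.mean(y) else -np.inf, _P_FLOOR)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    p = float(p)
    if p == 0.0:
        warnings.warn("Welch p underflowed; clamped to smallest positive float", stacklevel=2)
        p = _P_FLOOR
    return (float(t), p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a batch of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classification_report(
    scores: pd.Series, labels: pd.Series, case_label, control_label=None
) -> ClassificationReport:
    """ROC-AUC plus Welch's t of composite scores, case vs control.

    With ``control_label`` None every labeled non-case sample is a
    control (the multiclass display compares each class against a
    declared reference by repeated calls).
    """
    labels = labels.reindex(scores.index)
    if control_label is None:
        mask = labels.notna()
    else:
        mask = labels.isin([case_label, control_label])
    mask &= scores.notna()
    y = (labels[mask] == case_label).astype(int).to_numpy()
    s = scores[mask].to_numpy(dtype=float)
    auc = roc_auc(s, y)
    t, p = welch_t(s[y == 1], s[y == 0])
    return ClassificationReport(
        roc_auc=auc, welch_t=t, p_value=p, n_case=int(y.sum()), n_control=int((1 - y).sum())
    )
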