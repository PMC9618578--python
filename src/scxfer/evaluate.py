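"""Benchmark metrics, DEG scores, and the stratified stability harness.

Seven metrics summarize one prediction run: precision, recall, F1 and the
threshold-free AUROC / average-precision on the sensitive-class
probability, plus adjusted mutual information and adjusted Rand index
treating the true and predicted binary labels as two partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Callable, Optional

import numpy as np
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .matrix import ExpressionMatrix


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    auroc: float
    ap: float
    ami: float
    ari: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def classification_metrics(y_true, prob) -> MetricsReport:
    """Score binary predictions given per-sample sensitive probabilities.

    Threshold metrics use the 0.5 rule; AUROC/AP are NaN (with a warning)
    when ``y_true`` contains a single class.
    """
    y_true = np.asarray(y_true, dtype=int)
    prob = np.asarray(prob, dtype=float)
    if y_true.shape != prob.shape:
        raise ValueError("y_true and prob length mismatch")
    y_pred = (prob > 0.5).astype(int)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUROC and AP are undefined (NaN)")
        auroc = ap = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, prob))
        ap = float(average_precision_score(y_true, prob))
    return MetricsReport(
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        auroc=auroc,
        ap=ap,
        ami=float(adjusted_mutual_info_score(y_true, y_pred)),
        ari=float(adjusted_rand_score(y_true, y_pred)),
    )


def deg_score(
    X: ExpressionMatrix,
    group: np.ndarray,
    n_top: int = 50,
    seed: int = 0,
    adj_p_max: float = 0.05,
) -> np.ndarray:
    """Per-cell differential-program score for a cell group.

    Genes are ranked by the rank-sum z-score of group vs rest; the top
    ``n_top`` with Benjamini-Hochberg adjusted p < ``adj_p_max`` form the
    program.  Each cell's raw score is the mean expression of the program
    genes minus the mean of a size-matched randomly sampled reference gene
    set; scores are min-max scaled to [0, 1].
    """
    from scipy.stats import ranksums
    from statsmodels.stats.multitest import multipletests

    group = np.asarray(group, dtype=bool)
    if group.sum() < 3 or (~group).sum() < 3:
        raise ValueError("group and complement must each have >= 3 cells")
    rng = np.random.default_rng(seed)
    stats, pvals = ranksums(X.values[group], X.values[~group], axis=0)
    adj = multipletests(pvals, method="fdr_bh")[1]
    sig = np.flatnonzero(adj < adj_p_max)
    if len(sig) == 0:
        warnings.warn("no significant genes; score is constant 0")
        return np.zeros(X.n_samples)
    if len(sig) < n_top:
        warnings.warn(f"only {len(sig)} significant genes (< n_top={n_top}); using all")
    top = sig[np.argsort(-stats[sig], kind="stable")[:n_top]]
    ref = rng.choice(
        np.setdiff1d(np.arange(X.n_genes), top), size=len(top), replace=False
    )
    raw = X.values[:, top].mean(axis=1) - X.values[:, ref].mean(axis=1)
    span = raw.max() - raw.min()
    return (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)


def stability_test(
    pipeline: Callable[[ExpressionMatrix, np.ndarray], np.ndarray],
    X_s: ExpressionMatrix,
    y_true: np.ndarray,
    n_repeats: int = 20,
    frac: float = 0.80,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Metric dispersion over stratified subsamples.

    Draws ``n_repeats`` class-ratio-preserving subsamples of ``frac`` of the
    cells without replacement, calls ``pipeline(X_subset, y_subset)`` (which
    must return per-cell sensitive probabilities), and reports mean and
    standard deviation of every metric.
    """
    y_true = np.asarray(y_true, dtype=int)
    classes, counts = np.unique(y_true, return_counts=True)
    if (np.floor(frac * counts) < 1).any():
        raise ValueError("frac leaves a class empty in the subsample")
    rng = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []
    for _ in range(n_repeats):
        keep: list[np.ndarray] = []
        for c in classes:
            idx = np.flatnonzero(y_true == c)
            keep.append(rng.choice(idx, size=int(round(frac * len(idx))), replace=False))
        sel = np.sort(np.concatenate(keep))
        prob = pipeline(X_s.subset_samples(sel), y_true[sel])
        rows.append(classification_metrics(y_true[sel], prob).as_dict())
    out: dict[str, dict[str, float]] = {}
    for key in rows[0]:
        vals = np.array([r[key] for r in rows], dtype=float)
        out[key] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals))}
    return out
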