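"""Drug-response label construction, class rebalancing, and data splits.

The waterfall method binarizes per-cell-line dose-response AUC values:
cell lines are sorted by AUC in descending order; if the sorted curve is
near-linear (|Pearson r| between rank and AUC above 0.95) the cutoff is
the median AUC, otherwise it is the AUC at the knee — the point with the
largest perpendicular distance to the chord joining the highest- and
lowest-AUC points.  Lower AUC means stronger drug effect, so cell lines
at or below the cutoff are labelled sensitive (1) and the rest resistant
(0); the orientation can be flipped for datasets using the opposite
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix


class InsufficientDataError(ValueError):
    pass


class DegenerateCurveError(ValueError):
    pass


class ClassBalanceError(ValueError):
    pass


@dataclass
class WaterfallResult:
    cutoff: float
    regime: str  # "linear" | "nonlinear"
    pearson_r: float
    labels: dict[str, int] = field(default_factory=dict)


@dataclass
class SplitSpec:
    train_frac: float = 0.64
    val_frac: float = 0.16
    test_frac: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def waterfall_binarize(
    auc: list[tuple[str, float]],
    linear_r_threshold: float = 0.95,
    sensitive_low_auc: bool = True,
) -> WaterfallResult:
    """Binarize AUC values into sensitive (1) / resistant (0) labels.

    Parameters
    ----------
    auc
        ``(cell_line_id, auc)`` pairs; at least three lines with not all
        values identical.
    linear_r_threshold
        |Pearson r| between descending rank and AUC above which the sorted
        curve counts as linear and the median cutoff applies.
    sensitive_low_auc
        If True (default, the dose-response convention) AUC <= cutoff is
        sensitive; set False to flip.
    """
    ids = [str(c) for c, _ in auc]
    vals = np.array([float(v) for _, v in auc])
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate cell line ids")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite AUC values")
    if len(vals) < 3:
        raise InsufficientDataError("waterfall needs at least 3 cell lines")
    if np.ptp(vals) == 0:
        raise DegenerateCurveError("all AUC values identical; labels undefined")

    order = np.argsort(-vals, kind="stable")  # descending AUC
    y = vals[order]
    x = np.arange(len(y), dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])

    if abs(r) > linear_r_threshold:
        regime = "linear"
        cutoff = float(np.median(vals))
    else:
        regime = "nonlinear"
        # knee: max perpendicular distance to the chord between the first
        # (max AUC) and last (min AUC) sorted points
        p0 = np.array([x[0], y[0]])
        p1 = np.array([x[-1], y[-1]])
        chord = p1 - p0
        norm = np.hypot(*chord)
        pts = np.stack([x, y], axis=1) - p0
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
        cutoff = float(y[int(np.argmax(dist))])

    labels = {}
    for cid, v in zip(ids, vals):
        sens = v <= cutoff if sensitive_low_auc else v >= cutoff
        labels[cid] = int(sens)
    return WaterfallResult(cutoff=cutoff, regime=regime, pearson_r=r, labels=labels)


def _check_binary(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ClassBalanceError("rebalancing requires both classes present")
    if len(classes) > 2:
        raise ClassBalanceError("labels must be binary")
    return classes, counts


def rebalance(
    X: ExpressionMatrix,
    y: np.ndarray,
    method: str = "upsample",
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Equalize class counts by up-sampling, down-sampling, or SMOTE.

    Up-sampling duplicates minority rows uniformly at random; down-sampling
    discards majority rows uniformly at random; SMOTE synthesizes minority
    rows ``x + u * (x_nn - x)`` with ``u ~ U(0, 1)`` and ``x_nn`` one of the
    ``k_neighbors`` nearest minority neighbours (Euclidean).
    """
    y = np.asarray(y, dtype=int)
    if X.n_samples != len(y):
        raise ValueError("X and y length mismatch")
    classes, counts = _check_binary(y)
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    n_min, n_maj = len(min_idx), len(maj_idx)

    if method == "upsample":
        extra = rng.choice(min_idx, size=n_maj - n_min, replace=True)
        keep = np.concatenate([np.arange(len(y)), extra])
        return _take_rows(X, keep), y[keep]
    if method == "downsample":
        kept_maj = rng.choice(maj_idx, size=n_min, replace=False)
        keep = np.sort(np.concatenate([min_idx, kept_maj]))
        return _take_rows(X, keep), y[keep]
    if method == "smote":
        if n_min <= k_neighbors:
            raise ValueError(
                f"smote needs minority count > k_neighbors ({n_min} <= {k_neighbors})"
            )
        Xmin = X.values[min_idx]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
        _, nbrs = nn.kneighbors(Xmin)  # column 0 is the point itself
        n_new = n_maj - n_min
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(1, k_neighbors + 1, size=n_new)
        u = rng.random(n_new)
        x_base = Xmin[base]
        x_nn = Xmin[nbrs[base, pick]]
        synth = x_base + u[:, None] * (x_nn - x_base)
        new_ids = [f"smote_{i}" for i in range(n_new)]
        Xb = ExpressionMatrix(
            np.vstack([X.values, synth]),
            list(X.sample_ids) + new_ids,
            list(X.gene_ids),
            stage=X.stage,
            axis_kind=X.axis_kind,
        )
        return Xb, np.concatenate([y, np.full(n_new, minority)])
    raise ValueError(f"unknown rebalance method {method!r}")


def _take_rows(X: ExpressionMatrix, idx: np.ndarray) -> ExpressionMatrix:
    # duplicated rows need unique sample ids
    seen: dict[str, int] = {}
    ids = []
    for i in idx:
        s = X.sample_ids[i]
        if s in seen:
            seen[s] += 1
            ids.append(f"{s}.dup{seen[s]}")
        else:
            seen[s] = 0
            ids.append(s)
    return ExpressionMatrix(
        X.values[idx], ids, list(X.gene_ids), stage=X.stage, axis_kind=X.axis_kind
    )


def stratified_split(
    X: ExpressionMatrix, y: np.ndarray, spec: SplitSpec
) -> tuple[
    tuple[ExpressionMatrix, np.ndarray],
    tuple[ExpressionMatrix, np.ndarray],
    tuple[ExpressionMatrix, np.ndarray],
]:
    """Split into train/val/test (default 64/16/20) preserving class ratios.

    Falls back to an unstratified split (with a warning) when a class has
    fewer than 3 members.
    """
    import warnings

    y = np.asarray(y, dtype=int)
    idx = np.arange(len(y))
    _, counts = np.unique(y, return_counts=True)
    stratify = y if counts.min() >= 3 else None
    if stratify is None:
        warnings.warn("a class has <3 members; falling back to unstratified split")
    tr, rest = train_test_split(
        idx,
        train_size=spec.train_frac,
        random_state=spec.seed,
        stratify=stratify,
    )
    rel_val = spec.val_frac / (spec.val_frac + spec.test_frac)
    va, te = train_test_split(
        rest,
        train_size=rel_val,
        random_state=spec.seed,
        stratify=y[rest] if stratify is not None else None,
    )
    out = []
    for part in (tr, va, te):
        part = np.sort(part)
        out.append((_take_rows(X, part), y[part]))
    return tuple(out)
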