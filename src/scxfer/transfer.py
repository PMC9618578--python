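"""Domain-adaptive joint training of the bulk and single-cell models.

Training proceeds in four stages: (1) denoising-autoencoder pretraining on
the bulk training split, (2) supervised predictor training with best-epoch
selection on the validation split, (3) denoising-autoencoder pretraining on
the single-cell matrix, and (4) joint minimization of

    L = L_class(P(E_b(X_b)), y_b) + alpha * MMD(E_b(X_b), E_s(X_s))
        + beta * R(E_s(X_s), clusters)

where MMD is the (biased) squared maximum mean discrepancy under a
multi-bandwidth Gaussian RBF kernel and R is the negated sum over cell
clusters of the mean pairwise cosine similarity of their latent vectors
(so minimizing L compacts clusters).  All gradients are computed
analytically in NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph as ig
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix
from .networks import (
    ModelBundle,
    NetConfig,
    build_bundle,
    classification_loss,
    corrupt,
    predict_bulk,
)
from .nn import MLP, Adam, softmax


@dataclass
class KernelSpec:
    """Gaussian-RBF kernel bank for MMD.

    ``bandwidths`` is either an explicit list of sigma values or the string
    ``"median"`` meaning the median pairwise-distance heuristic scaled by
    ``median_factors``.
    """

    bandwidths: Sequence[float] | str = "median"
    median_factors: Sequence[float] = (0.5, 1.0, 2.0, 4.0)

    def resolve(self, Z_b: np.ndarray, Z_s: np.ndarray) -> np.ndarray:
        if isinstance(self.bandwidths, str):
            Z = np.vstack([Z_b, Z_s])
            d = cdist(Z, Z)
            med = np.median(d[np.triu_indices_from(d, k=1)])
            if med <= 0:
                med = 1.0
            bws = np.asarray(self.median_factors) * med
        else:
            bws = np.asarray(list(self.bandwidths), dtype=float)
        if len(bws) == 0 or np.any(bws <= 0):
            raise ValueError("kernel bandwidths must be positive")
        return bws


@dataclass
class LossWeights:
    alpha: float = 0.25  # MMD weight
    beta: float = 0.1  # cluster-regularizer weight

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("loss weights must be finite")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class ClusterLabels:
    assignment: dict[str, int]
    n_clusters: int

    def codes_for(self, cell_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[c] for c in cell_ids], dtype=int)


@dataclass
class TrainSchedule:
    pretrain_epochs: int = 200
    dann_epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 200


# ---------------------------------------------------------------------------
# MMD


def mmd(Z_b: np.ndarray, Z_s: np.ndarray, kernel: KernelSpec | None = None) -> float:
    """Biased squared MMD estimate summed over kernel bandwidths."""
    value, _, _ = _mmd_with_grads(Z_b, Z_s, kernel or KernelSpec(), want_grads=False)
    return value


def _mmd_with_grads(
    Z_b: np.ndarray,
    Z_s: np.ndarray,
    kernel: KernelSpec,
    want_grads: bool = True,
) -> tuple[float, Optional[np.ndarray], Optional[np.ndarray]]:
    Z_b = np.asarray(Z_b, dtype=float)
    Z_s = np.asarray(Z_s, dtype=float)
    if Z_b.ndim != 2 or Z_s.ndim != 2 or Z_b.shape[1] != Z_s.shape[1]:
        raise ValueError(
            f"latent dimension mismatch: {Z_b.shape} vs {Z_s.shape}"
        )
    n, m = len(Z_b), len(Z_s)
    bws = kernel.resolve(Z_b, Z_s)
    Dbb = cdist(Z_b, Z_b, "sqeuclidean")
    Dss = cdist(Z_s, Z_s, "sqeuclidean")
    Dbs = cdist(Z_b, Z_s, "sqeuclidean")
    total = 0.0
    gb = np.zeros_like(Z_b) if want_grads else None
    gs = np.zeros_like(Z_s) if want_grads else None
    for sigma in bws:
        s2 = 2.0 * sigma**2
        Kbb = np.exp(-Dbb / s2)
        Kss = np.exp(-Dss / s2)
        Kbs = np.exp(-Dbs / s2)
        total += Kbb.mean() + Kss.mean() - 2.0 * Kbs.mean()
        if want_grads:
            c = 2.0 / s2  # from d/dx exp(-||x-y||^2 / s2) = -(2/s2)(x-y) k
            # d mean(Kbb) / d Z_b[i] = (2/n^2) sum_j -(2/s2)(b_i-b_j) k_ij
            gb += -(c / n**2) * 2.0 * (Z_b * Kbb.sum(1)[:, None] - Kbb @ Z_b)
            gs += -(c / m**2) * 2.0 * (Z_s * Kss.sum(1)[:, None] - Kss @ Z_s)
            # cross term -2 mean(Kbs)
            gb += (c * 2.0 / (n * m)) * (Z_b * Kbs.sum(1)[:, None] - Kbs @ Z_s)
            gs += (c * 2.0 / (n * m)) * (Z_s * Kbs.sum(0)[:, None] - Kbs.T @ Z_b)
    return float(total), gb, gs


# ---------------------------------------------------------------------------
# clustering and the cluster regularizer


def cluster_cells(
    X_s: ExpressionMatrix,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 50,
    labels: Optional[dict[str, int]] = None,
) -> ClusterLabels:
    """Louvain community detection on a kNN graph in PCA space.

    User-supplied ``labels`` are passed through verbatim.  The graph is
    built with Euclidean k-nearest neighbours on up to ``n_pcs`` principal
    components; Louvain (igraph multilevel) runs with a seeded RNG so the
    assignment is deterministic for a given seed.
    """
    if labels is not None:
        missing = [c for c in X_s.sample_ids if c not in labels]
        if missing:
            raise ValueError(f"user labels missing for {len(missing)} cells")
        out = {c: int(labels[c]) for c in X_s.sample_ids}
        return ClusterLabels(out, n_clusters=len(set(out.values())))
    n = X_s.n_samples
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}")
    k = min(n_pcs, n - 1, X_s.n_genes)
    Z = PCA(n_components=k, random_state=seed).fit_transform(X_s.values)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(Z)
    dist, nbrs = nn.kneighbors(Z)
    edges, weights = [], []
    sigma = np.maximum(dist[:, -1], 1e-12)
    for i in range(n):
        for j_pos in range(1, n_neighbors + 1):
            j = nbrs[i, j_pos]
            edges.append((i, int(j)))
            weights.append(float(np.exp(-(dist[i, j_pos] ** 2) / (sigma[i] ** 2))))
    g = ig.Graph(n=n, edges=edges, edge_attrs={"weight": weights}, directed=False)
    g.simplify(combine_edges="max")
    import random as _random

    ig.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    ig.set_random_number_generator(_random)  # restore default
    assignment = {c: int(m) for c, m in zip(X_s.sample_ids, part.membership)}
    return ClusterLabels(assignment, n_clusters=len(part))


def cluster_regularizer(
    Z_s: np.ndarray, clusters: ClusterLabels, cell_ids: Sequence[str]
) -> float:
    value, _ = _regularizer_with_grad(Z_s, clusters.codes_for(cell_ids), want_grad=False)
    return value


def _regularizer_with_grad(
    Z_s: np.ndarray, codes: np.ndarray, want_grad: bool = True
) -> tuple[float, Optional[np.ndarray]]:
    """Negated sum over clusters of mean pairwise cosine similarity.

    Size-1 clusters contribute 0; zero-norm latents are treated as
    orthogonal via an epsilon-guarded norm.
    """
    Z_s = np.asarray(Z_s, dtype=float)
    eps = 1e-12
    total = 0.0
    grad = np.zeros_like(Z_s) if want_grad else None
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        s = len(idx)
        if s < 2:
            continue
        Z = Z_s[idx]
        norms = np.maximum(np.linalg.norm(Z, axis=1), eps)
        U = Z / norms[:, None]
        C = U @ U.T
        pair_sum = (C.sum() - np.trace(C)) / 2.0
        n_pairs = s * (s - 1) / 2.0
        total -= pair_sum / n_pairs
        if want_grad:
            # d/dz_i sum_{j != i} cos_ij = ((sum_j u_j - u_i) - (row_i - 1) u_i)/|z_i|
            row = C.sum(1) - 1.0  # sum_{j != i} cos_ij
            dZ = (U.sum(0)[None, :] - U - row[:, None] * U) / norms[:, None]
            grad[idx] -= dZ / n_pairs
    return float(total), grad


# ---------------------------------------------------------------------------
# joint loss (diagnostic entry point)


def joint_loss(
    bundle: ModelBundle,
    X_b: np.ndarray,
    y_b: np.ndarray,
    X_s: np.ndarray,
    clusters: ClusterLabels,
    cell_ids: Sequence[str],
    weights: LossWeights,
    kernel: KernelSpec | None = None,
) -> tuple[float, dict[str, float]]:
    """Evaluate the combined objective and its components (no training)."""
    kernel = kernel or KernelSpec()
    Z_b = bundle.E_b.forward(np.asarray(X_b, dtype=float))
    Z_s = bundle.E_s.forward(np.asarray(X_s, dtype=float))
    probs = softmax(bundle.P.forward(Z_b))
    l_class = classification_loss(probs, y_b)
    l_mmd = mmd(Z_b, Z_s, kernel)
    l_reg, _ = _regularizer_with_grad(Z_s, clusters.codes_for(cell_ids), want_grad=False)
    components = {
        "loss_class": l_class,
        "loss_mmd": l_mmd,
        "loss_reg": l_reg,
        "total": l_class + weights.alpha * l_mmd + weights.beta * l_reg,
    }
    for name, v in components.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component {name}")
    return components["total"], components


# ---------------------------------------------------------------------------
# training orchestration


def _pretrain_dae(
    E: MLP,
    D: MLP,
    X: np.ndarray,
    p: float,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
) -> list[float]:
    opt = Adam([E, D], lr=lr)
    n = len(X)
    log = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = X[idx]
            Xc = corrupt(Xb, p, rng=rng)
            Z = E.forward(Xc, train=True)
            R = D.forward(Z, train=True)
            diff = R - Xb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite reconstruction loss")
            opt.zero_grad()
            E.backward(D.backward(2.0 * diff / diff.size))
            opt.step()
            ep_loss += loss * len(idx)
        log.append(ep_loss / n)
    return log


def _train_predictor(
    E_b: MLP,
    P: MLP,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    from sklearn.metrics import f1_score

    opt = Adam([E_b, P], lr=lr)
    n = len(X_tr)
    best = (-1.0, None, None)
    log = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Z = E_b.forward(X_tr[idx], train=True)
            logits = P.forward(Z, train=True)
            probs = softmax(logits)
            loss = classification_loss(probs, y_tr[idx])
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(idx)), y_tr[idx]] = 1.0
            opt.zero_grad()
            E_b.backward(P.backward((probs - onehot) / len(idx)))
            opt.step()
            ep_loss += loss * len(idx)
        val_prob = predict_bulk(E_b, P, X_val)
        val_f1 = f1_score(y_val, (val_prob[:, 1] > 0.5).astype(int), zero_division=0)
        log.append({"loss_class": ep_loss / n, "val_f1": float(val_f1)})
        if val_f1 > best[0]:
            best = (val_f1, E_b.get_weights(), P.get_weights())
    if best[1] is not None:  # early selection on the validation split
        E_b.set_weights(best[1])
        P.set_weights(best[2])
    return log


def fit(
    bulk: tuple[ExpressionMatrix, np.ndarray],
    sc: ExpressionMatrix,
    config: NetConfig,
    weights: LossWeights | None = None,
    kernel: KernelSpec | None = None,
    schedule: TrainSchedule | None = None,
    seed: int = 0,
    clusters: Optional[ClusterLabels] = None,
    val: Optional[tuple[ExpressionMatrix, np.ndarray]] = None,
) -> tuple[ModelBundle, list[dict[str, float]]]:
    """Run the four training stages and return (bundle, per-epoch log).

    ``bulk`` is the rebalanced, label-binarized training split; ``val`` the
    validation split used for predictor best-epoch selection (falls back to
    the training data when absent).  ``clusters`` defaults to Louvain
    clustering of ``sc`` computed once before training.
    """
    weights = weights or LossWeights()
    kernel = kernel or KernelSpec()
    schedule = schedule or TrainSchedule()
    X_btr, y_btr = bulk
    Xb = np.asarray(X_btr.values, dtype=float)
    yb = np.asarray(y_btr, dtype=int)
    if len(np.unique(yb)) < 2:
        raise ValueError("bulk training labels contain a single class")
    Xs = np.asarray(sc.values, dtype=float)
    if clusters is None:
        clusters = cluster_cells(sc, seed=seed)
    codes_all = clusters.codes_for(sc.sample_ids)

    bundle = build_bundle(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    log: list[dict[str, float]] = []

    # Step 1: bulk DAE pretraining
    for i, l in enumerate(
        _pretrain_dae(
            bundle.E_b, bundle.D_b, Xb, config.noise_prob_bulk,
            schedule.pretrain_epochs, schedule.learning_rate, schedule.batch_size, rng,
        )
    ):
        log.append({"stage": 1, "epoch": i, "loss_recon_bulk": l})

    # Step 2: predictor training with validation-based selection
    if val is not None:
        Xv, yv = np.asarray(val[0].values, dtype=float), np.asarray(val[1], dtype=int)
    else:
        Xv, yv = Xb, yb
    for i, rec in enumerate(
        _train_predictor(
            bundle.E_b, bundle.P, Xb, yb, Xv, yv,
            schedule.pretrain_epochs, schedule.learning_rate, schedule.batch_size, rng,
        )
    ):
        log.append({"stage": 2, "epoch": i, **rec})

    # Step 3: single-cell DAE pretraining.  E_s/D_s start from the trained
    # bulk weights so the class orientation of the latent space is inherited
    # and MMD alignment only has to bridge the domain shift (unsupervised
    # marginal alignment from a random start can match distributions with
    # the classes swapped).
    bundle.E_s.set_weights(bundle.E_b.get_weights())
    bundle.D_s.set_weights(bundle.D_b.get_weights())
    for i, l in enumerate(
        _pretrain_dae(
            bundle.E_s, bundle.D_s, Xs, config.noise_prob_sc,
            schedule.pretrain_epochs, schedule.learning_rate, schedule.batch_size, rng,
        )
    ):
        log.append({"stage": 3, "epoch": i, "loss_recon_sc": l})

    # Step 4: joint DaNN training
    opt = Adam([bundle.E_b, bundle.E_s, bundle.P], lr=schedule.learning_rate)
    n, m = len(Xb), len(Xs)
    bs = schedule.batch_size
    steps = max(1, int(np.ceil(max(n, m) / bs)))
    last_good: Optional[list[list[np.ndarray]]] = None
    for epoch in range(schedule.dann_epochs):
        ep = {"loss_class": 0.0, "loss_mmd": 0.0, "loss_reg": 0.0}
        try:
            for _ in range(steps):
                bi = rng.choice(n, size=min(bs, n), replace=False)
                si = rng.choice(m, size=min(bs, m), replace=False)
                Xb_b, yb_b = Xb[bi], yb[bi]
                Xs_b = Xs[si]
                Z_b = bundle.E_b.forward(Xb_b, train=True)
                Z_s = bundle.E_s.forward(Xs_b, train=True)
                logits = bundle.P.forward(Z_b, train=True)
                probs = softmax(logits)
                l_class = classification_loss(probs, yb_b)
                l_mmd, g_zb_mmd, g_zs_mmd = _mmd_with_grads(Z_b, Z_s, kernel)
                l_reg, g_zs_reg = _regularizer_with_grad(Z_s, codes_all[si])
                for nm, v in (("class", l_class), ("mmd", l_mmd), ("reg", l_reg)):
                    if not np.isfinite(v):
                        raise FloatingPointError(f"non-finite loss_{nm} at epoch {epoch}")
                onehot = np.zeros_like(probs)
                onehot[np.arange(len(bi)), yb_b] = 1.0
                opt.zero_grad()
                dZ_b = bundle.P.backward((probs - onehot) / len(bi))
                dZ_b = dZ_b + weights.alpha * g_zb_mmd
                bundle.E_b.backward(dZ_b)
                dZ_s = weights.alpha * g_zs_mmd + weights.beta * g_zs_reg
                bundle.E_s.backward(dZ_s)
                opt.step()
                ep["loss_class"] += l_class / steps
                ep["loss_mmd"] += l_mmd / steps
                ep["loss_reg"] += l_reg / steps
        except FloatingPointError:
            if last_good is not None:
                for model, w in zip(bundle.all_models(), last_good):
                    model.set_weights(w)
            break
        ep["total"] = (
            ep["loss_class"] + weights.alpha * ep["loss_mmd"] + weights.beta * ep["loss_reg"]
        )
        log.append({"stage": 4, "epoch": epoch, **ep})
        last_good = [model.get_weights() for model in bundle.all_models()]
    return bundle, log
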