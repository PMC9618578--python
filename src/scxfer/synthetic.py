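"""Paired bulk / single-cell simulator with planted drug-response truth.

The generator emulates the structure the transfer model relies on:

* a shared *sensitivity program* — ``n_sig`` genes up-regulated and
  ``n_sig`` genes down-regulated with increasing drug sensitivity — present
  in both compartments;
* bulk cell lines spanning a continuum of sensitivity ``t in (0, 1)`` whose
  dose-response AUC is a monotone decreasing function of ``t`` (lower AUC =
  more sensitive), shaped either near-linear or with a knee so both
  waterfall regimes are exercised;
* single cells drawn from discrete treatment-condition clusters (at least
  two per response class, mimicking DMSO / treated / resistant conditions),
  with cluster-specific expression offsets;
* a systematic bulk-to-single-cell domain shift (per-gene offsets in
  log-rate plus a global compartment scale factor);
* dropout-style sparsity with expression-dependent zeroing on top of
  Poisson counting noise.

Bulk profiles are continuous log-normal intensities (already-normalized
microarray style); single-cell matrices are raw counts suitable for the
QC/normalization recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import DrugResponseTable, ExpressionMatrix
from .transfer import ClusterLabels

import pandas as pd


@dataclass
class SyntheticTruth:
    signature_genes_sensitive: list[str]
    signature_genes_resistant: list[str]
    bulk_labels: np.ndarray
    sc_labels: np.ndarray
    sc_clusters: ClusterLabels
    auc: dict[str, float]
    shift: np.ndarray
    bulk_latent: np.ndarray = field(default=None)
    sc_latent: np.ndarray = field(default=None)


def generate(
    n_lines: int = 1000,
    n_cells: int = 1000,
    n_genes: int = 2000,
    n_sig: int = 50,
    effect: float = 1.0,
    shift_scale: float = 0.5,
    dropout_rate: float = 0.2,
    knee: bool = False,
    n_clusters_per_class: int = 2,
    n_mito: int | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, DrugResponseTable, ExpressionMatrix, SyntheticTruth]:
    """Simulate a paired bulk + single-cell drug-response dataset.

    Parameters
    ----------
    effect
        Signature effect size in log-rate units; a cell at full sensitivity
        shifts sensitive-program genes up by ``effect`` and the resistant
        program down by ``effect`` (and vice versa).
    shift_scale
        Magnitude of the bulk-to-single-cell domain shift (standard
        deviation of the per-gene log-rate offset).
    dropout_rate
        Ceiling of the expression-dependent dropout probability.
    knee
        When True, the sorted AUC curve has a knee (nonlinear waterfall
        regime); otherwise it is near-linear (median regime).
    """
    if 2 * n_sig >= n_genes:
        raise ValueError("need 2*n_sig < n_genes")
    if n_mito is None:
        n_mito = max(4, round(0.01 * n_genes))  # ~1% mito content
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:05d}" for i in range(n_genes - n_mito)] + [
        f"MT-{i}" for i in range(n_mito)
    ]
    # signatures never include mitochondrial genes
    sig_pool = rng.permutation(n_genes - n_mito)
    sens_idx = np.sort(sig_pool[:n_sig])
    res_idx = np.sort(sig_pool[n_sig : 2 * n_sig])
    mu = rng.normal(1.0, 0.5, size=n_genes)  # baseline log-rate per gene

    def signal(t: np.ndarray) -> np.ndarray:
        """Per-sample signature shift in log-rate space; t in (0,1)."""
        s = np.zeros((len(t), n_genes))
        s[:, sens_idx] = effect * (2 * t - 1)[:, None]
        s[:, res_idx] = -effect * (2 * t - 1)[:, None]
        return s

    # ---- bulk compartment: continuum of sensitivity -----------------------
    t_b = rng.uniform(0.0, 1.0, size=n_lines)
    log_bulk = mu[None, :] + signal(t_b) + rng.normal(0, 0.2, size=(n_lines, n_genes))
    bulk_vals = np.exp(log_bulk)
    line_ids = [f"line{i:04d}" for i in range(n_lines)]
    bulk = ExpressionMatrix(
        bulk_vals, line_ids, gene_ids, stage="raw", axis_kind="bulk_cell_lines"
    )

    knee_t = 0.75
    if knee:
        # plateau then steep drop: knee near the 75th percentile of t
        auc_vals = np.where(
            t_b <= knee_t,
            0.85 - 0.067 * t_b,
            0.80 - 2.4 * (t_b - knee_t),
        )
        auc_vals = auc_vals + rng.normal(0, 0.004, size=n_lines)
        bulk_labels = (t_b > knee_t).astype(int)
    else:
        auc_vals = 0.2 + 0.6 * (1.0 - t_b) + rng.normal(0, 0.01, size=n_lines)
        bulk_labels = (t_b > 0.5).astype(int)
    auc_vals = np.clip(auc_vals, 1e-3, None)
    response = DrugResponseTable(
        pd.DataFrame(
            {"cell_line_id": line_ids, "drug_id": "drugA", "auc": auc_vals}
        )
    )

    # ---- single-cell compartment: condition clusters ----------------------
    n_clust = 2 * n_clusters_per_class
    clust_of_cell = rng.integers(0, n_clust, size=n_cells)
    # clusters 0..k-1 sensitive (high t), k..2k-1 resistant (low t)
    t_centers = np.concatenate(
        [
            rng.uniform(0.75, 0.9, size=n_clusters_per_class),
            rng.uniform(0.1, 0.25, size=n_clusters_per_class),
        ]
    )
    sc_labels = (clust_of_cell < n_clusters_per_class).astype(int)
    t_s = np.clip(t_centers[clust_of_cell] + rng.normal(0, 0.05, size=n_cells), 0, 1)
    # cluster-specific offsets on a random subset of non-signature genes
    clust_offsets = np.zeros((n_clust, n_genes))
    bg = np.setdiff1d(np.arange(n_genes - n_mito), np.concatenate([sens_idx, res_idx]))
    for k in range(n_clust):
        genes_k = rng.choice(bg, size=min(100, len(bg)), replace=False)
        clust_offsets[k, genes_k] = rng.normal(0, 0.5, size=len(genes_k))

    shift = rng.normal(0, 1.0, size=n_genes) * shift_scale
    log_sc = (
        mu[None, :]
        + signal(t_s)
        + clust_offsets[clust_of_cell]
        + shift[None, :]
        + 0.1 * shift_scale  # compartment-level scale factor (log space)
    )
    rate = np.exp(log_sc)
    counts = rng.poisson(rate).astype(float)
    if dropout_rate > 0:
        p_drop = dropout_rate * np.exp(-rate / 2.0)
        counts *= rng.random(counts.shape) >= p_drop
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    sc = ExpressionMatrix(counts, cell_ids, gene_ids, stage="raw", axis_kind="single_cells")

    truth = SyntheticTruth(
        signature_genes_sensitive=[gene_ids[i] for i in sens_idx],
        signature_genes_resistant=[gene_ids[i] for i in res_idx],
        bulk_labels=bulk_labels,
        sc_labels=sc_labels,
        sc_clusters=ClusterLabels(
            {c: int(k) for c, k in zip(cell_ids, clust_of_cell)}, n_clusters=n_clust
        ),
        auc={c: float(a) for c, a in zip(line_ids, auc_vals)},
        shift=shift,
        bulk_latent=t_b,
        sc_latent=t_s,
    )
    return bulk, response, sc, truth
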