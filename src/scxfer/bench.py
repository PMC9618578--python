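"""Desk-scale synthetic benchmark: one call runs the whole workflow.

The benchmark generates a paired bulk/single-cell dataset with planted
ground truth, runs the five-stage pipeline, and scores the result against
the truth.  Sizes and schedule are chosen so a run completes in a few
seconds on one CPU while keeping every qualitative property of the full
problem (shared signature, domain shift, cluster structure, dropout); see
docs/methods.md for the rationale behind these sizes.
"""

from __future__ import annotations

import numpy as np

from .evaluate import classification_metrics
from .networks import NetConfig
from .pipeline import RunConfig, run_pipeline
from .synthetic import generate
from .transfer import LossWeights, TrainSchedule, _regularizer_with_grad

DESK_SIZES = dict(n_lines=400, n_cells=400, n_genes=600, n_sig=30)
DESK_NET = dict(encoder_hidden=[128, 64], bottleneck_dim=32, predictor_hidden=[32, 16])
DESK_SCHEDULE = dict(pretrain_epochs=30, dann_epochs=60, learning_rate=1e-3, batch_size=128)


def within_cluster_cohesion(Z: np.ndarray, codes: np.ndarray) -> float:
    """Mean over clusters of the mean pairwise cosine similarity of latents."""
    reg, _ = _regularizer_with_grad(Z, codes, want_grad=False)
    n_eff = sum(1 for c in np.unique(codes) if (codes == c).sum() >= 2)
    return -reg / max(1, n_eff)


def run_desk_benchmark(
    seed: int,
    shift_scale: float = 0.5,
    alpha: float = 0.25,
    beta: float = 0.1,
    knee: bool = False,
    interpretation: bool = True,
    sizes: dict | None = None,
) -> dict:
    """Generate -> label -> train -> transfer -> score, against planted truth.

    Returns a dict with the seven single-cell metrics (vs planted labels),
    the bulk held-out metrics (vs waterfall labels), within-cluster latent
    cohesion, the sensitive-signature recovery fraction of the critical-gene
    table (when ``interpretation``), and the raw pipeline artifacts.
    """
    sizes = dict(sizes or DESK_SIZES)
    bulk, response, sc, truth = generate(
        shift_scale=shift_scale, knee=knee, seed=seed, **sizes
    )
    cfg = RunConfig(
        net_overrides=dict(DESK_NET),
        weights=LossWeights(alpha=alpha, beta=beta),
        schedule=TrainSchedule(**DESK_SCHEDULE),
        run_interpretation=interpretation,
        seed=seed,
    )
    arts = run_pipeline(bulk, response, sc, cfg)

    truth_map = dict(zip(sc.sample_ids, truth.sc_labels))
    kept = arts["sc_scaled"].sample_ids
    y_true = np.array([truth_map[c] for c in kept])
    sc_metrics = classification_metrics(y_true, arts["predictions"].prob_sensitive)

    Z = arts["bundle"].E_s.forward(arts["sc_scaled"].values)
    codes = arts["clusters"].codes_for(kept)
    cohesion = within_cluster_cohesion(Z, codes)

    recovery = None
    if interpretation and arts["critical_genes"] is not None:
        cg = arts["critical_genes"]
        sens_called = set(cg.loc[cg["direction"] == "sensitive", "gene_id"])
        planted = set(truth.signature_genes_sensitive)
        recovery = len(sens_called & planted) / len(planted)

    return {
        "sc_metrics": sc_metrics,
        "bulk_metrics": arts["bulk_test_metrics"],
        "cohesion": cohesion,
        "sensitive_signature_recovery": recovery,
        "y_true_sc": y_true,
        "truth": truth,
        "artifacts": arts,
    }
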