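"""End-to-end orchestration: label -> train -> predict -> interpret -> evaluate.

`run_pipeline` wires the individual stages together for the CLI and for
programmatic use.  A single global seed fans out into deterministic
per-stage seeds (stable hash of stage name + seed) so any stage can be
rerun in isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._version import __version__
from .bulk import SplitSpec, rebalance, stratified_split, waterfall_binarize
from .evaluate import classification_metrics
from .interpret import integrated_gradients, predict_sc, save_ig_h5ad, select_critical_genes
from .io import align_gene_spaces, qc_and_normalize_sc, scale_bulk
from .matrix import DrugResponseTable, ExpressionMatrix
from .networks import NetConfig, save_bundle
from .transfer import KernelSpec, LossWeights, TrainSchedule, cluster_cells, fit


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """All knobs of the five-stage pipeline in one validated bundle."""

    net: Optional[NetConfig] = None
    net_overrides: dict = field(default_factory=dict)
    weights: LossWeights = field(default_factory=LossWeights)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    split: SplitSpec = field(default_factory=SplitSpec)
    rebalance_method: str = "upsample"
    ig_steps: int = 64
    run_interpretation: bool = True
    seed: int = 0


def run_pipeline(
    bulk_raw: ExpressionMatrix,
    response: DrugResponseTable,
    sc_raw: ExpressionMatrix,
    config: RunConfig,
    out_dir: Optional[str] = None,
    sc_is_normalized: bool = False,
) -> dict:
    """Execute the full workflow; returns a dict of in-memory artifacts.

    When ``out_dir`` is given, writes model checkpoint, predictions TSV,
    IG container, critical-gene table and a provenance log there.
    """
    seed = config.seed
    # labels from AUC (waterfall)
    wf = waterfall_binarize(response.auc_pairs())
    # preprocessing
    sc_scaled = sc_raw if sc_is_normalized else qc_and_normalize_sc(sc_raw)
    bulk_scaled = scale_bulk(bulk_raw)
    bulk_scaled, sc_scaled = align_gene_spaces(bulk_scaled, sc_scaled)
    labels = np.array([wf.labels[s] for s in bulk_scaled.sample_ids], dtype=int)

    # split / rebalance
    split = SplitSpec(seed=stage_seed(seed, "split"))
    (Xtr, ytr), (Xva, yva), (Xte, yte) = stratified_split(bulk_scaled, labels, split)
    Xtr, ytr = rebalance(
        Xtr, ytr, method=config.rebalance_method, seed=stage_seed(seed, "rebalance")
    )

    # clustering + training
    clusters = cluster_cells(sc_scaled, seed=stage_seed(seed, "cluster"))
    net = config.net or NetConfig(n_genes=bulk_scaled.n_genes, **config.net_overrides)
    bundle, log = fit(
        (Xtr, ytr),
        sc_scaled,
        net,
        weights=config.weights,
        kernel=config.kernel,
        schedule=config.schedule,
        seed=stage_seed(seed, "train"),
        clusters=clusters,
        val=(Xva, yva),
    )

    # bulk test metrics
    from .networks import predict_bulk

    test_prob = predict_bulk(bundle.E_b, bundle.P, Xte.values)[:, 1]
    bulk_metrics = classification_metrics(yte, test_prob)

    # transfer to single cells + attribution
    pred = predict_sc(bundle, sc_scaled)
    if config.run_interpretation:
        ig_sens = integrated_gradients(bundle, sc_scaled, "sensitive", config.ig_steps)
        ig_res = integrated_gradients(bundle, sc_scaled, "resistant", config.ig_steps)
        groups = {
            c: ("sensitive" if l == 1 else "resistant")
            for c, l in zip(pred.cell_ids, pred.binary_label)
        }
        cg = select_critical_genes(ig_sens, groups)
    else:
        ig_sens = ig_res = None
        cg = None

    artifacts = {
        "waterfall": wf,
        "bulk_scaled": bulk_scaled,
        "sc_scaled": sc_scaled,
        "clusters": clusters,
        "bundle": bundle,
        "train_log": log,
        "bulk_test_metrics": bulk_metrics,
        "predictions": pred,
        "ig_sensitive": ig_sens,
        "ig_resistant": ig_res,
        "critical_genes": cg,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        save_bundle(bundle, os.path.join(out_dir, "model.ckpt.npz"))
        pred.to_frame().to_csv(os.path.join(out_dir, "predictions.tsv"), sep="\t", index=False)
        if config.run_interpretation:
            save_ig_h5ad(
                [ig_sens, ig_res], os.path.join(out_dir, "attr_integrated_gradient.h5ad")
            )
            cg.to_csv(os.path.join(out_dir, "critical_genes.tsv"), sep="\t", index=False)
        pd.DataFrame(log).to_csv(os.path.join(out_dir, "train_log.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
            json.dump(bulk_metrics.as_dict(), fh, indent=2)
        prov = {
            "version": __version__,
            "seed": seed,
            "net": asdict(net),
            "weights": asdict(config.weights),
            "schedule": asdict(config.schedule),
            "waterfall": {"cutoff": wf.cutoff, "regime": wf.regime, "pearson_r": wf.pearson_r},
        }
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump(prov, fh, indent=2)
    return artifacts
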