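"""The five trainable components and their local losses.

The model comprises two denoising autoencoders — one for bulk cell-line
profiles (encoder ``E_b``, decoder ``D_b``) and one for single cells
(``E_s``, ``D_s``) — plus a predictor head ``P`` that maps the shared
bottleneck space to two class probabilities (resistant, sensitive).
Denoising corruption zeroes each matrix entry independently with
probability ``p`` (a binomial mask); reconstruction is scored by MSE
against the uncorrupted input, classification by cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import MLP, softmax

EPS_LOG = 1e-12


class ShapeError(ValueError):
    pass


@dataclass
class NetConfig:
    """Architecture and noise configuration for the model bundle.

    ``encoder_hidden`` lists hidden widths of both encoders; decoders
    mirror them.  ``noise_prob_bulk`` / ``noise_prob_sc`` are the entry
    dropout probabilities of the denoising corruption.
    """

    n_genes: int
    encoder_hidden: list[int] = field(default_factory=lambda: [512, 256])
    bottleneck_dim: int = 128
    predictor_hidden: list[int] = field(default_factory=lambda: [64, 32])
    dropout: float = 0.3
    noise_prob_bulk: float = 0.2
    noise_prob_sc: float = 0.2

    def __post_init__(self) -> None:
        if self.bottleneck_dim >= self.n_genes:
            raise ValueError("bottleneck_dim must be smaller than n_genes")
        dims = [*self.encoder_hidden, self.bottleneck_dim, *self.predictor_hidden]
        if any(d < 1 for d in dims):
            raise ValueError("all layer dims must be >= 1")
        for name in ("dropout", "noise_prob_bulk", "noise_prob_sc"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class ModelBundle:
    """E_b, D_b, E_s, D_s, P plus their configuration and seed."""

    E_b: MLP
    D_b: MLP
    E_s: MLP
    D_s: MLP
    P: MLP
    config: NetConfig
    seed: int

    def all_models(self) -> list[MLP]:
        return [self.E_b, self.D_b, self.E_s, self.D_s, self.P]


def build_bundle(config: NetConfig, seed: int = 0) -> ModelBundle:
    """Construct the five components with seeded fan-in initialization.

    Encoders end in a ReLU bottleneck (non-negative latents), decoders are
    linear at the output; the predictor emits two logits (softmaxed by
    :func:`predict_proba`).
    """
    rng = np.random.default_rng(seed)
    enc_dims = [config.n_genes, *config.encoder_hidden, config.bottleneck_dim]
    dec_dims = list(reversed(enc_dims))
    pred_dims = [config.bottleneck_dim, *config.predictor_hidden, 2]
    E_b = MLP.build(enc_dims, rng, final_relu=True)
    D_b = MLP.build(dec_dims, rng)
    E_s = MLP.build(enc_dims, rng, final_relu=True)
    D_s = MLP.build(dec_dims, rng)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    P = MLP.build(pred_dims, rng, dropout=config.dropout, dropout_rng=drop_rng)
    return ModelBundle(E_b, D_b, E_s, D_s, P, config, seed)


def corrupt(
    X: np.ndarray, p: float, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Zero each entry independently with probability ``p`` (binomial mask)."""
    if not (0 <= p < 1):
        raise ValueError("noise probability must be in [0, 1)")
    if p == 0:
        return X.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = rng.random(X.shape) >= p
    return X * mask


def dae_reconstruction_loss(
    E: MLP,
    D: MLP,
    X: np.ndarray,
    p: float,
    rng: np.random.Generator | None = None,
    train: bool = False,
) -> tuple[float, np.ndarray]:
    """MSE between ``X`` and ``D(E(corrupt(X, p)))``.

    Returns ``(loss, reconstruction)``; with ``train=True`` the forward
    caches are kept so callers can backpropagate through E and D.
    """
    Xc = corrupt(X, p, rng=rng)
    recon = D.forward(E.forward(Xc, train=train), train=train)
    loss = float(np.mean((X - recon) ** 2))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite reconstruction loss")
    return loss, recon


def predict_bulk(E_b: MLP, P: MLP, X_b: np.ndarray) -> np.ndarray:
    """Class-probability matrix ``Y_b = softmax(P(E_b(X_b)))``; rows sum to 1."""
    X_b = np.asarray(X_b, dtype=float)
    n_in = E_b.layers[0].W.shape[0]
    if X_b.shape[1] != n_in:
        raise ShapeError(f"expected {n_in} genes, got {X_b.shape[1]}")
    return softmax(P.forward(E_b.forward(X_b)))


def classification_loss(Y_prob: np.ndarray, y_true: np.ndarray) -> float:
    """Mean cross-entropy between predicted probabilities and binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    p_true = np.clip(Y_prob[np.arange(len(y_true)), y_true], EPS_LOG, None)
    return float(-np.mean(np.log(p_true)))


# ---------------------------------------------------------------------------
# checkpoint serialization


def save_bundle(bundle: ModelBundle, path: str) -> None:
    """Serialize weights + NetConfig + seed into a single .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for name, model in zip(("E_b", "D_b", "E_s", "D_s", "P"), bundle.all_models()):
        for i, w in enumerate(model.get_weights()):
            arrays[f"{name}_{i}"] = w
    arrays["_meta"] = np.frombuffer(
        json.dumps({"config": asdict(bundle.config), "seed": bundle.seed}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_bundle(path: str) -> ModelBundle:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    config = NetConfig(**meta["config"])
    bundle = build_bundle(config, seed=meta["seed"])
    for name, model in zip(("E_b", "D_b", "E_s", "D_s", "P"), bundle.all_models()):
        n = len(model.get_weights())
        model.set_weights([data[f"{name}_{i}"] for i in range(n)])
    return bundle
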