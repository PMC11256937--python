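"""Fully connected autoencoder with a Poisson reconstruction likelihood.

Implemented directly on numpy arrays with hand-written gradients so the
package has no deep-learning framework dependency. The encoder maps scaled
expression to a low-dimensional representation; the decoder maps it back to
strictly positive Poisson rates through an exponential output link.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .errors import DomainError, NumericalError, ValidationError

__all__ = [
    "MLPParams",
    "EncoderParams",
    "DecoderParams",
    "init_autoencoder",
    "encode",
    "decode",
    "poisson_nll",
    "save_checkpoint",
    "load_checkpoint",
]

RATE_MIN = 1e-8
RATE_MAX = 1e8
_LOG_RATE_MIN = np.log(RATE_MIN)
_LOG_RATE_MAX = np.log(RATE_MAX)


def _softplus(a: np.ndarray) -> np.ndarray:
    # numerically stable: log(1 + e^a)
    return np.logaddexp(0.0, a)


@dataclass
class MLPParams:
    """Weights and biases of a fully connected network.

    ``weights[i]`` has shape ``(widths[i], widths[i+1])``; hidden layers use a
    softplus activation, the final layer is linear.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple([self.weights[0].shape[0]] + [w.shape[1] for w in self.weights])

    @property
    def in_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def out_dim(self) -> int:
        return self.weights[-1].shape[1]

    def copy(self) -> "MLPParams":
        return type(self)([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def flat(self) -> list[np.ndarray]:
        return self.weights + self.biases


class EncoderParams(MLPParams):
    """Encoder network parameters (input width G', output width D)."""


class DecoderParams(MLPParams):
    """Decoder network parameters (input width D, output width G')."""


def _init_mlp(rng: np.random.Generator, widths: tuple[int, ...], cls) -> MLPParams:
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return cls(weights, biases)


def init_autoencoder(
    n_features: int,
    latent_dim: int = 32,
    encoder_hidden: tuple[int, ...] = (256, 128),
    decoder_hidden: tuple[int, ...] = (128, 256),
    seed: int = 0,
) -> tuple[EncoderParams, DecoderParams]:
    """Fan-in scaled random initialization of both networks."""
    rng = np.random.default_rng(seed)
    enc = _init_mlp(rng, (n_features, *encoder_hidden, latent_dim), EncoderParams)
    dec = _init_mlp(rng, (latent_dim, *decoder_hidden, n_features), DecoderParams)
    return enc, dec


def _forward(x: np.ndarray, params: MLPParams) -> tuple[np.ndarray, list]:
    """Forward pass returning the linear output and a cache for backprop."""
    cache = []
    h = x
    last = len(params.weights) - 1
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        pre = h @ w + b
        cache.append((h, pre))
        h = pre if i == last else _softplus(pre)
    return h, cache


def _backward(grad_out: np.ndarray, params: MLPParams, cache: list
              ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Backpropagate ``grad_out`` (d loss / d linear output).

    Returns per-layer weight grads, bias grads and the gradient w.r.t. the input.
    """
    grads_w = [None] * len(params.weights)
    grads_b = [None] * len(params.biases)
    g = grad_out
    for i in range(len(params.weights) - 1, -1, -1):
        h_in, pre = cache[i]
        if i != len(params.weights) - 1:
            g = g * expit(pre)  # softplus' = sigmoid
        grads_w[i] = h_in.T @ g
        grads_b[i] = g.sum(axis=0)
        g = g @ params.weights[i].T
    return grads_w, grads_b, g


def encode(x_batch: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Deterministic map from scaled expression to the latent representation."""
    x_batch = np.atleast_2d(np.asarray(x_batch, dtype=np.float64))
    if x_batch.shape[1] != params.in_dim:
        raise ValidationError(
            f"encoder expects {params.in_dim} features, got {x_batch.shape[1]}"
        )
    z, _ = _forward(x_batch, params)
    if not np.all(np.isfinite(z)):
        raise NumericalError("encoder produced non-finite values")
    return z


def decode(z_batch: np.ndarray, params: DecoderParams) -> np.ndarray:
    """Map latent vectors to strictly positive Poisson rates.

    The output link is an exponential of the final pre-activation with its
    argument clamped so rates stay within ``[1e-8, 1e8]``.
    """
    z_batch = np.atleast_2d(np.asarray(z_batch, dtype=np.float64))
    if z_batch.shape[1] != params.in_dim:
        raise ValidationError(
            f"decoder expects {params.in_dim} latent dims, got {z_batch.shape[1]}"
        )
    pre, _ = _forward(z_batch, params)
    if not np.all(np.isfinite(pre)):
        bad = int(np.argwhere(~np.isfinite(pre).all(axis=1))[0, 0])
        raise NumericalError(f"decoder produced non-finite output at batch index {bad}")
    return np.exp(np.clip(pre, _LOG_RATE_MIN, _LOG_RATE_MAX))


def poisson_nll(x: np.ndarray, eta: np.ndarray) -> float:
    """Exact negative log Poisson mass, summed over entries.

    ``sum_g [eta_g - x_g * ln(eta_g) + ln(x_g!)]`` with the factorial term
    via log-gamma. ``x`` must be nonnegative integers and ``eta`` strictly
    positive.
    """
    x = np.asarray(x, dtype=np.float64)
    eta = np.asarray(eta, dtype=np.float64)
    if x.shape != eta.shape:
        raise ValidationError(f"shape mismatch: x {x.shape} vs eta {eta.shape}")
    if np.any(eta <= 0) or not np.all(np.isfinite(eta)):
        raise DomainError("rates must be strictly positive and finite")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValidationError("counts must be nonnegative integers")
    return float(np.sum(eta - x * np.log(eta) + gammaln(x + 1.0)))


CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str,
    encoder: EncoderParams,
    decoder: DecoderParams,
    hvg_indices: np.ndarray | None = None,
    per_gene_mean: np.ndarray | None = None,
    per_gene_sd: np.ndarray | None = None,
    extra: dict | None = None,
) -> None:
    """Persist both networks plus preprocessing state to an ``.npz`` container."""
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "version": CHECKPOINT_VERSION,
        "encoder_widths": list(encoder.widths),
        "decoder_widths": list(decoder.widths),
        "extra": extra or {},
    }
    for tag, params in (("enc", encoder), ("dec", decoder)):
        for i, (w, b) in enumerate(zip(params.weights, params.biases)):
            arrays[f"{tag}_w{i}"] = w
            arrays[f"{tag}_b{i}"] = b
    if hvg_indices is not None:
        arrays["hvg_indices"] = np.asarray(hvg_indices)
    if per_gene_mean is not None:
        arrays["per_gene_mean"] = np.asarray(per_gene_mean)
    if per_gene_sd is not None:
        arrays["per_gene_sd"] = np.asarray(per_gene_sd)
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> dict:
    """Load a checkpoint written by :func:`save_checkpoint`.

    Returns a dict with keys ``encoder``, ``decoder``, ``hvg_indices``,
    ``per_gene_mean``, ``per_gene_sd`` and ``meta``.
    """
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(f"unsupported checkpoint version {meta.get('version')}")

        def _mlp(tag: str, cls) -> MLPParams:
            n_layers = len(meta[f"{'encoder' if tag == 'enc' else 'decoder'}_widths"]) - 1
            ws = [data[f"{tag}_w{i}"] for i in range(n_layers)]
            bs = [data[f"{tag}_b{i}"] for i in range(n_layers)]
            return cls(ws, bs)

        out = {
            "encoder": _mlp("enc", EncoderParams),
            "decoder": _mlp("dec", DecoderParams),
            "meta": meta,
        }
        for key in ("hvg_indices", "per_gene_mean", "per_gene_sd"):
            out[key] = data[key] if key in data else None
    return out
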