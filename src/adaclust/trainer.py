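"""Alternating training of the autoencoder and the mixture prior.

Pretrain the autoencoder on the Poisson reconstruction loss alone, then
iterate: gradient steps on ``l_AE + lambda * l_z`` with the mixture state
frozen, refitting the mixture on the full latent matrix every few epochs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from . import autoencoder as ae
from . import dpmm
from .errors import NumericalError, ValidationError
from .io_preprocess import CountMatrix, ProcessedMatrix, preprocess

__all__ = [
    "TrainConfig",
    "TrainingTrace",
    "ClusteringResult",
    "AdamW",
    "pretrain_ae",
    "train",
    "infer_labels",
    "fit_pipeline",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    lam: float = 1.0
    alpha: float = 1e-10
    batch_size: int = 512
    learning_rate: float = 1e-4
    epochs: int = 100
    s_update_every: int = 1  # epochs between mixture refits
    pretrain_epochs: int = 50
    K_max: int = 50
    latent_dim: int = 32
    encoder_hidden: tuple[int, ...] = (256, 128)
    decoder_hidden: tuple[int, ...] = (128, 256)
    weight_decay: float = 1e-2
    dpmm_max_iter: int = 100
    dpmm_tol: float = 1e-4
    n_hvg: int = 4000
    scale_factor: float = 1e4
    clip_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.batch_size < 1 or self.s_update_every < 1:
            raise ValidationError("batch_size and s_update_every must be >= 1")
        if self.epochs < 0 or self.pretrain_epochs < 0:
            raise ValidationError("epoch counts must be nonnegative")


@dataclass
class TrainingTrace:
    """Per-epoch training records."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def column(self, name: str) -> np.ndarray:
        return np.array([r.get(name, np.nan) for r in self.records], dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


@dataclass
class ClusteringResult:
    labels: np.ndarray
    n_clusters: int
    cell_ids: list[str] | None = None

    def to_csv(self, path: str) -> None:
        import pandas as pd

        ids = self.cell_ids if self.cell_ids is not None else [
            f"cell{i}" for i in range(len(self.labels))
        ]
        pd.DataFrame({"cell_id": ids, "label": self.labels}).to_csv(path, index=False)


class AdamW:
    """Adam with decoupled weight decay on a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * self.wd * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _batch_losses_and_grads(
    x_scaled: np.ndarray,
    x_raw: np.ndarray,
    encoder: ae.EncoderParams,
    decoder: ae.DecoderParams,
    lam: float,
    state: dpmm.DPMMState | None,
) -> tuple[float, float, list[np.ndarray], list[np.ndarray]]:
    """Mean per-cell losses and parameter gradients for one minibatch."""
    b = x_scaled.shape[0]
    z, enc_cache = ae._forward(x_scaled, encoder)
    pre, dec_cache = ae._forward(z, decoder)
    pre_c = np.clip(pre, ae._LOG_RATE_MIN, ae._LOG_RATE_MAX)
    eta = np.exp(pre_c)
    recon = float(np.sum(eta - x_raw * pre_c + gammaln(x_raw + 1.0)) / b)

    inside = (pre > ae._LOG_RATE_MIN) & (pre < ae._LOG_RATE_MAX)
    d_pre = (eta - x_raw) * inside / b
    dec_gw, dec_gb, dz = ae._backward(d_pre, decoder, dec_cache)

    zloss = 0.0
    if lam > 0 and state is not None:
        lz, gz = dpmm.loss_z_grad(z, state)
        zloss = float(lz.mean())
        dz = dz + (lam / b) * gz
    enc_gw, enc_gb, _ = ae._backward(dz, encoder, enc_cache)
    grads = enc_gw + enc_gb + dec_gw + dec_gb
    return recon, zloss, grads, [z]


def _check_finite(loss: float, epoch: int) -> None:
    if not np.isfinite(loss):
        raise NumericalError(f"training diverged (non-finite loss) at epoch {epoch}; "
                             f"last finite epoch was {epoch - 1}")


def _sgd_epochs(
    encoder: ae.EncoderParams,
    decoder: ae.DecoderParams,
    x_scaled: np.ndarray,
    x_raw: np.ndarray,
    config: TrainConfig,
    n_epochs: int,
    rng: np.random.Generator,
    opt: AdamW,
    trace: TrainingTrace,
    lam: float = 0.0,
    state: dpmm.DPMMState | None = None,
    early_stop: bool = False,
    phase: str = "pretrain",
    on_epoch_end=None,
) -> None:
    n = x_scaled.shape[0]
    recent: list[float] = []
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        recon_sum = zloss_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            recon, zloss, grads, _ = _batch_losses_and_grads(
                x_scaled[idx], x_raw[idx], encoder, decoder, lam, state
            )
            _check_finite(recon + zloss, epoch)
            opt.step(grads)
            recon_sum += recon
            zloss_sum += zloss
            n_batches += 1
        recon_mean = recon_sum / n_batches
        zloss_mean = zloss_sum / n_batches
        record = dict(
            phase=phase, epoch=epoch, recon_loss=recon_mean, z_loss=zloss_mean,
            combined_loss=recon_mean + lam * zloss_mean, timestamp=time.time(),
        )
        if on_epoch_end is not None:
            extra = on_epoch_end(epoch)
            if extra:
                record.update(extra)
        trace.append(**record)
        if early_stop:
            recent.append(recon_mean)
            if len(recent) > 5:
                recent.pop(0)
                if abs(recent[0] - recent[-1]) < 1e-4 * max(abs(recent[0]), 1e-12):
                    break


def pretrain_ae(
    data: ProcessedMatrix,
    raw_counts: np.ndarray,
    config: TrainConfig,
    init: tuple[ae.EncoderParams, ae.DecoderParams] | None = None,
    early_stop: bool = True,
    rng_seed: int | None = None,
) -> tuple[ae.EncoderParams, ae.DecoderParams, TrainingTrace]:
    """Minimize the Poisson reconstruction loss alone.

    Runs for ``config.pretrain_epochs`` epochs, or stops early once the
    relative loss improvement over 5 epochs falls below 1e-4.
    """
    if data.n_cells == 0:
        raise ValidationError("empty dataset")
    if init is None:
        encoder, decoder = ae.init_autoencoder(
            data.n_hvgs, config.latent_dim, config.encoder_hidden,
            config.decoder_hidden, seed=config.seed,
        )
        # start the output rates at the per-gene mean so early epochs learn
        # cell-specific structure instead of gene means
        gene_mean = np.maximum(raw_counts.mean(axis=0), 1e-4)
        decoder.biases[-1][:] = np.log(gene_mean)
    else:
        encoder, decoder = init[0].copy(), init[1].copy()
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    opt = AdamW(encoder.flat() + decoder.flat(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    trace = TrainingTrace()
    _sgd_epochs(encoder, decoder, data.values, raw_counts, config,
                config.pretrain_epochs, rng, opt, trace,
                lam=0.0, state=None, early_stop=early_stop, phase="pretrain")
    return encoder, decoder, trace


def train(
    data: ProcessedMatrix,
    raw_counts: np.ndarray,
    config: TrainConfig,
) -> tuple[ae.EncoderParams, ae.DecoderParams, dpmm.DPMMState, TrainingTrace]:
    """Full alternating optimization.

    Pretrains the autoencoder, fits the mixture on the resulting latent
    matrix, then for each epoch takes minibatch gradient steps on the
    combined loss with the mixture frozen and refits the mixture on the full
    latent matrix every ``s_update_every`` epochs (warm-started).
    """
    encoder, decoder, trace = pretrain_ae(data, raw_counts, config)

    z_full = ae.encode(data.values, encoder)
    # merge moves are deferred to the final fit: the latent keeps moving
    # during training, so polishing intermediate fits is wasted work
    state = dpmm.fit_S(
        z_full, alpha=config.alpha, K_max=config.K_max,
        max_iter=config.dpmm_max_iter, tol=config.dpmm_tol, seed=config.seed,
        merge_moves=False,
    )

    holder = {"state": state}

    def refit(epoch: int) -> dict:
        k_eff = dpmm.effective_cluster_count(holder["state"])
        if (epoch + 1) % config.s_update_every == 0:
            z_now = ae.encode(data.values, encoder)
            try:
                holder["state"] = dpmm.fit_S(
                    z_now, alpha=config.alpha, K_max=config.K_max,
                    max_iter=config.dpmm_max_iter, tol=config.dpmm_tol,
                    seed=config.seed, warm_start=holder["state"],
                    merge_moves=False,
                )
                k_eff = dpmm.effective_cluster_count(holder["state"])
            except (np.linalg.LinAlgError, NumericalError):
                pass  # keep the previous state on a failed refit
        return {"k_eff": k_eff}

    rng = np.random.default_rng(config.seed + 1)
    opt = AdamW(encoder.flat() + decoder.flat(), lr=config.learning_rate,
                weight_decay=config.weight_decay)

    class _LiveState:
        """Proxy so each minibatch sees the most recent mixture state."""

        def __getattr__(self, name):
            return getattr(holder["state"], name)

    live = _LiveState() if config.lam > 0 else None
    _sgd_epochs(encoder, decoder, data.values, raw_counts, config,
                config.epochs, rng, opt, trace,
                lam=config.lam, state=live, early_stop=False, phase="train",
                on_epoch_end=refit)

    # final polished fit on the settled latent, with merge moves enabled
    z_final = ae.encode(data.values, encoder)
    try:
        holder["state"] = dpmm.fit_S(
            z_final, alpha=config.alpha, K_max=config.K_max,
            max_iter=max(config.dpmm_max_iter, 200), tol=config.dpmm_tol,
            seed=config.seed, warm_start=holder["state"], merge_moves=True,
        )
    except (np.linalg.LinAlgError, NumericalError):
        pass
    return encoder, decoder, holder["state"], trace


def infer_labels(
    data: ProcessedMatrix | np.ndarray,
    encoder: ae.EncoderParams,
    state: dpmm.DPMMState,
    cell_ids: list[str] | None = None,
) -> ClusteringResult:
    """Assign each cell the argmax-responsibility component of its latent vector."""
    x = data.values if isinstance(data, ProcessedMatrix) else np.asarray(data)
    z = ae.encode(x, encoder)
    if z.shape[1] != state.components.means.shape[1]:
        raise ValidationError(
            f"encoder latent dim {z.shape[1]} does not match mixture dim "
            f"{state.components.means.shape[1]}"
        )
    resp = dpmm.responsibilities(z, state)
    labels = resp.argmax(axis=1)
    return ClusteringResult(labels=labels, n_clusters=int(np.unique(labels).size),
                            cell_ids=cell_ids)


def fit_pipeline(counts: CountMatrix, config: TrainConfig):
    """Preprocess + train + label. Returns a dict bundle."""
    processed, raw_hvg = preprocess(
        counts, n_hvg=config.n_hvg, scale_factor=config.scale_factor,
        clip_max=config.clip_max,
    )
    encoder, decoder, state, trace = train(processed, raw_hvg, config)
    result = infer_labels(processed, encoder, state, cell_ids=counts.cell_ids)
    return {
        "processed": processed,
        "raw_hvg": raw_hvg,
        "encoder": encoder,
        "decoder": decoder,
        "state": state,
        "trace": trace,
        "result": result,
        "latent": ae.encode(processed.values, encoder),
    }


MODEL_VERSION = 1


def save_model(path: str, encoder: ae.EncoderParams, decoder: ae.DecoderParams,
               state: dpmm.DPMMState | None = None,
               hvg_indices: np.ndarray | None = None,
               per_gene_mean: np.ndarray | None = None,
               per_gene_sd: np.ndarray | None = None,
               config: TrainConfig | None = None) -> None:
    """Checkpoint both networks, preprocessing state and the fitted mixture."""
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "version": MODEL_VERSION,
        "encoder_widths": list(encoder.widths),
        "decoder_widths": list(decoder.widths),
        "has_state": state is not None,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()} if config else None,
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
    if state is not None:
        arrays["dp_delta"] = state.sticks.delta
        arrays["dp_alpha"] = np.array([state.sticks.alpha])
        arrays["dp_means"] = state.components.means
        arrays["dp_precisions"] = state.components.precisions
        if state.hyper is not None:
            arrays["dp_sigma"] = state.hyper.sigma
            arrays["dp_kappa0_nu0"] = np.array([state.hyper.kappa0, state.hyper.nu0])
            arrays["dp_zeta"] = state.hyper.zeta
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> dict:
    """Load a checkpoint written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta.get("version") != MODEL_VERSION:
            raise ValidationError(f"unsupported model version {meta.get('version')}")

        def _mlp(tag: str, widths, cls):
            ws = [data[f"{tag}_w{i}"] for i in range(len(widths) - 1)]
            bs = [data[f"{tag}_b{i}"] for i in range(len(widths) - 1)]
            return cls(ws, bs)

        out = {
            "encoder": _mlp("enc", meta["encoder_widths"], ae.EncoderParams),
            "decoder": _mlp("dec", meta["decoder_widths"], ae.DecoderParams),
            "meta": meta,
            "state": None,
        }
        for key in ("hvg_indices", "per_gene_mean", "per_gene_sd"):
            out[key] = data[key] if key in data else None
        if meta.get("has_state"):
            delta = data["dp_delta"]
            alpha = float(data["dp_alpha"][0])
            sticks = dpmm.StickBreaking(delta=delta, alpha=alpha)
            weights = dpmm.stick_to_weights(sticks)
            comps = dpmm.ComponentParams(means=data["dp_means"],
                                         precisions=data["dp_precisions"])
            hyper = None
            if "dp_sigma" in data:
                k0, n0 = data["dp_kappa0_nu0"]
                hyper = dpmm.NWHyper(sigma=data["dp_sigma"], kappa0=float(k0),
                                     nu0=float(n0), zeta=data["dp_zeta"])
            n_dummy = delta.size
            resp = np.eye(n_dummy)
            out["state"] = dpmm.DPMMState(
                sticks=sticks, weights=weights, components=comps,
                responsibilities=resp, hard_labels=resp.argmax(axis=1),
                hyper=hyper,
            )
    return out
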