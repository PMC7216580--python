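"""Conditional variational autoencoder for methylome generation.

The generative model: latent z with standard-normal prior p(z) = N(0, I),
decoder p_theta(x | z, y) mapping (z, one-hot cancer type y) to per-CpG
Bernoulli-style means in (0, 1) through a sigmoid output; encoder
(recognition network) q_phi(z | x, y) is a diagonal Gaussian whose mean and
log-variance are produced from (x, y).  Training maximizes the conditional
evidence lower bound

    E_q[log p(x | z, y)] - KL[q(z | x, y) || N(0, I)]

via the reparameterization trick (z = mu + sigma * eps) and minibatch Adam.
One independent model is trained per CpG chunk; generated chunk outputs are
concatenated in chunk order.

Default architecture: encoder hidden layers of 500 and 250 nodes (ELU then
tanh), 125 latent variables, a mirrored decoder, sigmoid output; learning
rate 1e-3, 10,000 epochs, Adam.  All of this is configurable through
:class:`CVAEConfig`.

The network is implemented directly in NumPy (dense layers with explicit
forward/backward passes and an Adam optimizer), which keeps the package
dependency-light and every result exactly reproducible from a single seed.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import BetaMatrix, ConditionVector
from .preprocess import ChunkedDataset

__all__ = [
    "CVAEConfig",
    "GaussianPosterior",
    "LatentSample",
    "CVAEModelState",
    "CVAEError",
    "ModelIOError",
    "kl_gaussian_vs_standard_normal",
    "elbo_loss",
    "encode",
    "reparameterize",
    "decode",
    "train_cvae",
    "generate",
    "save_state",
    "load_state",
]

_EPS = 1e-6
_STATE_VERSION = 1


class CVAEError(ValueError):
    pass


class ModelIOError(IOError):
    """Corrupt, truncated or version-incompatible model state on disk."""


@dataclass
class CVAEConfig:
    """Hyperparameters of the conditional VAE.

    ``activation_plan`` names the nonlinearity of each encoder hidden layer
    in order; the decoder uses the reversed plan (mirrored structure).
    ``reconstruction_loss`` is ``"cross_entropy"`` (elementwise binary
    cross-entropy on beta values, the default) or ``"mse"``.
    """

    encoder_hidden: tuple[int, ...] = (500, 250)
    latent_dim: int = 125
    decoder_hidden: tuple[int, ...] | None = None  # None -> mirror of encoder
    learning_rate: float = 1e-3
    epochs: int = 10000
    batch_size: int = 100
    seed: int = 0
    activation_plan: tuple[str, ...] = ("elu", "tanh")
    reconstruction_loss: str = "cross_entropy"

    def __post_init__(self) -> None:
        self.encoder_hidden = tuple(int(h) for h in self.encoder_hidden)
        if self.decoder_hidden is not None:
            self.decoder_hidden = tuple(int(h) for h in self.decoder_hidden)
        self.activation_plan = tuple(self.activation_plan)
        if self.latent_dim < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise CVAEError("latent_dim >= 1, epochs >= 1, learning_rate > 0 required")
        if len(self.activation_plan) != len(self.encoder_hidden):
            raise CVAEError("activation_plan must match encoder_hidden length")
        for a in self.activation_plan:
            if a not in ("elu", "tanh"):
                raise CVAEError(f"unknown activation {a!r}")
        if self.reconstruction_loss not in ("cross_entropy", "mse"):
            raise CVAEError("reconstruction_loss must be cross_entropy or mse")

    @property
    def decoder_layers(self) -> tuple[int, ...]:
        return (
            self.decoder_hidden
            if self.decoder_hidden is not None
            else tuple(reversed(self.encoder_hidden))
        )

    @property
    def decoder_activations(self) -> tuple[str, ...]:
        return tuple(reversed(self.activation_plan))


@dataclass
class GaussianPosterior:
    """Diagonal Gaussian q(z | x, y): mean and log-variance vectors."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.logvar = np.asarray(self.logvar, dtype=np.float64)
        if self.mu.shape != self.logvar.shape:
            raise CVAEError("mu and logvar must have the same shape")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise CVAEError("non-finite posterior parameters")


@dataclass
class LatentSample:
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)


@dataclass
class CVAEModelState:
    """Trained per-chunk weights plus the metadata needed to generate."""

    config: CVAEConfig
    vocabulary: list[str]
    chunk_cpg_ids: list[list[str]]
    weights: list[dict[str, np.ndarray]]
    loss_traces: list[list[float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chunks(self) -> int:
        return len(self.weights)

    @property
    def cpg_ids(self) -> list[str]:
        out: list[str] = []
        for ids in self.chunk_cpg_ids:
            out.extend(ids)
        return out


# ---------------------------------------------------------------- activations

def _act(name: str, a: np.ndarray) -> np.ndarray:
    if name == "elu":
        return np.where(a > 0, a, np.expm1(np.minimum(a, 0.0)))
    return np.tanh(a)


def _act_grad(name: str, a: np.ndarray, h: np.ndarray) -> np.ndarray:
    # derivative wrt the pre-activation, expressed via the cached output h
    if name == "elu":
        return np.where(a > 0, 1.0, h + 1.0)
    return 1.0 - h * h


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


# ------------------------------------------------------------------ ELBO math

def kl_gaussian_vs_standard_normal(q: GaussianPosterior) -> float:
    """KL[ N(mu, diag exp(logvar)) || N(0, I) ], the ELBO regularizer.

    Closed form: -1/2 * sum_d (1 + logvar_d - mu_d^2 - exp(logvar_d)).
    Always >= 0, zero iff q equals the prior.
    """
    mu, lv = q.mu, q.logvar
    return float(-0.5 * np.sum(1.0 + lv - mu * mu - np.exp(lv)))


def elbo_loss(
    x: np.ndarray,
    x_recon: np.ndarray,
    q: GaussianPosterior,
    reconstruction_loss: str = "cross_entropy",
) -> tuple[float, float, float]:
    """Negative ELBO for one sample: (total, reconstruction, kl).

    ``total = recon + kl``; minimizing it maximizes the variational lower
    bound.  Cross-entropy treats beta values as probabilities (x clipped to
    [1e-6, 1-1e-6]); mse is the summed squared error.
    """
    x = np.asarray(x, dtype=np.float64)
    x_recon = np.asarray(x_recon, dtype=np.float64)
    if x.shape != x_recon.shape:
        raise CVAEError(f"shape mismatch: x {x.shape} vs x_recon {x_recon.shape}")
    if reconstruction_loss == "cross_entropy":
        xc = np.clip(x, _EPS, 1.0 - _EPS)
        rc = np.clip(x_recon, _EPS, 1.0 - _EPS)
        recon = float(-np.sum(xc * np.log(rc) + (1.0 - xc) * np.log(1.0 - rc)))
    elif reconstruction_loss == "mse":
        recon = float(np.sum((x - x_recon) ** 2))
    else:
        raise CVAEError(f"unknown reconstruction loss {reconstruction_loss!r}")
    kl = kl_gaussian_vs_standard_normal(q)
    return recon + kl, recon, kl


def reparameterize(q: GaussianPosterior, rng: np.random.Generator) -> LatentSample:
    """Draw z = mu + exp(logvar / 2) * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(q.mu.shape)
    return LatentSample(q.mu + np.exp(0.5 * q.logvar) * eps)


# ------------------------------------------------------------- network passes

def _init_weights(
    n_cpgs: int, n_cond: int, cfg: CVAEConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fan-in-scaled Gaussian initialization; biases zero."""
    w: dict[str, np.ndarray] = {}

    def dense(tag: str, fan_in: int, fan_out: int) -> None:
        w[f"{tag}_W"] = rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)
        w[f"{tag}_b"] = np.zeros(fan_out)

    d = n_cpgs + n_cond
    for i, h in enumerate(cfg.encoder_hidden):
        dense(f"enc{i}", d, h)
        d = h
    dense("mu", d, cfg.latent_dim)
    dense("logvar", d, cfg.latent_dim)
    d = cfg.latent_dim + n_cond
    for i, h in enumerate(cfg.decoder_layers):
        dense(f"dec{i}", d, h)
        d = h
    dense("out", d, n_cpgs)
    return w


def _encoder_forward(
    w: dict[str, np.ndarray], xy: np.ndarray, cfg: CVAEConfig
) -> tuple[np.ndarray, np.ndarray, list[tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    h = xy
    cache = []
    for i, act in enumerate(cfg.activation_plan):
        a = h @ w[f"enc{i}_W"] + w[f"enc{i}_b"]
        out = _act(act, a)
        cache.append((h, a, out))
        h = out
    mu = h @ w["mu_W"] + w["mu_b"]
    logvar = h @ w["logvar_W"] + w["logvar_b"]
    return mu, logvar, cache


def _decoder_forward(
    w: dict[str, np.ndarray], zy: np.ndarray, cfg: CVAEConfig
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    h = zy
    cache = []
    for i, act in enumerate(cfg.decoder_activations):
        a = h @ w[f"dec{i}_W"] + w[f"dec{i}_b"]
        out = _act(act, a)
        cache.append((h, a, out))
        h = out
    logits = h @ w["out_W"] + w["out_b"]
    return logits, cache


def _train_step(
    w: dict[str, np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    cfg: CVAEConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], float]:
    """One minibatch forward+backward pass; returns (grads, mean total loss)."""
    B = x.shape[0]
    xc = np.clip(x, _EPS, 1.0 - _EPS)
    xy = np.concatenate([x, y], axis=1)
    mu, logvar, enc_cache = _encoder_forward(w, xy, cfg)
    eps = rng.standard_normal(mu.shape)
    std = np.exp(0.5 * logvar)
    z = mu + std * eps
    zy = np.concatenate([z, y], axis=1)
    logits, dec_cache = _decoder_forward(w, zy, cfg)
    p = _sigmoid(logits)

    if cfg.reconstruction_loss == "cross_entropy":
        # stable: sum(softplus(logits) - x * logits)
        recon = np.sum(np.logaddexp(0.0, logits) - xc * logits, axis=1)
        dlogits = (p - xc) / B
    else:
        recon = np.sum((p - x) ** 2, axis=1)
        dlogits = 2.0 * (p - x) * p * (1.0 - p) / B
    kl = -0.5 * np.sum(1.0 + logvar - mu * mu - np.exp(logvar), axis=1)
    loss = float(np.mean(recon + kl))

    g: dict[str, np.ndarray] = {}
    # decoder output layer
    h_last = dec_cache[-1][2] if dec_cache else zy
    g["out_W"] = h_last.T @ dlogits
    g["out_b"] = dlogits.sum(axis=0)
    dh = dlogits @ w["out_W"].T
    for i in range(len(dec_cache) - 1, -1, -1):
        h_in, a, h_out = dec_cache[i]
        da = dh * _act_grad(cfg.decoder_activations[i], a, h_out)
        g[f"dec{i}_W"] = h_in.T @ da
        g[f"dec{i}_b"] = da.sum(axis=0)
        dh = da @ w[f"dec{i}_W"].T
    dz = dh[:, : cfg.latent_dim]
    # reparameterization + KL gradients (KL averaged over batch)
    dmu = dz + mu / B
    dlogvar = dz * 0.5 * std * eps + 0.5 * (np.exp(logvar) - 1.0) / B
    h_enc = enc_cache[-1][2] if enc_cache else xy
    g["mu_W"] = h_enc.T @ dmu
    g["mu_b"] = dmu.sum(axis=0)
    g["logvar_W"] = h_enc.T @ dlogvar
    g["logvar_b"] = dlogvar.sum(axis=0)
    dh = dmu @ w["mu_W"].T + dlogvar @ w["logvar_W"].T
    for i in range(len(enc_cache) - 1, -1, -1):
        h_in, a, h_out = enc_cache[i]
        da = dh * _act_grad(cfg.activation_plan[i], a, h_out)
        g[f"enc{i}_W"] = h_in.T @ da
        g[f"enc{i}_b"] = da.sum(axis=0)
        dh = da @ w[f"enc{i}_W"].T
    return g, loss


class _Adam:
    """Plain Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + eps)


# ----------------------------------------------------------------- public API

def _one_hot_for(condition_or_vec, vocabulary: Sequence[str]) -> np.ndarray:
    if isinstance(condition_or_vec, str):
        if condition_or_vec not in vocabulary:
            raise CVAEError(
                f"unknown condition {condition_or_vec!r}; "
                f"vocabulary: {list(vocabulary)}"
            )
        vec = np.zeros(len(vocabulary))
        vec[list(vocabulary).index(condition_or_vec)] = 1.0
        return vec
    vec = np.asarray(condition_or_vec, dtype=np.float64)
    if vec.shape[-1] != len(vocabulary):
        raise CVAEError("one-hot length does not match vocabulary size")
    return vec


def encode(
    x: np.ndarray, y, state: CVAEModelState, chunk: int = 0
) -> GaussianPosterior:
    """Deterministic map (x, y) -> q(z | x, y) for one sample.

    ``y`` may be a condition string or a one-hot vector.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != len(state.chunk_cpg_ids[chunk]):
        raise CVAEError(
            f"x has {x.shape[1]} CpGs, chunk {chunk} expects "
            f"{len(state.chunk_cpg_ids[chunk])}"
        )
    yv = np.atleast_2d(_one_hot_for(y, state.vocabulary))
    yv = np.broadcast_to(yv, (x.shape[0], yv.shape[1]))
    xy = np.concatenate([x, yv], axis=1)
    mu, logvar, _ = _encoder_forward(state.weights[chunk], xy, state.config)
    if mu.shape[0] == 1:
        return GaussianPosterior(mu[0], logvar[0])
    return GaussianPosterior(mu, logvar)


def decode(z, y, state: CVAEModelState, chunk: int = 0) -> np.ndarray:
    """Deterministic map (z, y) -> reconstructed beta values in (0, 1)."""
    zv = z.z if isinstance(z, LatentSample) else np.asarray(z, dtype=np.float64)
    squeeze = zv.ndim == 1
    zv = np.atleast_2d(zv)
    if zv.shape[1] != state.config.latent_dim:
        raise CVAEError(
            f"z has length {zv.shape[1]}, expected {state.config.latent_dim}"
        )
    yv = np.atleast_2d(_one_hot_for(y, state.vocabulary))
    yv = np.broadcast_to(yv, (zv.shape[0], yv.shape[1]))
    logits, _ = _decoder_forward(
        state.weights[chunk], np.concatenate([zv, yv], axis=1), state.config
    )
    out = _sigmoid(logits)
    return out[0] if squeeze else out


def train_cvae(
    data: ChunkedDataset,
    labels: Sequence[ConditionVector] | ConditionVector,
    config: CVAEConfig | None = None,
) -> CVAEModelState:
    """Train one CVAE per chunk with minibatch Adam on the negative ELBO.

    ``data`` must be fully imputed (no missing values) — run the
    preprocessing pipeline first.  All randomness (weight init, shuffling,
    reparameterization noise) derives from ``config.seed``; two runs with
    the same inputs produce identical weights.
    """
    cfg = config if config is not None else CVAEConfig()
    if isinstance(labels, ConditionVector):
        labels = [labels] * data.n_chunks
    if len(labels) != data.n_chunks:
        raise CVAEError("need one ConditionVector per chunk")
    vocab = list(labels[0].vocabulary) if labels else []
    state = CVAEModelState(
        config=cfg,
        vocabulary=vocab,
        chunk_cpg_ids=[list(c.cpg_ids) for c in data.chunks],
        weights=[],
    )
    children = np.random.SeedSequence(cfg.seed).spawn(max(data.n_chunks, 1))
    for k, chunk in enumerate(data.chunks):
        if np.isnan(chunk.values).any():
            raise CVAEError(
                f"chunk {k} contains missing values; run preprocess_pipeline first"
            )
        if chunk.n_samples < 2:
            raise CVAEError(f"chunk {k} has fewer than 2 samples")
        lab = labels[k]
        if list(lab.vocabulary) != vocab:
            raise CVAEError("vocabulary must be identical across chunks")
        present = set(lab.labels)
        for cond in vocab:
            if cond not in present:
                state.warnings.append(
                    f"condition {cond!r} has no samples in chunk {k}"
                )
        rng = np.random.default_rng(children[k])
        x = chunk.values
        y = lab.one_hot
        w = _init_weights(chunk.n_cpgs, len(vocab), cfg, rng)
        opt = _Adam(w, cfg.learning_rate)
        n = x.shape[0]
        bs = min(cfg.batch_size, n)
        trace: list[float] = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses, sizes = [], []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                g, loss = _train_step(w, x[idx], y[idx], cfg, rng)
                opt.step(w, g)
                losses.append(loss)
                sizes.append(len(idx))
            trace.append(float(np.average(losses, weights=sizes)))
        state.weights.append(w)
        state.loss_traces.append(trace)
    return state


def generate(
    state: CVAEModelState, condition: str, n_samples: int, seed: int = 0
) -> BetaMatrix:
    """Sample new methylomes for one cancer type.

    For every sample and chunk, draw z ~ N(0, I), decode with the
    condition's one-hot, and concatenate chunk outputs in chunk order.
    Sample IDs are ``<condition>_sim_<k>``.  Bit-identical for identical
    (state, condition, seed).
    """
    if condition not in state.vocabulary:
        raise CVAEError(
            f"unknown condition {condition!r}; vocabulary: {state.vocabulary}"
        )
    if n_samples < 1:
        raise CVAEError("n_samples must be >= 1")
    children = np.random.SeedSequence(seed).spawn(max(state.n_chunks, 1))
    blocks = []
    for k in range(state.n_chunks):
        rng = np.random.default_rng(children[k])
        z = rng.standard_normal((n_samples, state.config.latent_dim))
        blocks.append(decode(z, condition, state, chunk=k))
    values = np.concatenate(blocks, axis=1)
    sample_ids = [f"{condition}_sim_{k}" for k in range(n_samples)]
    return BetaMatrix(sample_ids, state.cpg_ids, values)


# -------------------------------------------------------------- serialization

def save_state(state: CVAEModelState, path: str | Path) -> None:
    """Persist a trained model as a directory (metadata JSON + NPZ weights)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": _STATE_VERSION,
        "config": asdict(state.config),
        "vocabulary": state.vocabulary,
        "chunk_cpg_ids": state.chunk_cpg_ids,
        "loss_traces": state.loss_traces,
        "warnings": state.warnings,
    }
    (path / "meta.json").write_text(json.dumps(meta))
    arrays = {
        f"c{k}/{name}": arr
        for k, w in enumerate(state.weights)
        for name, arr in w.items()
    }
    np.savez(path / "weights.npz", **arrays)


def load_state(path: str | Path) -> CVAEModelState:
    """Load a saved model; generation from it is bit-identical to pre-save."""
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
        if meta.get("version") != _STATE_VERSION:
            raise ModelIOError(
                f"model state version {meta.get('version')} not supported"
            )
        cfgd = meta["config"]
        for key in ("encoder_hidden", "activation_plan"):
            cfgd[key] = tuple(cfgd[key])
        if cfgd.get("decoder_hidden") is not None:
            cfgd["decoder_hidden"] = tuple(cfgd["decoder_hidden"])
        cfg = CVAEConfig(**cfgd)
        npz = np.load(path / "weights.npz")
        weights: list[dict[str, np.ndarray]] = [
            {} for _ in meta["chunk_cpg_ids"]
        ]
        for key in npz.files:
            ck, name = key.split("/", 1)
            weights[int(ck[1:])][name] = npz[key]
    except ModelIOError:
        raise
    except (OSError, KeyError, ValueError, json.JSONDecodeError,
            zipfile.BadZipFile) as e:
        raise ModelIOError(f"corrupt or unreadable model state at {path}: {e}") from e
    return CVAEModelState(
        config=cfg,
        vocabulary=list(meta["vocabulary"]),
        chunk_cpg_ids=[list(c) for c in meta["chunk_cpg_ids"]],
        weights=weights,
        loss_traces=[list(t) for t in meta["loss_traces"]],
        warnings=list(meta["warnings"]),
    )
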