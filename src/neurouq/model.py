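"""Permutation-invariant transformer decoder over variable-size neural populations.

The model treats each neuron as a token whose features are the 9 activity
frames of the decoding window.  There is deliberately no positional encoding:
self-attention is permutation-equivariant over tokens and the final max-pool
over the neuron axis is permutation-invariant, so the class probabilities do
not depend on neuron order and populations of any size can be decoded with the
same weights.

Pipeline (pre-norm blocks)::

    affine encoder + GeLU -> [ LN -> multi-head self-attention -> dropout ->
    residual -> LN -> feed-forward (GeLU) -> dropout -> residual ] x n_blocks
    -> element-wise max over neurons -> feed-forward head -> softmax

Dropout sites ("embedding" after the encoder, "attention" on the attention
probabilities, "residual" after the attention output and after the FFN output)
are active in ``train`` and ``mc_dropout`` modes only.

Evaluation mode uses order-canonical reductions (per-sample, with sorted
summation over the token axis) so that permuting neurons reproduces the output
bit for bit, and padding a batch never changes a sample's prediction.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import erf
from scipy import stats

from . import _autograd as ag

__all__ = [
    "ModelConfig",
    "Checkpoint",
    "init_params",
    "forward",
    "predict_proba",
    "train_model",
    "evaluate",
    "holdout_protocol",
    "pad_batch",
]

_SQRT2 = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyper-parameters of the neuron transformer.

    Defaults follow the training regimen used throughout the package: latent
    width 24 (within the 9-30 range the encoder is designed for), two
    transformer blocks, one attention head, all three dropout probabilities at
    0.1, Adam with learning rate 1e-4 for 20,000 iterations with batch sizes
    64/16/16 for train/validation/test.
    """

    latent_dim: int = 24
    n_blocks: int = 2
    n_heads: int = 1
    dropout_embed: float = 0.1
    dropout_residual: float = 0.1
    dropout_attention: float = 0.1
    ffn_mult: int = 4
    n_features: int = 9
    learning_rate: float = 1e-4
    n_iterations: int = 20_000
    batch_train: int = 64
    batch_val: int = 16
    batch_test: int = 16
    eval_every: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.latent_dim % self.n_heads != 0:
            raise ValueError("latent_dim must be divisible by n_heads")
        for p in (self.dropout_embed, self.dropout_residual, self.dropout_attention):
            if not (0.0 <= p < 1.0):
                raise ValueError("dropout probabilities must lie in [0, 1)")


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> dict:
    """Seeded fan-in-scaled Gaussian initialisation; biases zero, LN affine identity."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d, f = config.latent_dim, config.n_features
    dff = config.ffn_mult * d

    def w(nin, nout):
        return rng.normal(0.0, 1.0 / np.sqrt(nin), size=(nin, nout))

    p = {"enc_w": w(f, d), "enc_b": np.zeros(d)}
    for i in range(config.n_blocks):
        p[f"b{i}_ln1_g"] = np.ones(d)
        p[f"b{i}_ln1_b"] = np.zeros(d)
        for nm in ("q", "k", "v", "o"):
            p[f"b{i}_w{nm}"] = w(d, d)
            p[f"b{i}_b{nm}"] = np.zeros(d)
        p[f"b{i}_ln2_g"] = np.ones(d)
        p[f"b{i}_ln2_b"] = np.zeros(d)
        p[f"b{i}_w1"] = w(d, dff)
        p[f"b{i}_b1"] = np.zeros(dff)
        p[f"b{i}_w2"] = w(dff, d)
        p[f"b{i}_b2"] = np.zeros(d)
    p["head_w1"] = w(d, d)
    p["head_b1"] = np.zeros(d)
    p["head_w2"] = w(d, 2)
    p["head_b2"] = np.zeros(2)
    return p


@dataclass
class Checkpoint:
    """Parameter snapshot at the iteration with minimal validation cross-entropy."""

    params: dict
    best_val_cross_entropy: float
    iteration_of_best: int
    config: ModelConfig

    def save(self, path: str) -> None:
        np.savez(path if path.endswith(".npz") else path + ".npz", **self.params)
        side = (path[:-4] if path.endswith(".npz") else path) + ".json"
        with open(side, "w") as fh:
            json.dump(
                {
                    "best_val_cross_entropy": self.best_val_cross_entropy,
                    "iteration_of_best": self.iteration_of_best,
                    "config": asdict(self.config),
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str) -> "Checkpoint":
        base = path[:-4] if path.endswith(".npz") else path
        with np.load(base + ".npz") as z:
            params = {k: z[k] for k in z.files}
        with open(base + ".json") as fh:
            meta = json.load(fh)
        return cls(
            params=params,
            best_val_cross_entropy=meta["best_val_cross_entropy"],
            iteration_of_best=meta["iteration_of_best"],
            config=ModelConfig(**meta["config"]),
        )


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def pad_batch(segments: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad a list of (n_i, F) segments to (B, max n_i, F) plus a token mask."""
    if len(segments) == 0:
        raise ValueError("empty batch")
    f = segments[0].shape[1]
    nmax = max(s.shape[0] for s in segments)
    x = np.zeros((len(segments), nmax, f))
    mask = np.zeros((len(segments), nmax), dtype=bool)
    for i, s in enumerate(segments):
        x[i, : s.shape[0]] = s
        mask[i, : s.shape[0]] = True
    return x, mask


def _check_segment(seg: np.ndarray, config: ModelConfig) -> np.ndarray:
    seg = np.asarray(seg, dtype=np.float64)
    if seg.ndim != 2 or seg.shape[0] < 1:
        raise ValueError("segment must be a (n_neurons >= 1, n_frames) matrix")
    if seg.shape[1] != config.n_features:
        raise ValueError(
            f"segment has {seg.shape[1]} features per neuron; "
            f"encoder expects {config.n_features}"
        )
    return seg


# ---------------------------------------------------------------------------
# fast batched forward (plain NumPy; used for MC dropout and validation)
# ---------------------------------------------------------------------------

def _gelu_np(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _ln_np(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.sqrt(x.var(axis=-1, keepdims=True) + eps)
    return g * (x - mu) / sd + b


def _softmax_np(x):
    m = np.max(x, axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x - m)
    return e / e.sum(axis=-1, keepdims=True)


def _drop_mask(rng, p, shape):
    return (rng.random(shape) >= p) / (1.0 - p)


def forward_batch(
    params: Mapping[str, np.ndarray],
    x: np.ndarray,
    mask: np.ndarray,
    config: ModelConfig,
    dropout: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Batched class probabilities (B, 2); BLAS reductions, optional dropout."""
    if dropout and rng is None:
        raise ValueError("dropout requires an rng")
    b, n, _ = x.shape
    d, h = config.latent_dim, config.n_heads
    dh = d // h
    hdn = _gelu_np(x @ params["enc_w"] + params["enc_b"])
    if dropout and config.dropout_embed > 0:
        hdn = hdn * _drop_mask(rng, config.dropout_embed, hdn.shape)
    addmask = np.where(mask, 0.0, -np.inf)[:, None, None, :]

    def heads(t):
        return t.reshape(b, n, h, dh).transpose(0, 2, 1, 3)

    for i in range(config.n_blocks):
        a = _ln_np(hdn, params[f"b{i}_ln1_g"], params[f"b{i}_ln1_b"])
        q = heads(a @ params[f"b{i}_wq"] + params[f"b{i}_bq"])
        k = heads(a @ params[f"b{i}_wk"] + params[f"b{i}_bk"])
        v = heads(a @ params[f"b{i}_wv"] + params[f"b{i}_bv"])
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(dh) + addmask
        w = _softmax_np(scores)
        if dropout and config.dropout_attention > 0:
            w = w * _drop_mask(rng, config.dropout_attention, w.shape)
        ctx = (w @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        o = ctx @ params[f"b{i}_wo"] + params[f"b{i}_bo"]
        if dropout and config.dropout_residual > 0:
            o = o * _drop_mask(rng, config.dropout_residual, o.shape)
        hdn = hdn + o
        a2 = _ln_np(hdn, params[f"b{i}_ln2_g"], params[f"b{i}_ln2_b"])
        f = _gelu_np(a2 @ params[f"b{i}_w1"] + params[f"b{i}_b1"])
        f = f @ params[f"b{i}_w2"] + params[f"b{i}_b2"]
        if dropout and config.dropout_residual > 0:
            f = f * _drop_mask(rng, config.dropout_residual, f.shape)
        hdn = hdn + f
    pooled = np.max(np.where(mask[..., None], hdn, -np.inf), axis=1)
    z = _gelu_np(pooled @ params["head_w1"] + params["head_b1"])
    z = z @ params["head_w2"] + params["head_b2"]
    return _softmax_np(z)


# ---------------------------------------------------------------------------
# order-canonical evaluation forward (per sample, bit-stable under permutation)
# ---------------------------------------------------------------------------

def _rlinear(x, w, b):
    # elementwise-reduced affine map: each token's output is independent of
    # how many tokens there are and of their order
    return np.add.reduce(x[..., :, None] * w, axis=-2) + b


def _sortsum(a, axis):
    # canonical-order summation: depends on the multiset of addends only
    return np.sort(a, axis=axis).sum(axis=axis)


def _forward_eval_single(params, x, config: ModelConfig) -> np.ndarray:
    n = x.shape[0]
    d, h = config.latent_dim, config.n_heads
    dh = d // h
    hdn = _gelu_np(_rlinear(x, params["enc_w"], params["enc_b"]))
    for i in range(config.n_blocks):
        a = _ln_np(hdn, params[f"b{i}_ln1_g"], params[f"b{i}_ln1_b"])
        q = _rlinear(a, params[f"b{i}_wq"], params[f"b{i}_bq"]).reshape(n, h, dh).transpose(1, 0, 2)
        k = _rlinear(a, params[f"b{i}_wk"], params[f"b{i}_bk"]).reshape(n, h, dh).transpose(1, 0, 2)
        v = _rlinear(a, params[f"b{i}_wv"], params[f"b{i}_bv"]).reshape(n, h, dh).transpose(1, 0, 2)
        scores = np.add.reduce(q[:, :, None, :] * k[:, None, :, :], axis=-1) / np.sqrt(dh)
        m = scores.max(axis=-1, keepdims=True)
        e = np.exp(scores - m)
        denom = _sortsum(e, axis=-1)[..., None]
        w = e / denom
        ctx = _sortsum(w[..., None] * v[:, None, :, :], axis=-2)  # (h, n, dh)
        ctx = ctx.transpose(1, 0, 2).reshape(n, d)
        hdn = hdn + _rlinear(ctx, params[f"b{i}_wo"], params[f"b{i}_bo"])
        a2 = _ln_np(hdn, params[f"b{i}_ln2_g"], params[f"b{i}_ln2_b"])
        f = _gelu_np(_rlinear(a2, params[f"b{i}_w1"], params[f"b{i}_b1"]))
        f = _rlinear(f, params[f"b{i}_w2"], params[f"b{i}_b2"])
        hdn = hdn + f
    pooled = np.max(hdn, axis=0)
    z = _gelu_np(pooled @ params["head_w1"] + params["head_b1"])
    z = z @ params["head_w2"] + params["head_b2"]
    return _softmax_np(z)


# ---------------------------------------------------------------------------
# autodiff forward (training)
# ---------------------------------------------------------------------------

def _forward_ad(
    tparams: Mapping[str, ag.Tensor],
    x: np.ndarray,
    mask: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> ag.Tensor:
    """Training-mode logits (B, 2) as an autodiff Tensor, dropout active."""
    b, n, _ = x.shape
    d, h = config.latent_dim, config.n_heads
    dh = d // h
    xt = ag.Tensor(x)
    hdn = ag.gelu(ag.linear(xt, tparams["enc_w"], tparams["enc_b"]))
    if config.dropout_embed > 0:
        hdn = ag.mul_const(hdn, _drop_mask(rng, config.dropout_embed, hdn.shape))
    addmask = np.where(mask, 0.0, -np.inf)[:, None, None, :]

    def heads(t):
        return ag.transpose(ag.reshape(t, (b, n, h, dh)), (0, 2, 1, 3))

    for i in range(config.n_blocks):
        a = ag.layer_norm(hdn, tparams[f"b{i}_ln1_g"], tparams[f"b{i}_ln1_b"])
        q = heads(ag.linear(a, tparams[f"b{i}_wq"], tparams[f"b{i}_bq"]))
        k = heads(ag.linear(a, tparams[f"b{i}_wk"], tparams[f"b{i}_bk"]))
        v = heads(ag.linear(a, tparams[f"b{i}_wv"], tparams[f"b{i}_bv"]))
        scores = ag.mul_const(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        scores = ag.add_const(scores, addmask)
        w = ag.softmax_last(scores)
        if config.dropout_attention > 0:
            w = ag.mul_const(w, _drop_mask(rng, config.dropout_attention, w.shape))
        ctx = ag.reshape(ag.transpose(ag.matmul(w, v), (0, 2, 1, 3)), (b, n, d))
        o = ag.linear(ctx, tparams[f"b{i}_wo"], tparams[f"b{i}_bo"])
        if config.dropout_residual > 0:
            o = ag.mul_const(o, _drop_mask(rng, config.dropout_residual, o.shape))
        hdn = ag.add(hdn, o)
        a2 = ag.layer_norm(hdn, tparams[f"b{i}_ln2_g"], tparams[f"b{i}_ln2_b"])
        f = ag.gelu(ag.linear(a2, tparams[f"b{i}_w1"], tparams[f"b{i}_b1"]))
        f = ag.linear(f, tparams[f"b{i}_w2"], tparams[f"b{i}_b2"])
        if config.dropout_residual > 0:
            f = ag.mul_const(f, _drop_mask(rng, config.dropout_residual, f.shape))
        hdn = ag.add(hdn, f)
    pool_mask = np.where(mask[..., None], 0.0, -np.inf)
    pooled = ag.max_last_axis2(ag.add_const(hdn, pool_mask))  # (B, D)
    z = ag.gelu(ag.linear(pooled, tparams["head_w1"], tparams["head_b1"]))
    z = ag.linear(z, tparams["head_w2"], tparams["head_b2"])
    return z


# ---------------------------------------------------------------------------
# public forward
# ---------------------------------------------------------------------------

def _as_params(model) -> tuple[Mapping[str, np.ndarray], ModelConfig | None]:
    if isinstance(model, Checkpoint):
        return model.params, model.config
    return model, None


def forward(
    model,
    segment: np.ndarray,
    config: ModelConfig | None = None,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities (length 2) for one (n_neurons, 9) segment.

    ``mode`` is ``eval`` (deterministic, order-canonical reductions so neuron
    permutations are bit-identical), ``train`` or ``mc_dropout`` (dropout
    active, one stochastic pass).
    """
    params, ckpt_cfg = _as_params(model)
    config = config or ckpt_cfg
    if config is None:
        raise ValueError("a ModelConfig is required when passing raw parameters")
    seg = _check_segment(segment, config)
    if mode == "eval":
        return _forward_eval_single(params, seg, config)
    if mode in ("train", "mc_dropout"):
        if rng is None:
            rng = np.random.default_rng()
        x, mask = pad_batch([seg])
        return forward_batch(params, x, mask, config, dropout=True, rng=rng)[0]
    raise ValueError(f"unknown mode {mode!r}")


def predict_proba(model, segments: Iterable[np.ndarray], config: ModelConfig | None = None) -> np.ndarray:
    """Deterministic eval-mode probabilities for a list of segments, (n, 2)."""
    params, ckpt_cfg = _as_params(model)
    config = config or ckpt_cfg
    return np.stack([_forward_eval_single(params, _check_segment(s, config), config) for s in segments])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _segments_labels(samples) -> tuple[list[np.ndarray], np.ndarray]:
    segs = [np.asarray(s.segment, dtype=np.float64) for s in samples]
    labels = np.asarray([s.label for s in samples])
    if labels.dtype == object or np.any([l is None for l in [s.label for s in samples]]):
        raise ValueError("all samples must be labeled")
    return segs, labels.astype(int)


def _val_cross_entropy(params, segs, labels, config) -> float:
    total = 0.0
    for i in range(0, len(segs), config.batch_val):
        chunk = segs[i : i + config.batch_val]
        x, mask = pad_batch(chunk)
        p = forward_batch(params, x, mask, config, dropout=False)
        p1 = np.clip(p[np.arange(len(chunk)), labels[i : i + config.batch_val]], 1e-12, None)
        total += -np.log(p1).sum()
    return total / len(segs)


def train_model(
    train_samples: Sequence,
    val_samples: Sequence,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> Checkpoint:
    """Adam optimisation of the cross-entropy; returns the minimal-validation-CE snapshot.

    Validation cross-entropy is evaluated at initialisation, every
    ``config.eval_every`` iterations and after the last iteration; on ties the
    earlier iteration is kept, so the checkpoint can never come from a later
    iteration with higher validation loss.
    """
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("train and validation sets must be nonempty")
    tsegs, tlabels = _segments_labels(train_samples)
    vsegs, vlabels = _segments_labels(val_samples)
    if len(np.unique(tlabels)) < 2:
        raise ValueError("training set contains a single class")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    params = init_params(config, rng)
    tparams = {k: ag.Tensor(v) for k, v in params.items()}
    mstate = {k: np.zeros_like(v) for k, v in params.items()}
    vstate = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def snapshot():
        return {k: t.value.copy() for k, t in tparams.items()}

    best_ce = _val_cross_entropy({k: t.value for k, t in tparams.items()}, vsegs, vlabels, config)
    best_params = snapshot()
    best_iter = 0

    for it in range(1, config.n_iterations + 1):
        idx = rng.integers(0, len(tsegs), size=min(config.batch_train, len(tsegs)))
        x, mask = pad_batch([tsegs[j] for j in idx])
        logits = _forward_ad(tparams, x, mask, config, rng)
        loss = ag.cross_entropy_with_logits(logits, tlabels[idx])
        ag.backward(loss)
        for k, t in tparams.items():
            g = t.grad if t.grad is not None else np.zeros_like(t.value)
            mstate[k] = beta1 * mstate[k] + (1 - beta1) * g
            vstate[k] = beta2 * vstate[k] + (1 - beta2) * g * g
            mhat = mstate[k] / (1 - beta1 ** it)
            vhat = vstate[k] / (1 - beta2 ** it)
            t.value = t.value - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            t.grad = None
        if it % config.eval_every == 0 or it == config.n_iterations:
            ce = _val_cross_entropy({k: t.value for k, t in tparams.items()}, vsegs, vlabels, config)
            if ce < best_ce:
                best_ce, best_params, best_iter = ce, snapshot(), it

    return Checkpoint(
        params=best_params,
        best_val_cross_entropy=float(best_ce),
        iteration_of_best=best_iter,
        config=config,
    )


# ---------------------------------------------------------------------------
# evaluation and hold-out protocols
# ---------------------------------------------------------------------------

def evaluate(checkpoint: Checkpoint, test_samples: Sequence) -> dict:
    """Deterministic accuracy (dropout off) with a per-class breakdown."""
    if len(test_samples) == 0:
        raise ValueError("test set is empty")
    segs, labels = _segments_labels(test_samples)
    probs = predict_proba(checkpoint, segs)
    pred = probs.argmax(axis=1)
    out = {
        "accuracy": float((pred == labels).mean()),
        "n": len(labels),
        "predictions": pred,
        "probabilities": probs,
        "per_class": {},
    }
    for c in np.unique(labels):
        sel = labels == c
        out["per_class"][int(c)] = float((pred[sel] == c).mean())
    return out


def _shuffle_neurons(samples, rng):
    out = []
    for s in samples:
        seg = np.asarray(s.segment)
        s2 = copy.copy(s)
        s2.segment = seg[rng.permutation(seg.shape[0])]
        out.append(s2)
    return out


def holdout_protocol(
    groups: Mapping,
    holdout_key,
    config: ModelConfig,
    n_repeats: int = 10,
    shuffled_control: bool = False,
    val_frac: float = 0.2,
) -> dict:
    """Leave-one-group-out decoding (group = day or mouse).

    Trains on every group except ``holdout_key`` (with an internal
    train/validation split) and evaluates on the held-out group, repeated over
    ``n_repeats`` seeds.  With ``shuffled_control`` the held-out segments are
    also evaluated with their neuron rows shuffled and the accuracy difference
    tested with a two-sample t-test (exact permutation invariance of the eval
    forward makes this difference identically zero by construction).
    """
    from sklearn.model_selection import train_test_split

    if len(groups) < 2:
        raise ValueError("need at least 2 distinct hold-out groups")
    if holdout_key not in groups:
        raise KeyError(f"{holdout_key!r} not among groups")
    test_samples = list(groups[holdout_key])
    if len(test_samples) == 0:
        raise ValueError("held-out group is empty")
    pool = [s for k, v in groups.items() if k != holdout_key for s in v]
    labels = [s.label for s in pool]

    accs, shuf_accs = [], []
    for r in range(n_repeats):
        seed = config.seed + r
        tr_idx, va_idx = train_test_split(
            np.arange(len(pool)), test_size=val_frac, stratify=labels, random_state=seed
        )
        cfg = replace(config, seed=seed)
        ckpt = train_model([pool[i] for i in tr_idx], [pool[i] for i in va_idx], cfg)
        accs.append(evaluate(ckpt, test_samples)["accuracy"])
        if shuffled_control:
            rng = np.random.default_rng(seed + 10_000)
            shuf_accs.append(evaluate(ckpt, _shuffle_neurons(test_samples, rng))["accuracy"])

    out = {"accuracy": np.asarray(accs), "mean_accuracy": float(np.mean(accs))}
    if shuffled_control:
        out["shuffled_accuracy"] = np.asarray(shuf_accs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance difference yields nan p
            t, p = stats.ttest_ind(accs, shuf_accs)
        out["shuffle_ttest"] = {"t": float(t), "p": float(p)}
    return out
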