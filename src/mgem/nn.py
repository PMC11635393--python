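"""Minimal transformer encoder-regressor in pure numpy.

A deliberately small pre-norm transformer (token embedding + sinusoidal and
relative-position encodings, multi-head self-attention, ReLU feed-forward
blocks, start-token linear readout) with hand-written reverse-mode
gradients and an Adam optimizer. Two layers by two heads at model_dim 64 is
small enough that explicit gradients are both tractable and fast on a CPU.

The relative-position channel (position / sequence length) is added because
the regression tasks this package targets carry signal tied to relative
sequence position (e.g. an N-terminal region defined as a fraction of the
length), which absolute sinusoidal encodings alone represent poorly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import PAD_TOKEN, VOCAB_SIZE

_NEG = np.float32(-1e9)
_EPS = 1e-5


@dataclass
class NNConfig:
    layers: int = 2
    heads: int = 2
    model_dim: int = 64
    ffn_mult: int = 4
    max_len: int = 1024

    def __post_init__(self) -> None:
        if self.layers < 1 or self.heads < 1:
            raise ValueError("layers and heads must be >= 1")
        if self.model_dim % self.heads:
            raise ValueError("model_dim must be divisible by heads")


def sinusoidal_encoding(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / (10000.0 ** (2 * i / dim))
    enc = np.zeros((max_len, dim), dtype=np.float32)
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc


def init_params(cfg: NNConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    D, F = cfg.model_dim, cfg.ffn_mult * cfg.model_dim

    def mat(shape, scale):
        return (rng.normal(0.0, scale, size=shape)).astype(np.float32)

    p: dict[str, np.ndarray] = {
        "emb": mat((VOCAB_SIZE, D), 0.02),
        "rel": mat((D,), 0.02),
        "out_w": mat((D,), D**-0.5),
        "out_b": np.zeros(1, dtype=np.float32),
        "lnf_g": np.ones(D, dtype=np.float32),
        "lnf_b": np.zeros(D, dtype=np.float32),
    }
    for l in range(cfg.layers):
        for name in ("q", "k", "v", "o"):
            p[f"l{l}_W{name}"] = mat((D, D), D**-0.5)
            p[f"l{l}_b{name}"] = np.zeros(D, dtype=np.float32)
        p[f"l{l}_W1"] = mat((D, F), D**-0.5)
        p[f"l{l}_b1"] = np.zeros(F, dtype=np.float32)
        p[f"l{l}_W2"] = mat((F, D), F**-0.5)
        p[f"l{l}_b2"] = np.zeros(D, dtype=np.float32)
        for ln in ("ln1", "ln2"):
            p[f"l{l}_{ln}_g"] = np.ones(D, dtype=np.float32)
            p[f"l{l}_{ln}_b"] = np.zeros(D, dtype=np.float32)
    return p


def _layernorm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv)


def _layernorm_back(dy, g, cache):
    xhat, inv = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    m = dxhat.mean(-1, keepdims=True)
    mxh = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m - xhat * mxh)
    return dx, dg, db


def forward(
    params: dict[str, np.ndarray],
    cfg: NNConfig,
    ids: np.ndarray,
    rel: np.ndarray,
    mask: np.ndarray,
    want_cache: bool = True,
):
    """Forward pass.

    ids/rel/mask: (B, T) int token ids, float32 relative positions, float32
    validity mask (1 = real token). Returns (predictions (B,), cache).
    """
    B, T = ids.shape
    D, H = cfg.model_dim, cfg.heads
    Dh = D // H
    scale = np.float32(Dh**-0.5)

    x = params["emb"][ids] + sinusoidal_encoding(T, D)[None] \
        + rel[:, :, None].astype(np.float32) * params["rel"]
    key_bias = ((1.0 - mask) * _NEG).astype(np.float32)[:, None, None, :]
    cache: dict = {"ids": ids, "rel": rel, "mask": mask, "x0": x}
    for l in range(cfg.layers):
        pre = x
        a, ln1c = _layernorm(x, params[f"l{l}_ln1_g"], params[f"l{l}_ln1_b"])
        q = a @ params[f"l{l}_Wq"] + params[f"l{l}_bq"]
        k = a @ params[f"l{l}_Wk"] + params[f"l{l}_bk"]
        v = a @ params[f"l{l}_Wv"] + params[f"l{l}_bv"]
        qh = q.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        s = qh @ kh.swapaxes(-1, -2) * scale + key_bias
        s -= s.max(-1, keepdims=True)
        e = np.exp(s)
        att = e / e.sum(-1, keepdims=True)
        oh = att @ vh
        o = oh.transpose(0, 2, 1, 3).reshape(B, T, D)
        proj = o @ params[f"l{l}_Wo"] + params[f"l{l}_bo"]
        x = pre + proj
        mid = x
        f, ln2c = _layernorm(x, params[f"l{l}_ln2_g"], params[f"l{l}_ln2_b"])
        h1 = f @ params[f"l{l}_W1"] + params[f"l{l}_b1"]
        hr = np.maximum(h1, 0.0)
        ff = hr @ params[f"l{l}_W2"] + params[f"l{l}_b2"]
        x = mid + ff
        if want_cache:
            cache[f"l{l}"] = (pre, a, ln1c, qh, kh, vh, att, o, mid, f, ln2c, hr)
    z, lnfc = _layernorm(x, params["lnf_g"], params["lnf_b"])
    pred = z[:, 0, :] @ params["out_w"] + params["out_b"]
    if want_cache:
        cache["final"] = (z, lnfc, x)
        cache["attn"] = None
    return pred, cache


def attention_tensors(
    params: dict[str, np.ndarray], cfg: NNConfig, ids: np.ndarray,
    rel: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Row-stochastic attention matrices, shape (layers, heads, T, T), B=1."""
    B, T = ids.shape
    D, H = cfg.model_dim, cfg.heads
    Dh = D // H
    scale = np.float32(Dh**-0.5)
    x = params["emb"][ids] + sinusoidal_encoding(T, D)[None] \
        + rel[:, :, None].astype(np.float32) * params["rel"]
    key_bias = ((1.0 - mask) * _NEG).astype(np.float32)[:, None, None, :]
    mats = []
    for l in range(cfg.layers):
        pre = x
        a, _ = _layernorm(x, params[f"l{l}_ln1_g"], params[f"l{l}_ln1_b"])
        q = a @ params[f"l{l}_Wq"] + params[f"l{l}_bq"]
        k = a @ params[f"l{l}_Wk"] + params[f"l{l}_bk"]
        v = a @ params[f"l{l}_Wv"] + params[f"l{l}_bv"]
        qh = q.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        s = qh @ kh.swapaxes(-1, -2) * scale + key_bias
        s -= s.max(-1, keepdims=True)
        e = np.exp(s)
        att = e / e.sum(-1, keepdims=True)
        mats.append(att[0])
        oh = att @ vh
        o = oh.transpose(0, 2, 1, 3).reshape(B, T, D)
        x = pre + o @ params[f"l{l}_Wo"] + params[f"l{l}_bo"]
        mid = x
        f, _ = _layernorm(x, params[f"l{l}_ln2_g"], params[f"l{l}_ln2_b"])
        hr = np.maximum(f @ params[f"l{l}_W1"] + params[f"l{l}_b1"], 0.0)
        x = mid + hr @ params[f"l{l}_W2"] + params[f"l{l}_b2"]
    return np.stack(mats)


def final_embeddings(
    params: dict[str, np.ndarray], cfg: NNConfig, ids: np.ndarray,
    rel: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Final-layer-norm token representations, shape (B, T, D)."""
    pred, cache = forward(params, cfg, ids, rel, mask, want_cache=True)
    return cache["final"][0]


def backward(
    params: dict[str, np.ndarray],
    cfg: NNConfig,
    cache: dict,
    dpred: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss given d(loss)/d(pred), shape (B,)."""
    B, T = cache["ids"].shape
    D, H = cfg.model_dim, cfg.heads
    Dh = D // H
    scale = np.float32(Dh**-0.5)
    g: dict[str, np.ndarray] = {}

    z, lnfc, x_final = cache["final"]
    dz = np.zeros_like(z)
    dz[:, 0, :] = dpred[:, None] * params["out_w"]
    g["out_w"] = dpred @ z[:, 0, :]
    g["out_b"] = dpred.sum(keepdims=True)
    dx, g["lnf_g"], g["lnf_b"] = _layernorm_back(dz, params["lnf_g"], lnfc)

    for l in reversed(range(cfg.layers)):
        pre, a, ln1c, qh, kh, vh, att, o, mid, f, ln2c, hr = cache[f"l{l}"]
        # FFN block: x = mid + relu(LN(mid) W1 + b1) W2 + b2
        dff = dx
        g[f"l{l}_W2"] = hr.reshape(-1, hr.shape[-1]).T @ dff.reshape(-1, D)
        g[f"l{l}_b2"] = dff.sum((0, 1))
        dhr = dff @ params[f"l{l}_W2"].T
        dh1 = dhr * (hr > 0)
        g[f"l{l}_W1"] = f.reshape(-1, D).T @ dh1.reshape(-1, dh1.shape[-1])
        g[f"l{l}_b1"] = dh1.sum((0, 1))
        df = dh1 @ params[f"l{l}_W1"].T
        dmid, g[f"l{l}_ln2_g"], g[f"l{l}_ln2_b"] = _layernorm_back(
            df, params[f"l{l}_ln2_g"], ln2c
        )
        dx = dx + dmid
        # attention block: mid = pre + (att @ v) Wo + bo
        dproj = dx
        g[f"l{l}_Wo"] = o.reshape(-1, D).T @ dproj.reshape(-1, D)
        g[f"l{l}_bo"] = dproj.sum((0, 1))
        do = dproj @ params[f"l{l}_Wo"].T
        doh = do.reshape(B, T, H, Dh).transpose(0, 2, 1, 3)
        datt = doh @ vh.swapaxes(-1, -2)
        dvh = att.swapaxes(-1, -2) @ doh
        ds = att * (datt - (datt * att).sum(-1, keepdims=True))
        dqh = ds @ kh * scale
        dkh = ds.swapaxes(-1, -2) @ qh * scale
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, D)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, D)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, D)
        g[f"l{l}_Wq"] = a.reshape(-1, D).T @ dq.reshape(-1, D)
        g[f"l{l}_bq"] = dq.sum((0, 1))
        g[f"l{l}_Wk"] = a.reshape(-1, D).T @ dk.reshape(-1, D)
        g[f"l{l}_bk"] = dk.sum((0, 1))
        g[f"l{l}_Wv"] = a.reshape(-1, D).T @ dv.reshape(-1, D)
        g[f"l{l}_bv"] = dv.sum((0, 1))
        da = dq @ params[f"l{l}_Wq"].T + dk @ params[f"l{l}_Wk"].T \
            + dv @ params[f"l{l}_Wv"].T
        dpre_ln, g[f"l{l}_ln1_g"], g[f"l{l}_ln1_b"] = _layernorm_back(
            da, params[f"l{l}_ln1_g"], ln1c
        )
        dx = dx + dpre_ln
    # embedding, relative-position channel
    g["rel"] = (dx * cache["rel"][:, :, None]).sum((0, 1))
    demb = np.zeros_like(params["emb"])
    np.add.at(demb, cache["ids"], dx)
    demb[PAD_TOKEN] = 0.0
    g["emb"] = demb
    return g


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             clip: float | None = 1.0) -> None:
        self.t += 1
        if clip is not None:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if norm > clip:
                grads = {k: g * (clip / norm) for k, g in grads.items()}
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, grad in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grad**2
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
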