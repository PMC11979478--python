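"""Minimal NumPy neural-network internals for the sequence encoder.

Implements a pre-LayerNorm Transformer encoder stack (sum of four embedding
channels -> L x [LN -> multi-head self-attention -> residual, LN -> feed-forward
-> residual]) with exact manual backpropagation, inverted dropout and Adam.
Everything is plain NumPy (float32 weights by default; any float dtype works,
which the gradient tests exploit with float64), so training is reproducible on
one CPU and desk-scale configurations (d_model 64, two layers) train in
seconds to minutes.

The public encoder API lives in :mod:`ehrsubtype.encoder`; this module only
knows about parameter dicts, id arrays and gradients.
"""

from __future__ import annotations

import numpy as np

_LN_EPS = 1e-5
_MASK_BIAS = -1e9


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def init_params(
    rng: np.random.Generator,
    n_codes: int,
    n_ages: int,
    n_years: int,
    n_visits: int,
    d_model: int,
    n_layers: int,
    d_ff: int,
    dtype=np.float32,
) -> dict[str, np.ndarray]:
    scale = 0.02

    def g(*shape):
        return rng.normal(0.0, scale, size=shape).astype(dtype)

    params: dict[str, np.ndarray] = {
        "emb_code": g(n_codes, d_model),
        "emb_age": g(n_ages, d_model),
        "emb_year": g(n_years, d_model),
        "emb_visit": g(n_visits, d_model),
    }
    for l in range(n_layers):
        p = f"l{l}_"
        params[p + "ln1_g"] = np.ones(d_model, dtype=dtype)
        params[p + "ln1_b"] = np.zeros(d_model, dtype=dtype)
        for w in ("Wq", "Wk", "Wv", "Wo"):
            params[p + w] = g(d_model, d_model)
        for b in ("bq", "bk", "bv", "bo"):
            params[p + b] = np.zeros(d_model, dtype=dtype)
        params[p + "ln2_g"] = np.ones(d_model, dtype=dtype)
        params[p + "ln2_b"] = np.zeros(d_model, dtype=dtype)
        params[p + "W1"] = g(d_model, d_ff)
        params[p + "b1"] = np.zeros(d_ff, dtype=dtype)
        params[p + "W2"] = g(d_ff, d_model)
        params[p + "b2"] = np.zeros(d_model, dtype=dtype)
    return params


def zeros_like_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Primitive layers
# ---------------------------------------------------------------------------

def _layernorm_fwd(x, gamma, beta):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xn = xc * inv
    return gamma * xn + beta, (xn, inv, gamma)


def _layernorm_bwd(dy, cache):
    xn, inv, gamma = cache
    dgamma = (dy * xn).sum(axis=tuple(range(dy.ndim - 1)))
    dbeta = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxn = dy * gamma
    dx = inv * (
        dxn
        - dxn.mean(-1, keepdims=True)
        - xn * (dxn * xn).mean(-1, keepdims=True)
    )
    return dx, dgamma, dbeta


def _dropout_fwd(x, p, rng):
    if p <= 0.0 or rng is None:
        return x, None
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(x.dtype)
    return x * mask, mask


def _dropout_bwd(dy, mask):
    return dy if mask is None else dy * mask


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


# ---------------------------------------------------------------------------
# Full-stack forward / backward
# ---------------------------------------------------------------------------

def forward(
    params: dict[str, np.ndarray],
    token_ids: np.ndarray,
    age_ids: np.ndarray,
    year_ids: np.ndarray,
    visit_ids: np.ndarray,
    mask: np.ndarray,
    n_layers: int,
    n_heads: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Run the encoder stack on a padded batch.

    Returns ``(layers, cache)`` where ``layers[0]`` is the summed embedding
    output and ``layers[l]`` the output of encoder layer ``l`` (each
    ``(B, T, d_model)``).  ``mask`` is 1.0 at real positions, 0.0 at padding;
    padded keys are excluded from attention.  Pass an ``rng`` to enable
    dropout (training mode); without it the forward pass is deterministic.
    """
    x = (
        params["emb_code"][token_ids]
        + params["emb_age"][age_ids]
        + params["emb_year"][year_ids]
        + params["emb_visit"][visit_ids]
    )
    x, emb_drop = _dropout_fwd(x, dropout, rng)
    layers = [x]
    mask = mask.astype(x.dtype)
    key_bias = (1.0 - mask[:, None, None, :]) * x.dtype.type(_MASK_BIAS)
    caches = []
    b_sz, t_sz, d_model = x.shape
    dh = d_model // n_heads
    inv_sqrt_dh = x.dtype.type(1.0 / np.sqrt(dh))
    # all dense projections run as single (B*T, d) GEMMs; only the attention
    # score/context products stay batched per head
    for l in range(n_layers):
        p = f"l{l}_"
        h, ln1_cache = _layernorm_fwd(x, params[p + "ln1_g"], params[p + "ln1_b"])
        h2d = h.reshape(b_sz * t_sz, d_model)
        q = _split_heads(
            (h2d @ params[p + "Wq"] + params[p + "bq"]).reshape(b_sz, t_sz, d_model),
            n_heads,
        )
        k = _split_heads(
            (h2d @ params[p + "Wk"] + params[p + "bk"]).reshape(b_sz, t_sz, d_model),
            n_heads,
        )
        v = _split_heads(
            (h2d @ params[p + "Wv"] + params[p + "bv"]).reshape(b_sz, t_sz, d_model),
            n_heads,
        )
        scores = q @ k.swapaxes(-1, -2) * inv_sqrt_dh + key_bias
        scores -= scores.max(-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(-1, keepdims=True)
        ctx = _merge_heads(attn @ v)
        o = (
            ctx.reshape(b_sz * t_sz, d_model) @ params[p + "Wo"] + params[p + "bo"]
        ).reshape(b_sz, t_sz, d_model)
        o, attn_drop = _dropout_fwd(o, dropout, rng)
        x_mid = x + o

        h2, ln2_cache = _layernorm_fwd(
            x_mid, params[p + "ln2_g"], params[p + "ln2_b"]
        )
        u = h2.reshape(b_sz * t_sz, d_model) @ params[p + "W1"] + params[p + "b1"]
        r = np.maximum(u, 0.0)
        rd, ffn_drop = _dropout_fwd(r, dropout, rng)  # rd stays (B*T, d_ff)
        x = x_mid + (rd @ params[p + "W2"] + params[p + "b2"]).reshape(
            b_sz, t_sz, d_model
        )

        layers.append(x)
        caches.append(
            dict(
                ln1=ln1_cache, h=h, q=q, k=k, v=v, attn=attn, ctx=ctx,
                attn_drop=attn_drop, ln2=ln2_cache, h2=h2, u=u, rd=rd,
                ffn_drop=ffn_drop,
            )
        )
    cache = dict(
        caches=caches,
        emb_drop=emb_drop,
        ids=(token_ids, age_ids, year_ids, visit_ids),
        n_heads=n_heads,
        n_layers=n_layers,
    )
    return layers, cache


def backward(
    params: dict[str, np.ndarray],
    cache: dict,
    d_layers: dict[int, np.ndarray],
    grads: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Backpropagate gradients injected at any subset of layer outputs.

    ``d_layers`` maps layer index (0 = embedding output, l = encoder layer l)
    to the gradient of the loss with respect to that layer's output.  Returns
    (and accumulates into) a parameter-gradient dict.
    """
    if grads is None:
        grads = zeros_like_params(params)
    n_layers = cache["n_layers"]
    n_heads = cache["n_heads"]
    dx = np.zeros_like(next(iter(d_layers.values())))
    if n_layers in d_layers:
        dx = dx + d_layers[n_layers]
    b_sz, t_sz, d_model = dx.shape
    n2 = b_sz * t_sz
    for l in range(n_layers - 1, -1, -1):
        c = cache["caches"][l]
        p = f"l{l}_"
        # feed-forward sublayer
        df2d = dx.reshape(n2, d_model)
        rd = c["rd"]
        grads[p + "W2"] += rd.T @ df2d
        grads[p + "b2"] += df2d.sum(0)
        drd = df2d @ params[p + "W2"].T
        dr = _dropout_bwd(drd, c["ffn_drop"])
        du = dr * (c["u"] > 0)
        h2_2d = c["h2"].reshape(n2, d_model)
        grads[p + "W1"] += h2_2d.T @ du
        grads[p + "b1"] += du.sum(0)
        dh2 = (du @ params[p + "W1"].T).reshape(b_sz, t_sz, d_model)
        dln2, dg2, db2 = _layernorm_bwd(dh2, c["ln2"])
        grads[p + "ln2_g"] += dg2
        grads[p + "ln2_b"] += db2
        dx_mid = dx + dln2
        # attention sublayer
        do = _dropout_bwd(dx_mid, c["attn_drop"]).reshape(n2, d_model)
        grads[p + "Wo"] += c["ctx"].reshape(n2, d_model).T @ do
        grads[p + "bo"] += do.sum(0)
        dctx = _split_heads(
            (do @ params[p + "Wo"].T).reshape(b_sz, t_sz, d_model), n_heads
        )
        attn, q, k, v = c["attn"], c["q"], c["k"], c["v"]
        dattn = dctx @ v.swapaxes(-1, -2)
        dv = attn.swapaxes(-1, -2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
        inv_sqrt_dh = 1.0 / np.sqrt(q.shape[-1])
        dq = dscores @ k * inv_sqrt_dh
        dk = dscores.swapaxes(-1, -2) @ q * inv_sqrt_dh
        dq_f = _merge_heads(dq).reshape(n2, d_model)
        dk_f = _merge_heads(dk).reshape(n2, d_model)
        dv_f = _merge_heads(dv).reshape(n2, d_model)
        h2d = c["h"].reshape(n2, d_model)
        grads[p + "Wq"] += h2d.T @ dq_f
        grads[p + "Wk"] += h2d.T @ dk_f
        grads[p + "Wv"] += h2d.T @ dv_f
        grads[p + "bq"] += dq_f.sum(0)
        grads[p + "bk"] += dk_f.sum(0)
        grads[p + "bv"] += dv_f.sum(0)
        dh = (
            dq_f @ params[p + "Wq"].T
            + dk_f @ params[p + "Wk"].T
            + dv_f @ params[p + "Wv"].T
        ).reshape(b_sz, t_sz, d_model)
        dln1, dg1, db1 = _layernorm_bwd(dh, c["ln1"])
        grads[p + "ln1_g"] += dg1
        grads[p + "ln1_b"] += db1
        dx = dx_mid + dln1
        # after processing encoder layer l the running gradient is w.r.t.
        # H^(l); add any gradient injected directly at that output (the
        # pooling taps an intermediate layer as well as the final one)
        if l in d_layers and l != n_layers:
            dx = dx + d_layers[l]
    # dx is now the gradient at the embedding output H^(0)
    dx = _dropout_bwd(dx, cache["emb_drop"])
    token_ids, age_ids, year_ids, visit_ids = cache["ids"]
    np.add.at(grads["emb_code"], token_ids, dx)
    np.add.at(grads["emb_age"], age_ids, dx)
    np.add.at(grads["emb_year"], year_ids, dx)
    np.add.at(grads["emb_visit"], visit_ids, dx)
    return grads


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = zeros_like_params(params)
        self.v = zeros_like_params(params)
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
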