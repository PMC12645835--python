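"""Differentiable building blocks on top of autograd/numpy.

All layers are pure functions of ``(input, parameter arrays)`` so that
reverse-mode autodiff over nested parameter dicts gives exact gradients.
Convolutions are realized as gather (im2col) + einsum, which autograd
differentiates through natively.  Batch normalization carries its running
statistics in a separate, non-differentiated state dict.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval
from numpy.lib.stride_tricks import sliding_window_view

BN_EPS = 1e-5
LN_EPS = 1e-5
BN_MOMENTUM = 0.1


def elu(x, alpha: float = 1.0):
    # exp evaluated only on the clipped branch to avoid overflow warnings
    return anp.where(x > 0, x, alpha * (anp.exp(anp.minimum(x, 0.0)) - 1.0))


@primitive
def _conv1d_valid(xp, W, dilation):
    """Valid-mode dilated cross-correlation on pre-padded input.

    ``xp`` is (B, C, Lp), ``W`` is (O, C, K); output (B, O, Lp - (K-1)*d).
    Implemented as an einsum over a strided sliding-window view; the
    vjps below express both backward passes as convolutions too, which is
    far faster than scatter-adds through a gather.
    """
    K = W.shape[2]
    span = (K - 1) * dilation
    win = sliding_window_view(xp, span + 1, axis=2)[..., ::dilation]
    return np.einsum("bclk,ock->bol", win, W, optimize=True)


def _conv1d_vjp_x(ans, xp, W, dilation):
    def vjp(g):
        K = W.shape[2]
        span = (K - 1) * dilation
        gp = np.pad(g, ((0, 0), (0, 0), (span, span)))
        win = sliding_window_view(gp, span + 1, axis=2)[..., ::dilation]
        return np.einsum("bolk,ock->bcl", win, W[:, :, ::-1], optimize=True)
    return vjp


def _conv1d_vjp_W(ans, xp, W, dilation):
    def vjp(g):
        K = W.shape[2]
        span = (K - 1) * dilation
        win = sliding_window_view(xp, span + 1, axis=2)[..., ::dilation]
        return np.einsum("bclk,bol->ock", win, g, optimize=True)
    return vjp


defvjp(_conv1d_valid, _conv1d_vjp_x, _conv1d_vjp_W)


def conv1d(x, W, b, *, padding: str = "same", dilation: int = 1, stride: int = 1):
    """1-D convolution (cross-correlation) over (batch, channels, length).

    ``padding='same'`` keeps length L (then subsamples when stride > 1,
    which is arithmetically identical to a strided convolution);
    ``padding='causal'`` left-pads only, so output t sees inputs <= t.
    """
    B, Cin, L = x.shape
    Cout, Cin_w, K = W.shape
    if Cin_w != Cin:
        raise ValueError(f"weight expects {Cin_w} input channels, got {Cin}")
    span = (K - 1) * dilation
    if padding == "same":
        left = span // 2
        right = span - left
    elif padding == "causal":
        left, right = span, 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    zeros_l = anp.zeros((B, Cin, left))
    zeros_r = anp.zeros((B, Cin, right))
    xp = anp.concatenate([zeros_l, x, zeros_r], axis=2)
    out = _conv1d_valid(xp, W, dilation)
    if stride > 1:
        out = out[:, :, ::stride]
    return out + b[None, :, None]


def avg_pool(x, p: int):
    """Non-overlapping average pooling by factor p along the last axis."""
    B, C, L = x.shape
    if L % p != 0:
        x = x[:, :, : (L // p) * p]
        L = (L // p) * p
    return anp.reshape(x, (B, C, L // p, p)).mean(axis=3)


def batch_norm(x, gamma, beta, running, mode: str):
    """Per-channel batch normalization over (batch, time).

    In train mode the batch statistics normalize the activations and the
    running estimates are updated in place (biased variance, momentum
    BN_MOMENTUM); eval mode uses the stored running statistics, making the
    forward pass independent of batch composition.
    """
    if mode == "train":
        mean = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        running["mean"] = (1 - BN_MOMENTUM) * running["mean"] + BN_MOMENTUM * getval(mean)
        running["var"] = (1 - BN_MOMENTUM) * running["var"] + BN_MOMENTUM * getval(var)
    else:
        mean, var = running["mean"], running["var"]
    xn = (x - mean[None, :, None]) / anp.sqrt(var[None, :, None] + BN_EPS)
    return xn * gamma[None, :, None] + beta[None, :, None]


def layer_norm(x, gamma, beta, axis: int = -1):
    """Layer normalization over ``axis`` (feature dimension)."""
    mean = x.mean(axis=axis, keepdims=True)
    var = x.var(axis=axis, keepdims=True)
    xn = (x - mean) / anp.sqrt(var + LN_EPS)
    shape = [1] * x.ndim
    shape[axis] = gamma.shape[0]
    return xn * anp.reshape(gamma, shape) + anp.reshape(beta, shape)


def dropout(x, rate: float, mode: str, rng: np.random.RandomState | None):
    """Inverted dropout; identity in eval mode or when rate is 0."""
    if mode != "train" or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("train-mode dropout requires an RNG")
    mask = rng.binomial(1, 1.0 - rate, size=getval(x).shape) / (1.0 - rate)
    return x * mask


def linear(x, W, b):
    return anp.dot(x, W) + b


def softmax(x, axis: int = -1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis: int = -1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


def sinusoidal_encoding(T: int, d: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding of shape (T, d)."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.zeros((T, d))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


def multi_head_attention(x, p, n_heads: int):
    """Scaled-dot-product self-attention on (B, T, D).

    Returns the attended values and the (B, H, T, T) attention weights,
    each row a probability distribution over key positions.
    """
    B, T, D = x.shape
    dh = D // n_heads

    def split(z):
        return anp.transpose(anp.reshape(z, (B, T, n_heads, dh)), (0, 2, 1, 3))

    q = split(linear(x, p["Wq"], p["bq"]))
    k = split(linear(x, p["Wk"], p["bk"]))
    v = split(linear(x, p["Wv"], p["bv"]))
    scores = anp.einsum("bhqd,bhkd->bhqk", q, k) / np.sqrt(dh)
    attn = softmax(scores, axis=-1)
    ctx = anp.einsum("bhqk,bhkd->bhqd", attn, v)
    ctx = anp.reshape(anp.transpose(ctx, (0, 2, 1, 3)), (B, T, D))
    return linear(ctx, p["Wo"], p["bo"]), attn


# ---------------------------------------------------------------------------
# parameter-tree utilities
# ---------------------------------------------------------------------------


def tree_map(fn, *trees):
    """Apply ``fn`` leaf-wise over parallel nested dict/list structures."""
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: tree_map(fn, *[t[k] for t in trees]) for k in t0}
    if isinstance(t0, (list, tuple)):
        return [tree_map(fn, *[t[i] for t in trees]) for i in range(len(t0))]
    return fn(*trees)


def tree_leaves(tree):
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k])
    elif isinstance(tree, (list, tuple)):
        for item in tree:
            yield from tree_leaves(item)
    else:
        yield tree


def tree_size(tree) -> int:
    return int(sum(np.asarray(leaf).size for leaf in tree_leaves(tree)))


def tree_copy(tree):
    return tree_map(lambda a: np.array(a, copy=True), tree)
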