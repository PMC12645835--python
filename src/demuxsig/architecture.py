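"""The demultiplexing network.

The classifier maps a fixed-length raw current window to barcode logits in
four stages:

1. **Multi-layer feature fusion** — three stacked 1-D convolutions extract
   increasingly abstract temporal features while average pooling halves the
   resolution twice; two residual paths (a strided convolution from the
   input, and a pooled copy of the first feature map) carry low- and
   mid-level detail to the same resolution.  The four streams are
   concatenated channel-wise, so the fused map mixes fine-grained local
   structure with higher-level context at length ``L / p**2``.
2. **Transformer encoder** — the fused channels are projected to
   ``d_model``, given a fixed sinusoidal positional encoding, and passed
   through pre-norm encoder layers whose multi-head self-attention models
   long-range dependencies between signal regions.
3. **Temporal convolution stack** — residual blocks of causal dilated
   convolutions (output at time t depends only on inputs at times <= t)
   summarize sequential patterns with an exponentially growing receptive
   field.
4. **Head** — global average pooling over time followed by a one-hidden-
   layer MLP produces the class logits.

All forward functions are pure in the parameters so autodiff provides
exact gradients; batch-norm running statistics live in a separate state
dict and are only consulted (never updated) in eval mode, which makes
eval-mode inference deterministic and batch-composition independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import autograd.numpy as anp
import numpy as np

from . import _nn
from ._nn import (
    avg_pool,
    batch_norm,
    conv1d,
    dropout,
    elu,
    layer_norm,
    linear,
    multi_head_attention,
    sinusoidal_encoding,
    tree_copy,
    tree_size,
)
from .signal_io import SignalBatch

__all__ = [
    "ModelConfig",
    "FusionOutput",
    "AttentionTensor",
    "DemuxTransModel",
    "init_params",
    "fusion_forward",
    "transformer_forward",
    "tcn_forward",
    "head_forward",
    "model_forward",
    "param_count",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters.

    Defaults are the full-size configuration; :meth:`small` returns a
    compact variant used for desk-scale experiments on simulated data.
    """

    input_length: int = 512
    fusion_channels: tuple[int, int, int] = (32, 64, 64)
    residual_channels: int = 32
    kernel_sizes: tuple[int, int, int, int] = (7, 7, 7, 7)
    pool_factor: int = 2
    d_model: int = 128
    n_heads: int = 4
    n_transformer_layers: int = 1
    ff_dim: int = 256
    tcn_channels: int = 128
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4, 8)
    dropout: float = 0.1
    n_classes: int = 4
    mlp_hidden: int = 128

    def __post_init__(self) -> None:
        p = self.pool_factor
        if p < 1:
            raise ValueError("pool_factor must be >= 1")
        if self.input_length < 1 or self.input_length % (p * p) != 0:
            raise ValueError(
                f"input_length {self.input_length} must be a positive multiple of "
                f"pool_factor^2 = {p * p}"
            )
        if len(self.fusion_channels) != 3 or any(c < 1 for c in self.fusion_channels):
            raise ValueError("fusion_channels must be three positive integers")
        if self.residual_channels < 1:
            raise ValueError("residual_channels must be >= 1")
        if len(self.kernel_sizes) != 4 or any(k < 1 or k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel_sizes must be four odd positive integers")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} must be divisible by n_heads {self.n_heads}"
            )
        if self.n_transformer_layers < 0:
            raise ValueError("n_transformer_layers must be >= 0")
        if not self.tcn_dilations:
            raise ValueError("tcn_dilations must be non-empty")
        if any(d < 1 for d in self.tcn_dilations):
            raise ValueError("tcn_dilations must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.mlp_hidden < 1 or self.ff_dim < 1 or self.tcn_channels < 1:
            raise ValueError("layer widths must be positive")

    @property
    def fused_channels(self) -> int:
        c1, c2, c3 = self.fusion_channels
        return self.residual_channels + c1 + c2 + c3

    @property
    def n_positions(self) -> int:
        """Temporal length T = L / p**2 after fusion."""
        return self.input_length // (self.pool_factor ** 2)

    @classmethod
    def small(cls, n_classes: int = 4) -> "ModelConfig":
        """Compact configuration for CPU-scale simulated experiments."""
        return cls(
            input_length=256,
            fusion_channels=(8, 16, 16),
            residual_channels=8,
            kernel_sizes=(7, 7, 7, 7),
            d_model=32,
            n_heads=4,
            n_transformer_layers=1,
            ff_dim=64,
            tcn_channels=32,
            tcn_kernel=3,
            tcn_dilations=(1, 2, 4),
            dropout=0.1,
            n_classes=n_classes,
            mlp_hidden=32,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("fusion_channels", "kernel_sizes", "tcn_dilations"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("fusion_channels", "kernel_sizes", "tcn_dilations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FusionOutput:
    """The concatenated multi-scale feature streams.

    ``features`` has shape (batch, residual + c1 + c2 + c3, L/p**2);
    ``path_lengths`` records each stream's temporal length before fusion.
    """

    features: np.ndarray
    path_lengths: dict[str, int]


@dataclass
class AttentionTensor:
    """Per-layer, per-head attention weights for one read.

    ``weights`` has shape (layer, head, T, T); every row is a probability
    distribution over key positions.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 4 or w.shape[2] != w.shape[3]:
            raise ValueError("weights must have shape (layer, head, T, T)")
        if np.any(w < -1e-12):
            raise ValueError("attention weights must be non-negative")
        rows = w.sum(axis=-1)
        if w.shape[0] and not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1")
        self.weights = w


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _conv_init(rng, c_out, c_in, k):
    std = np.sqrt(2.0 / (c_in * k))
    return {"W": rng.normal(0.0, std, size=(c_out, c_in, k)), "b": np.zeros(c_out)}


def _linear_init(rng, d_in, d_out):
    std = np.sqrt(2.0 / (d_in + d_out))
    return {"W": rng.normal(0.0, std, size=(d_in, d_out)), "b": np.zeros(d_out)}


def _norm_init(c):
    return {"gamma": np.ones(c), "beta": np.zeros(c)}


def init_params(config: ModelConfig, seed: int = 0) -> tuple[dict, dict]:
    """Draw initial weights (He/Glorot) and fresh batch-norm state."""
    rng = np.random.RandomState(seed)
    c1, c2, c3 = config.fusion_channels
    cr = config.residual_channels
    k1, k2, k3, kr = config.kernel_sizes
    D = config.d_model

    params: dict = {
        "fusion": {
            "conv1": _conv_init(rng, c1, 1, k1),
            "bn1": _norm_init(c1),
            "conv2": _conv_init(rng, c2, c1, k2),
            "bn2": _norm_init(c2),
            "conv3": _conv_init(rng, c3, c2, k3),
            "bn3": _norm_init(c3),
            "convr1": _conv_init(rng, cr, 1, kr),
            "bnr1": _norm_init(cr),
        },
        "proj": _linear_init(rng, config.fused_channels, D),
        "encoder": [],
        "tcn": [],
        "head": {
            "fc1": _linear_init(rng, config.tcn_channels, config.mlp_hidden),
            "fc2": _linear_init(rng, config.mlp_hidden, config.n_classes),
        },
    }
    for _ in range(config.n_transformer_layers):
        params["encoder"].append(
            {
                "ln1": _norm_init(D),
                "attn": {
                    **{f"W{n}": _linear_init(rng, D, D)["W"] for n in "qkvo"},
                    **{f"b{n}": np.zeros(D) for n in "qkvo"},
                },
                "ln2": _norm_init(D),
                "ff": {
                    "fc1": _linear_init(rng, D, config.ff_dim),
                    "fc2": _linear_init(rng, config.ff_dim, D),
                },
            }
        )
    c_in = D
    for _ in config.tcn_dilations:
        block = {
            "conv1": _conv_init(rng, config.tcn_channels, c_in, config.tcn_kernel),
            "ln1": _norm_init(config.tcn_channels),
            "conv2": _conv_init(rng, config.tcn_channels, config.tcn_channels, config.tcn_kernel),
            "ln2": _norm_init(config.tcn_channels),
        }
        if c_in != config.tcn_channels:
            block["down"] = _conv_init(rng, config.tcn_channels, c_in, 1)
        params["tcn"].append(block)
        c_in = config.tcn_channels

    state = {
        name: {"mean": np.zeros(c), "var": np.ones(c)}
        for name, c in (("bn1", c1), ("bn2", c2), ("bn3", c3), ("bnr1", cr))
    }
    return params, state


def param_count(config: ModelConfig) -> int:
    """Total number of trainable scalars — a pure function of the config."""
    params, _ = init_params(config, seed=0)
    return tree_size(params)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def _as_array(batch) -> np.ndarray:
    if isinstance(batch, SignalBatch):
        return batch.values
    return batch


def fusion_forward(batch, config: ModelConfig, params: dict, state: dict,
                   mode: str = "eval"):
    """Multi-scale convolutional feature fusion.

    The hierarchical streams are
    ``x1 = AvgPool(ELU(BN(Conv(X))))`` at L/p,
    ``x2 = AvgPool(ELU(BN(Conv(x1))))`` and ``x3 = ELU(BN(Conv(x2)))`` at
    L/p**2, the residual streams ``r1 = AvgPool(ELU(BN(Conv_stride-p(X))))``
    and ``r2 = AvgPool(x1)``, and the output is the channel-wise
    concatenation (r1, r2, x2, x3).
    """
    x = _as_array(batch)
    if x.shape[2] != config.input_length:
        raise ValueError(
            f"batch length {x.shape[2]} != configured input length {config.input_length}"
        )
    p = config.pool_factor
    fp = params["fusion"]

    x1 = avg_pool(elu(batch_norm(conv1d(x, **fp["conv1"]), **fp["bn1"],
                                 running=state["bn1"], mode=mode)), p)
    x2 = avg_pool(elu(batch_norm(conv1d(x1, **fp["conv2"]), **fp["bn2"],
                                 running=state["bn2"], mode=mode)), p)
    x3 = elu(batch_norm(conv1d(x2, **fp["conv3"]), **fp["bn3"],
                        running=state["bn3"], mode=mode))
    r1 = avg_pool(elu(batch_norm(conv1d(x, **fp["convr1"], stride=p), **fp["bnr1"],
                                 running=state["bnr1"], mode=mode)), p)
    r2 = avg_pool(x1, p)

    fused = anp.concatenate([r1, r2, x2, x3], axis=1)
    lengths = {
        "x1": x1.shape[2], "x2": x2.shape[2], "x3": x3.shape[2],
        "r1": r1.shape[2], "r2": r2.shape[2], "fused": fused.shape[2],
    }
    return FusionOutput(features=fused, path_lengths=lengths)


def transformer_forward(fused, config: ModelConfig, params: dict,
                        mode: str = "eval", rng=None):
    """Project fused channels to d_model, add positional encoding, and run
    the pre-norm encoder layers.

    Returns ``(contextual, attention)`` with ``contextual`` of shape
    (batch, d_model, T) and ``attention`` of shape
    (batch, n_layers, n_heads, T, T).  With zero encoder layers the output
    is exactly the projected input plus positional encoding.
    """
    feats = fused.features if isinstance(fused, FusionOutput) else fused
    B, _, T = feats.shape
    h = anp.transpose(feats, (0, 2, 1))                       # (B, T, C)
    h = linear(h, params["proj"]["W"], params["proj"]["b"])   # (B, T, D)
    h = h + sinusoidal_encoding(T, config.d_model)[None, :, :]

    attn_layers = []
    for lp in params["encoder"]:
        a, attn = multi_head_attention(
            layer_norm(h, lp["ln1"]["gamma"], lp["ln1"]["beta"]), lp["attn"],
            config.n_heads,
        )
        h = h + dropout(a, config.dropout, mode, rng)
        f = layer_norm(h, lp["ln2"]["gamma"], lp["ln2"]["beta"])
        f = linear(elu(linear(f, lp["ff"]["fc1"]["W"], lp["ff"]["fc1"]["b"])),
                   lp["ff"]["fc2"]["W"], lp["ff"]["fc2"]["b"])
        h = h + dropout(f, config.dropout, mode, rng)
        attn_layers.append(attn)

    if attn_layers:
        attention = anp.stack(attn_layers, axis=1)            # (B, layers, H, T, T)
    else:
        attention = np.zeros((B, 0, config.n_heads, T, T))
    return anp.transpose(h, (0, 2, 1)), attention


def tcn_forward(contextual, config: ModelConfig, params: dict,
                mode: str = "eval", rng=None):
    """Causal temporal-convolution stack.

    One residual block per dilation; each block applies (causal dilated
    conv -> channel layer-norm -> ELU -> dropout) twice, then adds a
    1x1-matched residual.  Channel layer-norm acts per time step, so the
    whole stack is strictly causal: output t never sees inputs > t.
    """
    h = contextual
    for d, bp in zip(config.tcn_dilations, params["tcn"]):
        y = conv1d(h, **bp["conv1"], padding="causal", dilation=d)
        y = elu(layer_norm(y, bp["ln1"]["gamma"], bp["ln1"]["beta"], axis=1))
        y = dropout(y, config.dropout, mode, rng)
        y = conv1d(y, **bp["conv2"], padding="causal", dilation=d)
        y = elu(layer_norm(y, bp["ln2"]["gamma"], bp["ln2"]["beta"], axis=1))
        y = dropout(y, config.dropout, mode, rng)
        res = conv1d(h, **bp["down"]) if "down" in bp else h
        h = y + res
    return h


def head_forward(tcn_out, config: ModelConfig, params: dict,
                 mode: str = "eval", rng=None):
    """Global average pooling over time, then a one-hidden-layer MLP."""
    pooled = tcn_out.mean(axis=2)                             # (B, C)
    hp = params["head"]
    h = elu(linear(pooled, hp["fc1"]["W"], hp["fc1"]["b"]))
    h = dropout(h, config.dropout, mode, rng)
    return linear(h, hp["fc2"]["W"], hp["fc2"]["b"])


def model_forward(batch, config: ModelConfig, params: dict, state: dict,
                  mode: str = "eval", rng=None, return_attention: bool = False):
    """End-to-end forward pass: fusion -> encoder -> TCN -> head.

    Eval mode is deterministic (dropout off, batch norm on running stats).
    Returns logits of shape (batch, n_classes), and additionally the
    (batch, n_layers, n_heads, T, T) attention weights when requested.
    """
    fused = fusion_forward(batch, config, params, state, mode=mode)
    contextual, attention = transformer_forward(fused, config, params, mode=mode, rng=rng)
    seq = tcn_forward(contextual, config, params, mode=mode, rng=rng)
    logits = head_forward(seq, config, params, mode=mode, rng=rng)
    if return_attention:
        return logits, attention
    return logits


# ---------------------------------------------------------------------------
# model wrapper + checkpointing
# ---------------------------------------------------------------------------


class DemuxTransModel:
    """Config + weights + batch-norm state, with a convenience forward."""

    def __init__(self, config: ModelConfig, params: dict | None = None,
                 state: dict | None = None, seed: int = 0):
        self.config = config
        if params is None or state is None:
            params, state = init_params(config, seed=seed)
        self.params = params
        self.state = state

    def forward(self, batch, mode: str = "eval", rng=None, return_attention: bool = False):
        return model_forward(batch, self.config, self.params, self.state,
                             mode=mode, rng=rng, return_attention=return_attention)

    def n_parameters(self) -> int:
        return tree_size(self.params)

    def copy(self) -> "DemuxTransModel":
        return DemuxTransModel(self.config, tree_copy(self.params), tree_copy(self.state))


def _flatten_tree(tree, prefix="", out=None):
    if out is None:
        out = {}
    if isinstance(tree, dict):
        for k, v in tree.items():
            _flatten_tree(v, f"{prefix}{k}/", out)
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            _flatten_tree(v, f"{prefix}{i}/", out)
    else:
        out[prefix[:-1]] = np.asarray(tree)
    return out


def _unflatten_tree(flat: dict):
    root: dict = {}
    for path, value in flat.items():
        keys = path.split("/")
        node = root
        for k in keys[:-1]:
            node = node.setdefault(k, {})
        node[keys[-1]] = value

    def listify(node):
        if not isinstance(node, dict):
            return node
        if node and all(k.isdigit() for k in node):
            return [listify(node[k]) for k in sorted(node, key=int)]
        return {k: listify(v) for k, v in node.items()}

    return listify(root)


def save_checkpoint(model: DemuxTransModel, path) -> None:
    """Write weights, batch-norm state and the full config to one file."""
    from . import __version__

    arrays = {}
    for key, val in _flatten_tree(model.params).items():
        arrays[f"params/{key}"] = val
    for key, val in _flatten_tree(model.state).items():
        arrays[f"state/{key}"] = val
    header = json.dumps(
        {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "library_version": __version__,
            "config": model.config.to_dict(),
        }
    )
    arrays["__meta__"] = np.frombuffer(header.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> DemuxTransModel:
    """Load a checkpoint, validating the stored config."""
    with np.load(path) as npz:
        try:
            meta = json.loads(bytes(npz["__meta__"]).decode())
        except KeyError:
            raise ValueError(f"{path}: not a model checkpoint (missing metadata)") from None
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported checkpoint format {meta.get('format_version')!r}"
            )
        config = ModelConfig.from_dict(meta["config"])
        params_flat, state_flat = {}, {}
        for key in npz.files:
            if key.startswith("params/"):
                params_flat[key[7:]] = npz[key]
            elif key.startswith("state/"):
                state_flat[key[6:]] = npz[key]
    params = _unflatten_tree(params_flat)
    state = _unflatten_tree(state_flat)
    model = DemuxTransModel(config, params, state)
    expected = param_count(config)
    if model.n_parameters() != expected:
        raise ValueError(
            f"{path}: checkpoint incompatible with its config "
            f"({model.n_parameters()} vs {expected} parameters)"
        )
    return model
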