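"""Attention-based interpretability exports.

Two artifacts link a trained model's self-attention back to the raw
current trace: an :class:`AttentionProfile` (per-sample importance,
obtained by averaging attention over layers, heads and query positions
and upsampling to signal resolution) and a :class:`ChordMatrix`
(symmetrized inter-position attention mass with its strongest pairwise
dependencies).  Aggregation across layers/heads/queries is the simple
mean; upsampling repeats each model-resolution value ``p**2`` times so
mass attribution stays honest to the model's temporal resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architecture import AttentionTensor, DemuxTransModel
from .signal_io import RawSignal, SignalSet
from .signal_io import make_batches

__all__ = [
    "AttentionProfile",
    "ChordMatrix",
    "attention_profile",
    "chord_matrix",
    "export_interpretation",
    "load_interpretation",
]


@dataclass
class AttentionProfile:
    """Raw trace plus a per-sample importance vector summing to 1."""

    read_id: str
    signal: np.ndarray
    importance: np.ndarray
    downsample_factor: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.importance = np.asarray(self.importance, dtype=float)
        if self.signal.shape != self.importance.shape:
            raise ValueError("signal and importance must have equal length")
        if np.any(self.importance < -1e-12):
            raise ValueError("importance must be non-negative")
        if abs(self.importance.sum() - 1.0) > 1e-6:
            raise ValueError("importance must sum to 1")


@dataclass
class ChordMatrix:
    """Symmetrized T x T attention mass and its top-k off-diagonal edges."""

    read_id: str
    matrix: np.ndarray
    edges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        T = self.matrix.shape[0]
        if self.matrix.shape != (T, T):
            raise ValueError("matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")


def _single_read_attention(model: DemuxTransModel, signal: RawSignal,
                           normalize_method: str = "median_mad") -> AttentionTensor:
    sset = SignalSet(signals=[signal], n_classes=model.config.n_classes)
    [batch] = make_batches(sset, model.config.input_length, 1,
                           normalize_method=normalize_method)
    _, attn = model.forward(batch, mode="eval", return_attention=True)
    if attn.shape[1] == 0:
        raise ValueError("model has no transformer layers; attention is undefined")
    return AttentionTensor(weights=np.asarray(attn)[0]), batch


def attention_profile(model: DemuxTransModel, signal: RawSignal,
                      normalize_method: str = "median_mad") -> AttentionProfile:
    """Per-sample attention importance aligned with the raw trace.

    Attention is averaged over layers, heads and query positions, giving a
    length-T key-importance vector; each entry is repeated ``p**2`` times
    to reach raw-signal resolution and the result renormalized to sum 1.
    """
    attn, batch = _single_read_attention(model, signal, normalize_method)
    key_importance = attn.weights.mean(axis=(0, 1, 2))          # (T,)
    factor = model.config.pool_factor ** 2
    upsampled = np.repeat(key_importance, factor)
    upsampled = upsampled / upsampled.sum()
    return AttentionProfile(
        read_id=signal.read_id,
        signal=batch.values[0, 0],
        importance=upsampled,
        downsample_factor=factor,
    )


def chord_matrix(model: DemuxTransModel, signal: RawSignal, top_k: int = 50,
                 normalize_method: str = "median_mad") -> ChordMatrix:
    """Symmetrized inter-position attention with the k strongest edges.

    The layer/head-averaged T x T attention M is symmetrized as
    (M + M^T)/2 with the diagonal zeroed; edges (i, j, weight), i < j, are
    returned sorted by weight descending.  ``top_k`` beyond the number of
    off-diagonal pairs is clamped with a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    attn, _ = _single_read_attention(model, signal, normalize_method)
    M = attn.weights.mean(axis=(0, 1))                          # (T, T)
    S = (M + M.T) / 2.0
    np.fill_diagonal(S, 0.0)
    T = S.shape[0]
    max_edges = T * (T - 1) // 2
    if top_k > max_edges:
        warnings.warn(
            f"top_k={top_k} exceeds the {max_edges} off-diagonal pairs; clamping",
            stacklevel=2,
        )
        top_k = max_edges
    iu = np.triu_indices(T, k=1)
    weights = S[iu]
    order = np.argsort(weights)[::-1][:top_k]
    edges = [(int(iu[0][o]), int(iu[1][o]), float(weights[o])) for o in order]
    return ChordMatrix(read_id=signal.read_id, matrix=S, edges=edges)


def export_interpretation(obj, path, fmt: str = "json") -> None:
    """Serialize a profile or chord matrix losslessly to JSON or TSV."""
    path = Path(path)
    if fmt not in ("json", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    try:
        if isinstance(obj, AttentionProfile):
            _export_profile(obj, path, fmt)
        elif isinstance(obj, ChordMatrix):
            _export_chord(obj, path, fmt)
        else:
            raise TypeError(f"cannot export object of type {type(obj).__name__}")
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def _export_profile(profile: AttentionProfile, path: Path, fmt: str) -> None:
    if fmt == "json":
        doc = {
            "kind": "attention_profile",
            "read_id": profile.read_id,
            "downsample_factor": profile.downsample_factor,
            "signal": profile.signal.tolist(),
            "importance": profile.importance.tolist(),
        }
        path.write_text(json.dumps(doc) + "\n", encoding="utf-8")
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# kind=attention_profile\n# read_id={profile.read_id}\n")
            fh.write(f"# downsample_factor={profile.downsample_factor}\n")
            fh.write("position\tsignal\timportance\n")
            for i, (s, w) in enumerate(zip(profile.signal, profile.importance)):
                fh.write(f"{i}\t{s!r}\t{w!r}\n")


def _export_chord(chord: ChordMatrix, path: Path, fmt: str) -> None:
    if fmt == "json":
        doc = {
            "kind": "chord_matrix",
            "read_id": chord.read_id,
            "matrix": chord.matrix.tolist(),
            "edges": [[i, j, w] for i, j, w in chord.edges],
        }
        path.write_text(json.dumps(doc) + "\n", encoding="utf-8")
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# kind=chord_matrix\n# read_id={chord.read_id}\n")
            fh.write("i\tj\tweight\n")
            for i, j, w in chord.edges:
                fh.write(f"{i}\t{j}\t{w!r}\n")


def load_interpretation(path):
    """Read back a JSON export of a profile or chord matrix."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("kind") == "attention_profile":
        return AttentionProfile(
            read_id=doc["read_id"],
            signal=np.asarray(doc["signal"]),
            importance=np.asarray(doc["importance"]),
            downsample_factor=int(doc["downsample_factor"]),
        )
    if doc.get("kind") == "chord_matrix":
        return ChordMatrix(
            read_id=doc["read_id"],
            matrix=np.asarray(doc["matrix"]),
            edges=[(int(i), int(j), float(w)) for i, j, w in doc["edges"]],
        )
    raise ValueError(f"{path}: unknown interpretation kind {doc.get('kind')!r}")
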