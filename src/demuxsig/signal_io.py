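"""Signal dataset I/O, normalization and length standardization.

A dataset is a collection of raw nanopore current traces (one per read),
each a variable-length real-valued sequence with an optional integer
barcode label.  Two on-disk representations are supported:

* a plain-text signal table (TSV) with columns
  ``read_id<TAB>label<TAB>samples`` where ``samples`` is a comma-separated
  list of decimals (label empty when absent), preceded by optional
  ``# key=value`` metadata lines and a mandatory header row;
* a single-file HDF5 container with one float32 dataset per read carrying
  ``read_id`` and ``label`` attributes.

Traces are normalized per read (median/MAD by default, robust to the
spike outliers typical of pore current measurements) and cut or padded to
the fixed input length the classifier expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

__all__ = [
    "RawSignal",
    "SignalSet",
    "SignalBatch",
    "read_signal_table",
    "write_signal_table",
    "normalize",
    "standardize_length",
    "make_batches",
    "MAD_SCALE",
]

#: 1 / Phi^{-1}(3/4): scales the MAD to estimate sigma under normality.
MAD_SCALE = 1.4826

NORMALIZE_METHODS = ("median_mad", "zscore", "none")
LENGTH_POLICIES = ("truncate_head", "truncate_tail", "pad_edge", "pad_zero")


@dataclass
class RawSignal:
    """One read's current trace plus optional class label.

    Parameters
    ----------
    read_id:
        Opaque unique identifier.
    samples:
        Current values (arbitrary units), length >= 1, all finite.
    label:
        Optional class index in ``[0, C)``.
    source:
        Optional free-text provenance.
    """

    read_id: str
    samples: np.ndarray
    label: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError(
                f"read {self.read_id!r}: samples must be a non-empty 1-D sequence"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"read {self.read_id!r}: non-finite sample values")
        if self.label is not None:
            if int(self.label) != self.label or self.label < 0:
                raise ValueError(
                    f"read {self.read_id!r}: label must be a non-negative integer"
                )
            self.label = int(self.label)

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class SignalSet:
    """An ordered collection of :class:`RawSignal` with a class count."""

    signals: list[RawSignal]
    n_classes: int
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        seen: set[str] = set()
        for sig in self.signals:
            if sig.read_id in seen:
                raise ValueError(f"duplicate read_id {sig.read_id!r}")
            seen.add(sig.read_id)
            if sig.label is not None and sig.label >= self.n_classes:
                raise ValueError(
                    f"read {sig.read_id!r}: label {sig.label} >= n_classes {self.n_classes}"
                )

    def __len__(self) -> int:
        return len(self.signals)

    def __iter__(self):
        return iter(self.signals)

    @property
    def labels(self) -> np.ndarray | None:
        """Label vector, or None when any read is unlabeled."""
        if any(s.label is None for s in self.signals):
            return None
        return np.array([s.label for s in self.signals], dtype=np.int64)

    @property
    def read_ids(self) -> list[str]:
        return [s.read_id for s in self.signals]


@dataclass
class SignalBatch:
    """A fixed-length, normalized mini-batch ready for the model.

    ``values`` has shape ``(batch, 1, L)`` (one input channel); ``lengths``
    records each read's pre-standardization length.
    """

    values: np.ndarray
    labels: np.ndarray | None
    lengths: np.ndarray
    read_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1] != 1:
            raise ValueError("values must have shape (batch, 1, L)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("batch contains non-finite entries")

    def __len__(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# normalization / length standardization
# ---------------------------------------------------------------------------


def normalize(signal: RawSignal, method: str = "median_mad") -> RawSignal:
    """Return a per-read normalized copy of ``signal``.

    ``median_mad`` maps x to ``(x - median) / (MAD_SCALE * MAD)`` which has
    median 0 and a robust scale of 1; ``zscore`` is the classical
    ``(x - mean) / sd``; ``none`` is the identity.

    Raises
    ------
    ValueError
        If the trace is constant (zero MAD or zero sd), which makes the
        requested normalization degenerate.
    """
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    x = signal.samples
    if method == "none":
        return replace(signal, samples=x.copy())
    if method == "median_mad":
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad <= 0.0:
            raise ValueError(
                f"read {signal.read_id!r}: zero MAD (constant trace), "
                "cannot median/MAD-normalize"
            )
        return replace(signal, samples=(x - med) / (MAD_SCALE * mad))
    sd = x.std()
    if sd <= 0.0:
        raise ValueError(
            f"read {signal.read_id!r}: zero standard deviation (constant trace), "
            "cannot z-score"
        )
    return replace(signal, samples=(x - x.mean()) / sd)


def standardize_length(
    samples: np.ndarray | RawSignal, L: int, policy: str = "truncate_head"
) -> np.ndarray:
    """Cut or pad a trace to exactly ``L`` samples.

    ``truncate_head`` keeps the first L samples (the barcode sits at the
    read start), ``truncate_tail`` the last L.  When the trace is shorter
    than L, ``pad_edge`` repeats the final value and ``pad_zero`` appends
    zeros; the two truncation policies then fall back to edge padding.
    Idempotent when the input already has length L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if policy not in LENGTH_POLICIES:
        raise ValueError(f"unknown length policy {policy!r}")
    x = samples.samples if isinstance(samples, RawSignal) else np.asarray(samples)
    n = x.size
    if n == L:
        return x.copy()
    if n > L:
        if policy == "truncate_tail":
            return x[n - L:].copy()
        # truncate_head is also the sane default for the padding policies
        return x[:L].copy()
    pad = L - n
    if policy == "pad_zero":
        return np.concatenate([x, np.zeros(pad)])
    return np.concatenate([x, np.full(pad, x[-1])])


def make_batches(
    sset: SignalSet,
    L: int,
    batch_size: int,
    normalize_method: str = "median_mad",
    length_policy: str = "truncate_head",
    shuffle: bool = False,
    seed: int = 0,
) -> list[SignalBatch]:
    """Normalize, length-standardize and group a dataset into batches.

    Every read lands in exactly one batch; with ``shuffle`` the order is a
    seeded permutation, reproducible for a fixed ``seed``.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    order = np.arange(len(sset))
    if shuffle:
        order = np.random.RandomState(seed).permutation(order)
    batches: list[SignalBatch] = []
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        rows, labels, lengths, ids = [], [], [], []
        for i in idx:
            sig = sset.signals[i]
            try:
                norm = normalize(sig, normalize_method)
            except ValueError as exc:
                raise ValueError(f"normalization failed for {sig.read_id!r}: {exc}") from exc
            rows.append(standardize_length(norm.samples, L, length_policy))
            labels.append(sig.label)
            lengths.append(len(sig))
            ids.append(sig.read_id)
        lab = None
        if all(l is not None for l in labels):
            lab = np.array(labels, dtype=np.int64)
        batches.append(
            SignalBatch(
                values=np.stack(rows)[:, None, :],
                labels=lab,
                lengths=np.array(lengths, dtype=np.int64),
                read_ids=ids,
            )
        )
    return batches


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

_TSV_HEADER = "read_id\tlabel\tsamples"


def write_signal_table(sset: SignalSet, path: str | Path, dialect: str = "tsv") -> None:
    """Write a dataset as a signal table TSV or HDF5 container.

    TSV numbers are written with ``repr`` precision so that a read/write
    round trip is lossless at double precision.
    """
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# n_classes={sset.n_classes}\n")
            for key, val in sorted(sset.metadata.items()):
                fh.write(f"# {key}={val}\n")
            fh.write(_TSV_HEADER + "\n")
            for sig in sset.signals:
                label = "" if sig.label is None else str(sig.label)
                samples = ",".join(repr(float(v)) for v in sig.samples)
                fh.write(f"{sig.read_id}\t{label}\t{samples}\n")
    elif dialect == "container":
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["n_classes"] = sset.n_classes
            for key, val in sset.metadata.items():
                h5.attrs[f"meta_{key}"] = val
            for i, sig in enumerate(sset.signals):
                ds = h5.create_dataset(f"read_{i:08d}", data=sig.samples.astype(np.float32))
                ds.attrs["read_id"] = sig.read_id
                ds.attrs["label"] = -1 if sig.label is None else sig.label
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_signal_table(path: str | Path, dialect: str = "tsv") -> SignalSet:
    """Read a signal table written by :func:`write_signal_table`.

    Malformed TSV rows raise a ``ValueError`` naming the offending line
    number; duplicate read ids are rejected.
    """
    path = Path(path)
    if dialect == "container":
        return _read_container(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    signals: list[RawSignal] = []
    metadata: dict[str, str] = {}
    n_classes: int | None = None
    max_label = -1
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() == "n_classes":
                        n_classes = int(val)
                    else:
                        metadata[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != _TSV_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {_TSV_HEADER!r}, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            read_id, label_str, samples_str = parts
            if not samples_str:
                raise ValueError(f"{path}:{lineno}: empty samples field")
            try:
                samples = np.array([float(tok) for tok in samples_str.split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric sample value ({exc})") from None
            label = None
            if label_str:
                try:
                    label = int(label_str)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer label {label_str!r}") from None
                max_label = max(max_label, label)
            try:
                signals.append(RawSignal(read_id=read_id, samples=samples, label=label))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not header_seen:
        raise ValueError(f"{path}: missing header row")
    if n_classes is None:
        n_classes = max(max_label + 1, 1)
    return SignalSet(signals=signals, n_classes=n_classes, metadata=metadata)


def _read_container(path: Path) -> SignalSet:
    import h5py

    signals: list[RawSignal] = []
    metadata: dict[str, str] = {}
    with h5py.File(path, "r") as h5:
        n_classes = int(h5.attrs.get("n_classes", 1))
        for key, val in h5.attrs.items():
            if key.startswith("meta_"):
                metadata[key[5:]] = str(val)
        for name in sorted(h5.keys()):
            ds = h5[name]
            label = int(ds.attrs["label"])
            signals.append(
                RawSignal(
                    read_id=str(ds.attrs["read_id"]),
                    samples=np.asarray(ds[...], dtype=np.float64),
                    label=None if label < 0 else label,
                )
            )
    return SignalSet(signals=signals, n_classes=n_classes, metadata=metadata)
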