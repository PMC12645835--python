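"""Synthetic nanopore squiggle generation.

A translocating molecule produces a piecewise-constant current trace: each
k-mer occupying the pore contributes an expected level held for a random
dwell (the motor protein steps stochastically), on top of which sit
Gaussian measurement noise, slow baseline drift and occasional spike
outliers.  This module draws k-mer levels from a seeded pore model,
simulates labeled reads for a panel of barcode sequences, and assembles
class-balanced train/validation/test splits with controllable difficulty
(the noise standard deviation is the main separability dial).

The dwell distribution is a shifted negative binomial: ``d = 1 + NB`` with
``NB`` parameterized by mean ``dwell_mean - 1`` and a dispersion ``a`` such
that ``Var = mu + a * mu**2`` (motor stepping is over-dispersed relative to
Poisson).  Dispersion 0 is the deterministic limit: every k-mer dwells
``max(1, round(dwell_mean))`` samples, which makes noiseless traces exactly
predictable and hence testable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .signal_io import RawSignal, SignalSet

__all__ = [
    "PoreModel",
    "SimParams",
    "BarcodePanel",
    "make_pore_model",
    "simulate_read",
    "generate_dataset",
    "default_panel",
]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class PoreModel:
    """Map from each of the 4**k k-mers to an expected current level.

    Levels are drawn i.i.d. standard normal (the trace is produced on a
    standardized, dimensionless scale) from a generator seeded with
    ``seed``, so the model is fully reproducible from ``(k, seed)``.
    """

    k: int
    levels: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if len(self.levels) != 4 ** self.k:
            raise ValueError(f"pore model must have 4^{self.k} levels")


@dataclass(frozen=True)
class SimParams:
    """Noise/kinetics parameters of the squiggle generator.

    dwell_mean:
        Mean samples per k-mer (> 0); 8 by default so a 40-nt barcode with
        k=3 yields ~300 samples, comfortably covering a 256-sample window.
    dwell_dispersion:
        Over-dispersion ``a`` of the dwell distribution (>= 0); 0.3 gives
        visibly ragged segment lengths without degenerate single-sample
        dwells dominating.
    noise_sd:
        Gaussian measurement noise s.d. on the standardized level scale.
    drift_amp:
        Amplitude of a one-period sinusoidal baseline drift with random phase.
    spike_rate:
        Per-sample probability of an outlier spike.
    spike_amp:
        Magnitude of a spike (sign chosen at random per spike).
    """

    dwell_mean: float = 8.0
    dwell_dispersion: float = 0.3
    noise_sd: float = 0.5
    drift_amp: float = 0.3
    spike_rate: float = 0.001
    spike_amp: float = 4.0

    def __post_init__(self) -> None:
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be > 0")
        if self.dwell_dispersion < 0:
            raise ValueError("dwell_dispersion must be >= 0")
        if self.noise_sd < 0 or self.drift_amp < 0 or self.spike_amp < 0:
            raise ValueError("noise_sd, drift_amp, spike_amp must be >= 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must be in [0, 1]")


@dataclass(frozen=True)
class BarcodePanel:
    """Ordered barcode sequences; class index = position in the list."""

    barcodes: tuple[str, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("panel must contain at least one barcode")
        names = self.names or tuple(f"BC{i + 1:02d}" for i in range(len(self.barcodes)))
        object.__setattr__(self, "names", names)
        if len(self.names) != len(self.barcodes):
            raise ValueError("names and barcodes must be parallel lists")
        for bc in self.barcodes:
            if not bc or any(c not in _ALPHABET for c in bc):
                raise ValueError(f"barcode {bc!r} contains characters outside ACGT")

    def __len__(self) -> int:
        return len(self.barcodes)


def make_pore_model(k: int, seed: int = 0) -> PoreModel:
    """Draw a standardized k-mer level table from a seeded generator."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in [1, 8]")
    rng = np.random.default_rng(seed)
    kmers = ["".join(t) for t in itertools.product(_ALPHABET, repeat=k)]
    values = rng.standard_normal(len(kmers))
    return PoreModel(k=k, levels=dict(zip(kmers, values.tolist())), seed=seed)


def _draw_dwells(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.dwell_dispersion == 0.0:
        return np.full(n, max(1, round(params.dwell_mean)), dtype=np.int64)
    mu = max(params.dwell_mean - 1.0, 1e-12)
    r = 1.0 / params.dwell_dispersion          # NB size parameter
    p = r / (r + mu)
    return 1 + rng.negative_binomial(r, p, size=n)


def simulate_read(
    barcode: str,
    model: PoreModel,
    params: SimParams,
    seed: int,
    read_id: str | None = None,
) -> RawSignal:
    """Simulate one squiggle for ``barcode`` under ``model`` and ``params``.

    The (len(barcode) - k + 1) successive k-mers each contribute a segment
    of their expected level held for a random dwell; noise, drift and
    spikes are then superimposed.  Fully deterministic given
    ``(barcode, model, params, seed)``.
    """
    if any(c not in _ALPHABET for c in barcode):
        raise ValueError(f"barcode contains characters outside ACGT: {barcode!r}")
    k = model.k
    if len(barcode) < k:
        raise ValueError(f"barcode shorter than k={k}")
    rng = np.random.default_rng(seed)
    kmers = [barcode[i:i + k] for i in range(len(barcode) - k + 1)]
    dwells = _draw_dwells(len(kmers), params, rng)
    trace = np.repeat([model.levels[km] for km in kmers], dwells)
    n = trace.size
    if params.noise_sd > 0:
        trace = trace + rng.normal(0.0, params.noise_sd, size=n)
    if params.drift_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        trace = trace + params.drift_amp * np.sin(2.0 * np.pi * np.arange(n) / n + phase)
    if params.spike_rate > 0:
        hits = rng.random(n) < params.spike_rate
        signs = rng.choice([-1.0, 1.0], size=n)
        trace = trace + hits * signs * params.spike_amp
    return RawSignal(read_id=read_id or f"sim-{seed}", samples=trace)


def default_panel(
    n_barcodes: int = 4, length: int = 40, min_hamming: int = 20, seed: int = 2024
) -> BarcodePanel:
    """Greedily build a panel of well-separated random barcodes.

    Candidates are drawn uniformly over ACGT and kept only when at pairwise
    Hamming distance >= ``min_hamming`` from every accepted barcode, mirroring
    the four-barcode setting typical of direct-RNA demultiplexing kits.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n_barcodes:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not satisfy the Hamming-distance constraint")
        cand = "".join(rng.choice(list(_ALPHABET), size=length))
        if all(
            sum(a != b for a, b in zip(cand, prev)) >= min_hamming for prev in chosen
        ):
            chosen.append(cand)
    return BarcodePanel(barcodes=tuple(chosen))


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must be positive and sum to 1")
    n_train = round(n * fractions[0])
    n_val = round(n * fractions[1])
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split {fractions} leaves an empty split for n_per_class={n}"
        )
    return n_train, n_val, n_test


def generate_dataset(
    panel: BarcodePanel,
    model: PoreModel,
    params: SimParams,
    n_per_class: int,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[SignalSet, SignalSet, SignalSet]:
    """Simulate a labeled, class-balanced dataset split into train/val/test.

    Per-read seeds are derived deterministically from the master ``seed``,
    so the same call reproduces byte-identical splits; read ids are unique
    and disjoint across splits.
    """
    if n_per_class < 3:
        raise ValueError("n_per_class must be >= 3")
    n_train, n_val, n_test = _split_counts(n_per_class, split)
    seed_rng = np.random.default_rng(seed)
    read_seeds = seed_rng.integers(0, 2 ** 31 - 1, size=len(panel) * n_per_class)

    meta = {
        "simulator": "demuxsig.squiggle",
        "k": str(model.k),
        "pore_seed": str(model.seed),
        "noise_sd": repr(params.noise_sd),
        "dwell_mean": repr(params.dwell_mean),
        "dwell_dispersion": repr(params.dwell_dispersion),
        "drift_amp": repr(params.drift_amp),
        "spike_rate": repr(params.spike_rate),
        "spike_amp": repr(params.spike_amp),
        "master_seed": str(seed),
    }
    buckets: dict[str, list[RawSignal]] = {"train": [], "val": [], "test": []}
    i = 0
    for cls, barcode in enumerate(panel.barcodes):
        for j in range(n_per_class):
            rid = f"sim-c{cls}-r{j:05d}"
            sig = simulate_read(barcode, model, params, int(read_seeds[i]), read_id=rid)
            sig.label = cls
            sig.source = panel.names[cls]
            if j < n_train:
                buckets["train"].append(sig)
            elif j < n_train + n_val:
                buckets["val"].append(sig)
            else:
                buckets["test"].append(sig)
            i += 1
    make = lambda key: SignalSet(
        signals=buckets[key], n_classes=len(panel), metadata={**meta, "split": key}
    )
    return make("train"), make("val"), make("test")
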