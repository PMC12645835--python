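# demuxsig

Barcode demultiplexing for nanopore sequencing, directly from the raw
current signal.

Multiplexed nanopore runs pool several samples on one flow cell after
ligating a short barcode (adapter) sequence to each sample's molecules.
Assigning every read back to its sample — demultiplexing — is usually done
on basecalled sequence, which discards signal-level information and
inherits basecalling errors. `demuxsig` instead classifies the squiggle
itself: the raw current trace produced as the barcode region translocates
the pore.

The classifier is a hybrid network

```
X ──► multi-layer feature fusion ──► Transformer encoder ──► causal TCN ──► pooling + MLP ──► logits
```

whose fusion stage combines hierarchical convolutions

```
x1 = AvgPool(ELU(BN(Conv(X))))          r1 = AvgPool(ELU(BN(Conv_stride-p(X))))
x2 = AvgPool(ELU(BN(Conv(x1))))         r2 = AvgPool(x1)
x3 = ELU(BN(Conv(x2)))                  F  = Concat(r1, r2, x2, x3)
```

at a common temporal resolution L/p², followed by multi-head
self-attention for long-range dependencies and a stack of causal dilated
temporal-convolution blocks for sequential patterns. See
[docs/methods.md](docs/methods.md) for the full model description,
parameter defaults and limitations.

The package ships with a seeded squiggle simulator (k-mer pore model,
negative-binomial dwell times, Gaussian noise, sinusoidal drift, spike
outliers, controllable class separability), a reproducible training loop,
an evaluation suite (accuracy / precision / recall / F1, per-class
one-vs-rest ROC AUC, and the clustering-comparison protocol of
homogeneity / completeness / majority-vote mapped accuracy), and
attention-based interpretability exports. It is implemented on
numpy + autograd — no GPU framework required.

## Worked example

Simulate an easy four-barcode dataset, train the compact model, and
evaluate:

```bash
demuxsig simulate --k 3 --n-per-class 100 --noise-sd 0.1 --seed 7 --out sim/
demuxsig train --train sim/train.tsv --val sim/val.tsv --epochs 12 --seed 1 --out ckpt/
demuxsig predict --ckpt ckpt/best.npz --in sim/test.tsv --out preds.tsv
demuxsig evaluate --pred preds.tsv --truth sim/test.tsv --out report.json
```

The train step prints the selected epoch,

```
best epoch 11: val_loss=0.1808 val_acc=0.9500
```

and the evaluate step prints the test-set report:

```
accuracy        0.9500
macro precision 0.9542
macro recall    0.9500
macro F1        0.9505
class 0: P=0.8696 R=1.0000 F1=0.9302 AUC=0.9983
class 1: P=0.9474 R=0.9000 F1=0.9231 AUC=0.9967
class 2: P=1.0000 R=0.9500 F1=0.9744 AUC=1.0000
class 3: P=1.0000 R=0.9500 F1=0.9744 AUC=0.9967
```

With measurement noise well below the k-mer level separation
(noise_sd 0.1) and only 60 training reads per class, the four barcodes
are already recovered at 95% accuracy on the 80-read held-out test split
(AUC ≥ 0.9967 for every class); more training reads and epochs — the
regime of `scripts/acceptance.py` below — push accuracy above 0.99.
`demuxsig explain` exports per-sample attention
importance and inter-timepoint (chord) dependencies for any read, and
`demuxsig convert` round-trips datasets between the TSV signal table and
an HDF5 container.

The same pipeline is available as a library:

```python
import demuxsig as dx

panel = dx.default_panel()                      # 4 barcodes, Hamming >= 20
pore = dx.make_pore_model(k=3, seed=1)
train, val, test = dx.generate_dataset(panel, pore, dx.SimParams(noise_sd=0.1),
                                       n_per_class=100, seed=7)
model, history = dx.train(dx.ModelConfig.small(), train, val, dx.TrainParams(epochs=12))
probs, preds = dx.predict(model, test)
report = dx.classification_metrics(test.labels, preds, 4)
```

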