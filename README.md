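# mammodense

Automatic breast-tumor segmentation in whole digital mammograms with an
**ASPP-FC-DenseNet**: a fully convolutional dense network whose bottleneck is
an atrous-spatial-pyramid-pooling (ASPP) module, trained with an
inverse-class-frequency weighted cross-entropy loss. The package is aimed at
medical-image-analysis researchers who want the full method — architecture,
losses, metrics, training protocol and classical threshold baselines —
runnable and testable at desk scale on synthetic mammogram phantoms, since
clinical mammogram datasets are typically private.

## The method

Whole-mammogram tumor segmentation has two structural difficulties: tumors
span a wide size range (height/width mostly within 200–800 px at the native
4096-px resolution, i.e. a handful of pixels after resizing to the 512×512
network input), and tumor pixels are a tiny fraction of the image.

The network addresses the first problem. It is an FC-DenseNet encoder–decoder
— dense blocks (4 layers, growth rate 12) alternating with stride-2
transitions, with skip concatenations between the two paths — modified in two
ways: the number of downsampling steps is reduced from 5 to 4 (downsample
rate 16 instead of 32, so small tumors survive the encoder), and the
bottleneck dense block is replaced by an ASPP module: parallel convolutions
(one 1×1 and three 3×3 atrous branches at sampling rates 6, 12, 18)
concatenated with the bottleneck input and fused by a 1×1 convolution. An
atrous convolution at rate *r* inserts *r* − 1 zeros between kernel taps,
enlarging a *k*×*k* kernel's support to *k* + (*k* − 1)(*r* − 1) without
extra parameters — a 3×3 kernel covers 5×5 at rate 2 and 7×7 at rate 3.
Under the FC-DenseNet layer-counting convention the proposed network has
**47** counted layers; the 5-transition dense-bottleneck baseline
(FC-DenseNet56) has **56**.

The loss addresses the second problem. With class frequencies
*f<sub>l</sub>* (fractions of pixels, Σ*f<sub>l</sub>* = 1),

> L = −(1/N) Σ<sub>i</sub> (1/f<sub>y<sub>i</sub></sub>) log p<sub>i</sub>

so rare tumor pixels are up-weighted by their inverse frequency. Plain
cross-entropy and soft Dice loss are provided for ablation. Evaluation uses
DI = 2TP/(2TP+FP+FN), PA = TP/(TP+FN) (foreground recall) and
IOU = TP/(TP+FN+FP).

Because clinical data are withheld, the package ships a seeded phantom
generator: bright half-elliptical breast on dark background, multiscale
parenchymal texture, optional pectoral wedge (MLO-like), and lobulated
elliptical tumors with exact masks and configurable contrast — reproducing
the class imbalance and low contrast the method targets. A classical
double-threshold baseline (iterative/ISODATA first pass, mean-of-region
second pass, small-component removal) is included for comparison.

## Worked example

```python
import numpy as np
import mammodense as md
from mammodense.train import TrainConfig, train, evaluate
from mammodense.backend.network import realize
from mammodense.mammo_io import preprocess

cfg = md.PhantomConfig(canvas_side=64, tumor_size_range=(10, 20),
                       tumor_contrast=0.25, noise_sd=0.03)
phantoms, _ = md.generate_dataset(4, cfg, seed=7)
pairs = [(preprocess(p.image, side=64), p.mask.astype(np.int64))
         for p in phantoms]

spec = md.assemble_network(md.tiny_config())   # desk-scale ASPP variant
weights, hist = train(spec, pairs,
                      cfg=TrainConfig(epochs=75, max_steps=300, seed=3))
net = realize(spec, seed=3)
net.load_state_dict(weights)
report = evaluate(net, pairs)
print(f"training loss: {hist.train_loss[0]:.3f} -> {hist.train_loss[-1]:.3f}")
print(f"mean DI  {report.mean_di:.4f}")
print(f"mean IOU {report.mean_iou:.4f}")
print(f"mean PA  {report.mean_pa:.4f}")
```

prints

```
training loss: 2.637 -> 0.016
mean DI  0.9313
mean IOU 0.8727
mean PA  1.0000
```

i.e. 300 weighted-cross-entropy steps drive the tiny network to overlap its
four training phantoms at Dice 0.93 with every tumor pixel recovered
(PA = 1) — the optimization, gradient flow through all ASPP branches, and
the metric stack all working end to end.

The full-size architecture is inspected from the shell:

```bash
$ mammodense inspect-arch --variant aspp
variant: aspp
counted layers: 47
downsample factor: 16
...
```

The CLI also exposes `generate`, `train`, `predict` and `evaluate`
subcommands over phantom datasets (manifest CSVs, `.npz` checkpoints with
embedded architecture specs, CSV metric reports).

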