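# cbgm — five-class ECG arrhythmia classification

`cbgm` is a self-contained pipeline for classifying single heartbeats from
the electrocardiogram into five beat classes — normal (N), atrial premature
(A), premature ventricular contraction (V), left bundle branch block (L) and
right bundle branch block (R). It is aimed at researchers who want a fully
testable re-implementation of this style of beat classifier that runs
end-to-end on synthetic ECG with exact ground truth, and that can also read
real WFDB-format records (MIT-BIH layout, 360 Hz; PTB layout, 1000 Hz).

The pipeline has four stages:

1. **Denoising** — the signal is decomposed into multiscale wavelet
   coefficients (orthogonal Daubechies db6, 4 levels), each detail-band
   coefficient sequence is filtered by a scalar random-walk Kalman filter
   (predict `x⁻ = x`, `P⁻ = P + q`; gain `K = P⁻/(P⁻ + r)`; update
   `x ← x⁻ + K(z − x⁻)`, `P ← (1 − K)P⁻`), and the signal is reconstructed.
2. **R-peak detection** — QRS energy is concentrated by a band-limited
   wavelet envelope; local maxima at or above **60% of the envelope
   maximum** are kept, a 200 ms refractory rule suppresses duplicates, and
   each detection is refined to the local signal maximum (±50 ms).
3. **Segmentation** — each pulse is cut **150 ms before and 150 ms after
   the R peak** and resampled to exactly **300 samples**, then z-scored.
4. **Classification (CBGM)** — a CNN–BiGRU network with multi-head
   attention: three triplets of (1-D convolution, batch norm, max pool),
   a bidirectional GRU, then `h = 8` scaled dot-product attention heads

   head_i = softmax( (X W_i^Q)(X W_i^K)ᵀ / √d_k ) · X W_i^V,
   MultiHead = concat(head_1 … head_h) · W_o,

   followed by dropout and a dense softmax over the five classes
   (13 hidden layers in total). Training uses cross-entropy with Adam
   (learning rate 0.001, batch size 128, up to 100 epochs with early
   stopping on validation accuracy, 7:3 train/test split; a 3×3 grid
   search over learning rates {0.01, 0.001, 0.0001} and batch sizes
   {32, 64, 128} is available).

Evaluation reports a 5×5 confusion matrix and one-vs-rest precision,
sensitivity, specificity, accuracy and F1 per class and macro-averaged,
plus ROC/AUC, multi-run mean ± sd summaries, 2-D embedding projections,
an ablation harness (full model vs. minus-BiGRU vs. minus-attention), and
1-D Grad-CAM saliency maps.

The network runs on a small numpy reverse-mode autodiff engine included in
the package, so no deep-learning framework is required.

## Worked example

```python
from cbgm import (SynthConfig, make_classification_fixture, ModelConfig,
                  CBGMModel, TrainConfig, split, train, confusion,
                  report_from_confusion, CLASSES)

dataset, _ = make_classification_fixture(200, SynthConfig(seed=7))
tr, te = split(dataset, 0.7, seed=7)              # 700 / 300 pulses
model = CBGMModel(ModelConfig(), seed=7)
_, hist = train(model, tr, te,
                TrainConfig(max_epochs=15, early_stopping_patience=3, seed=7))
X, y = te.to_arrays()
pred = model.predict(X)
cm = confusion([CLASSES[i] for i in y], [CLASSES[i] for i in pred])
print("test accuracy", cm.micro_accuracy())
print(report_from_confusion(cm).to_frame().round(4))
```

This trains for 9 epochs (early-stopped) and prints:

```
test accuracy 1.0
       accuracy  precision  specificity   f1  sensitivity
N           1.0        1.0          1.0  1.0          1.0
A           1.0        1.0          1.0  1.0          1.0
V           1.0        1.0          1.0  1.0          1.0
L           1.0        1.0          1.0  1.0          1.0
R           1.0        1.0          1.0  1.0          1.0
macro       1.0        1.0          1.0  1.0          1.0
```

i.e. on the clean, morphologically separable synthetic fixture the
classifier reaches perfect held-out accuracy within a few epochs — the
fixture establishes that the implementation learns; it does not emulate
the difficulty of real clinical recordings.

The same stages are scriptable from the shell:

```
cbgm synth --fs 360 --duration 60 --classes N,V --seed 7 --out rec/
cbgm preprocess --record rec/synth --out segments.csv
cbgm train --segments segments.csv --epochs 15 --seed 7 --out model.npz
cbgm evaluate --ckpt model.npz --segments segments.csv --out report.json
cbgm explain --ckpt model.npz --segments segments.csv --index 0 --out map.csv
cbgm run --config pipeline.yaml        # the whole pipeline + manifest
```

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch: it synthesizes
a noisy labelled record, denoises it and detects its R peaks, builds a
balanced 5-class fixture, trains the classifier on a 7:3 split, evaluates
accuracy and AUC on the held-out pulses, and computes a Grad-CAM map —
all derived from one seed:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A stage-by-stage summary is printed to stderr and the results file is
written to `--out`.
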