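# Methods

This note documents the models and procedures implemented in `cbgm`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish.

## Wavelet transform

The multiscale decomposition is a periodized, decimated (Mallat) transform
with orthonormal Daubechies filters. Filter coefficients are computed at
import time by spectral factorization of the Daubechies product polynomial
`P(y) = Σ_k C(N−1+k, k) y^k`: its roots are mapped into the z-plane through
`y = (2 − z − z⁻¹)/4`, the minimum-phase half is kept, and the result is
normalized to sum √2. The construction reproduces the closed-form db2
filter to machine precision and is orthonormal to ~1e−15 for db4–db8
(tested). Signals are zero-padded at the end to a multiple of `2^levels`
so every level has even length; the original length is restored after
reconstruction. Because the transform is orthonormal, energy is conserved
across bands and reconstruction is exact to floating-point rounding
(the test bound is 1e−8 relative; observed ~2e−15).

Defaults: `db6`, 4 levels. At 360 Hz the four detail bands cover
90–180, 45–90, 22.5–45 and 11.25–22.5 Hz.

## Denoising: per-band Kalman filtering

Each detail-coefficient sequence is filtered by a scalar random-walk
Kalman filter — state `x_t = x_{t−1} + w_t` with `w ~ N(0, q)`,
observation `z_t = x_t + v_t` with `v ~ N(0, r)`:

    predict  x⁻ = x,  P⁻ = P + q
    gain     K  = P⁻ / (P⁻ + r)
    update   x ← x⁻ + K (z − x⁻),  P ← (1 − K) P⁻

Its steady state has the closed form `P* = (−q + √(q² + 4qr))/2`,
`K* = (P* + q)/(P* + q + r)` (the positive root of the scalar Riccati
fixed point `P = (P + q) r / (P + q + r)`), which the tests verify against
direct iteration for 20 random `(q, r)` pairs.

When `q`/`r` are not set explicitly they are estimated per record:
`r = σ̂²` with `σ̂ = MAD(d₁)/0.6745` (the standard robust noise estimate
from the finest detail band, valid because white observation noise spreads
evenly across bands), and per band `q = max(mean(d²) − r, 10⁻³ r)` — the
band's power in excess of the noise floor. The resulting steady-state
gains behave like band-wise Wiener weights: noise-only bands are strongly
smoothed (`K* ≈ √(q/r)` for `q ≪ r`), bands carrying QRS energy pass
(`K* → 1` for `q ≫ r`). A fixed-gain alternative (constant `q`, `r` for
all bands) remains available through `DenoiseConfig(q=…, r=…)`; it was not
kept as the default because a uniform low gain flattens the sparse,
spike-like QRS detail coefficients and can worsen reconstruction error.
The approximation band passes through unfiltered by default (baseline
drift removal is not this stage's job).

On synthetic records with white noise at SNR 0, 5 and 10 dB the denoiser
reduces mean-squared error against the clean truth in 10/10 seeded
replicates at every SNR (typical MSE ratio 0.22–0.29).

## R-peak detection

Detection thresholds a QRS energy envelope at a fixed fraction (default
0.60) of its per-record maximum:

1. **Band signal.** Undecimated (à trous) wavelet details are summed over
   the levels whose dyadic band lies mostly inside 5–22.5 Hz (levels 4–5
   at 360 Hz). Each dilated filter is applied forward and then reversed,
   making the band signal zero-phase. The undecimated transform is used
   here — not the decimated one from the denoiser — because decimation is
   shift-variant: identical beats would receive envelope heights varying
   by ~20% with their sample alignment, which is fatal to a fixed
   60%-of-maximum threshold. The 5–22.5 Hz range follows standard QRS
   detector practice; wide ventricular complexes concentrate their energy
   in the lower half of it.
2. **Envelope.** RMS of the band signal over a 50 ms moving window.
3. **Thresholding.** Local envelope maxima at or above
   `threshold_fraction × max(envelope)` become candidates; candidates
   closer than the 200 ms refractory period (the physiological minimum RR
   interval) keep only the larger.
4. **Refinement.** Each candidate is moved to the signal maximum within
   ±50 ms, and duplicates are collapsed.

Flat or empty signals yield an empty detection list, not an error.
On mixed-class synthetic records the detector reaches sensitivity and
positive predictivity 1.0 when clean and ≥ 0.987 sensitivity at 5 dB SNR
(±50 ms matching tolerance).

## Segmentation

Each beat window spans 150 ms on each side of the R peak —
`round(0.150 · fs)` samples per side — and is resampled to exactly 300
samples by linear interpolation (at 1000 Hz the window is already 300
samples and the resampling is the identity). This resolves the apparent
tension between a 300-sample input layer and a 360 Hz source rate (where
300 ms span only 108 samples): every rate maps to the same fixed-length
input. Windows crossing a record boundary are dropped and counted.
Each segment is z-scored; constant windows map to zeros.

## The classifier

Input: one 300-sample pulse. Architecture (13 hidden layers):

| stage | layers | output shape |
|---|---|---|
| conv triplet ×3 | conv(32,k5) BN pool2 · conv(64,k5) BN pool2 · conv(128,k3) BN pool2 | (37, 128) |
| recurrence | BiGRU, 64 units/direction | (37, 128) |
| attention | 8 heads, d_model 128, d_k 16 | (37, 128) |
| head | dropout 0.3 → flatten → dense softmax | (5,) |

Convolutions are 'same'-padded so pooling alone controls length
(300 → 150 → 75 → 37). ReLU follows each batch norm. The GRU uses the
single-bias gate form `z = σ(xW_z + hU_z + b_z)`,
`r = σ(xW_r + hU_r + b_r)`, `n = tanh(xW_n + b_n + r·(hU_n))`,
`h' = (1−z)n + zh`; the bidirectional wrapper runs the sequence both ways
and concatenates. Attention is self-attention on the BiGRU output
sequence: per head `softmax((XW^Q)(XW^K)ᵀ/√d_k)·XW^V`, heads concatenated
and recombined by `W_o`; no residual connection or positional encoding is
added (the sequence is short and order is already encoded by the GRU).
The exact filter counts/kernels are not externally fixed; the defaults
above are a standard choice for a length-300 input and are configurable.

The network runs on a small reverse-mode autodiff engine over numpy
(float32). Inference runs in a no-graph mode; training frees intermediate
gradients during the backward sweep. Gradient correctness is spot-checked
against finite differences, and a test asserts that every trainable
tensor receives a nonzero gradient (no dead sub-module).

## Training protocol

Cross-entropy, Adam (β = 0.9/0.999), learning rate 0.001, batch size 128,
up to 100 epochs with early stopping on validation accuracy (patience 10
by default; the best-validation weights are restored). The optimizer is
Adam because the source protocol names none and it is the field default
for this architecture family. Splits are stratified 7:3 at beat level;
per-class train counts stay within one sample of `0.7 × count`. The grid
search evaluates the 3×3 grid over learning rates {0.01, 0.001, 0.0001}
and batch sizes {32, 64, 128}, breaking ties toward the lower learning
rate and then the smaller batch. Stratified k-fold cross-validation and a
10-run mean ± sd aggregation (one row per run plus mean and sd) are
provided. No class re-weighting is applied by default. All randomness
flows from explicit seeds; two runs with the same seed produce identical
loss trajectories.

## Evaluation

Per class `c` the one-vs-rest reduction is `TP = cm[c][c]`,
`FP = colsum − TP`, `FN = rowsum − TP`, `TN = total − TP − FP − FN`, with

    precision   = TP / (TP + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 · precision · recall / (precision + recall)

A metric whose denominator is zero is reported as 0 and logged. Macro
values are unweighted class means; the overall accuracy is additionally
reported as trace/total (micro) — both are labelled, since the per-class
"accuracy" is only meaningful one-vs-rest. These formulas are tested
against an exact-rational brute-force counting oracle on 200 random
confusion matrices. ROC is one-vs-rest per class with AUC by the
trapezoid rule (classes absent from the truth are excluded from the macro
average with a warning); AUC is checked against the Mann–Whitney rank
statistic and is invariant under monotone score transforms. Embedding
projections take the penultimate (pre-dense) features into 2-D via t-SNE
(default, seeded) or PCA, reporting the silhouette score by true label.

## Synthetic ECG generator

Beats are Gaussian sums: each class template lists (amplitude mV,
offset ms from R, width ms) components. N has a canonical P-QRS-T; A has
a reduced, early P, normal QRS, and a shortened (0.65×) preceding RR
interval; V is a wide (σ = 26 ms, ≥120 ms equivalent QRS), high-amplitude
complex without P and with a discordant T; L and R are notched, widened
complexes rendered as two offset R components with opposite S/R′
patterns. The dominant R component sits at offset 0 in every template so
the recorded ground-truth index is the signal apex. R amplitudes
(1.15–1.30 mV) and Q/S depths are set so each class's QRS energy in the
5–22.5 Hz detection band is within ~25% of the strongest class — real R
waves across these beat types are broadly similar in prominence, and it
keeps one fixed 60% threshold meaningful for every class. Per-class
morphology can be overridden (`SynthConfig.template_overrides`), which
the interpretability tests use to build a fixture in which V differs from
N only inside the QRS support.

Rhythm: RR intervals are Gaussian (default mean 750 ms ≈ 80 bpm, jitter
40 ms, floored at 300 ms); premature beats (A, V) arrive at 0.65× their
scheduled interval. Noise: baseline wander 0.1 mV at 0.3 Hz, powerline
0.05 mV at 50 Hz, white noise 0.05 mV sd — typical artifact scales — or a
target SNR in dB that sets the white-noise power against the clean beat
train. Everything is reproducible from one seed.

**What the fixtures do not establish.** Templates are deterministic per
class: there is no within-class morphological variability, no heart-rate
drift, no electrode artifacts, and no class imbalance. Clean fixtures are
therefore linearly separable (a nearest-centroid classifier exceeds 99%
accuracy), and the classifier reaching ~100% on them demonstrates that
the implementation learns and generalizes across the train/test split —
not that it would reach comparable accuracy on clinical recordings.
For the same reason the ablation comparison saturates: trained to their
early-stopped best, the ablated variants also reach ~1.0 on the fixture,
so the full-model-first ordering holds as an equality rather than a
strict gap.

## Grad-CAM

The class score is the pre-softmax logit (the standard choice; softmax
gradients saturate). Channel weights are the time-averaged gradients of
that logit with respect to a convolutional stage's activations (default:
the last triplet's output, 37 time steps); the map is the rectified
channel-weighted activation sum, linearly upsampled to the 300-sample
grid and max-normalized. An all-zero raw map (e.g. constant activations)
is returned as zeros with an explicit flag rather than normalized.
Saliency is invariant to uniform logit shifts, and upsampling preserves
the argmax to within one coarse-grid cell (~8 samples). On a fixture
whose wide-QRS class differs from normal beats only inside the QRS
support, the saliency argmax of correctly classified V pulses falls
within that support (±25 ms) for 40/40 test beats; on the default
fixture, where V also carries a discordant T wave, the model may
legitimately attend to the T region instead.

## Numerical conventions and degenerate inputs

Sample indices are 0-based; annotation indices refer to the R-peak
sample. Only the five literal symbols N/A/V/L/R map to classes; all
other annotation symbols are dropped. Multi-lead records feed a single
configurable lead (default: the first). WFDB support covers text
headers, format-16 signals and the MIT annotation byte format (including
long-interval skip codes) — enough to round-trip locally written
fixtures. Segment datasets are self-describing CSV with 12 significant
digits (round-trip error < 1e−9 per sample). Empty signals and flat
envelopes yield empty detections; boundary beats are dropped silently
(logged); a single-run aggregation reports sd = 0 with a flag; training
aborts with diagnostics if the loss becomes non-finite.

## Known limitations

- The autodiff engine is single-threaded numpy; a full 100-epoch run on
  tens of thousands of beats is feasible but slow compared to GPU
  frameworks. Desk-scale runs (≈1000 beats, ≤15 epochs) take ~30 s.
- The decimated DWT's shift variance is worked around for detection but
  still affects the denoiser slightly (denoising quality can vary by a
  few percent with signal alignment).
- WFDB reading is limited to the subset described above (no format 212,
  no multi-segment records), so real MIT-BIH files must be converted to
  format 16 first.
- Splits are at beat level by default, which on real data inflates
  accuracy relative to patient-wise protocols; a record-level split is
  available (`split(..., by_record=True)`) but cannot stratify classes
  when single-class records dominate.
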