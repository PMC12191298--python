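# Methods

This note documents the models and procedures `ecgmff` implements, the
choices made where the design was open, and what the synthetic experiments
do and do not demonstrate.

## Preprocessing

**Baseline removal.** Baseline wander (respiration, electrode motion;
< 0.5 Hz) is estimated per lead by a two-stage median-filter cascade and
subtracted. Window lengths are 200 ms then 600 ms (configurable): the short
window erases P-wave and QRS deflections from the estimate, the long window
the T wave, leaving only the drift. On a drift-free signal the operator is
close to the identity; on a constant offset it returns exactly zero.

**Wavelet denoising.** Each lead is decomposed to 5 levels (configurable to
9) with the db6 wavelet, whose shape resembles the QRS complex. For detail
level *b* (1 = finest) the threshold is

    TE_b = σ_b · √( 2·ln‖d_b‖ / ln(b+1) ),   σ_b = median(|d_b|) / 0.6745,

with ‖d_b‖ the L2 norm of the level's detail coefficients and 0.6745 the
0.75 quantile of the standard normal (the MAD-to-σ factor). Coefficients
with |d| ≤ TE_b are zeroed; larger ones are shrunk by TE_b with sign
preserved (soft thresholding). Approximation coefficients pass through
untouched. Numerical choices: the logarithms are natural; the radicand is
clamped at 0 so TE_b ≥ 0 even when ‖d_b‖ < 1; the threshold condition is
applied to |d|, not the signed coefficient, so negative coefficients shrink
symmetrically — the signed form would zero every negative coefficient,
contradicting the sign-preserving shrinkage branch. The noise estimate uses
median(|d_b|): the median of the signed coefficients is ~0 for any
symmetric coefficient distribution and would produce a useless zero
threshold. The resulting operator is odd: denoise(−x) = −denoise(x).

**R-peak detection.** Classic Pan–Tompkins on lead II (the imaging lead,
chosen because it carries the largest R projection): 5–15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration, adaptive dual
thresholds with search-back, 200 ms refractory period. Detected indices are
refined to the local extremum of the band-passed signal within ±50 ms, and
the peak positions are shared across all 12 leads. Records shorter than 2 s
are rejected (no room for threshold adaptation).

**Segmentation.** One beat per R peak: 250 samples before to 400 samples
after the R index inclusive — 651 samples per lead at 1000 Hz. Beats whose
window crosses a record edge are dropped rather than padded (padding would
fabricate signal). Records at other rates are polyphase-resampled to
1000 Hz first.

## Imaging

**GAF spectrum image.** The lead-II beat's one-sided DFT magnitude spectrum
(326 bins for 651 samples, DC retained) is smoothed to the image side
length by piecewise aggregation approximation (contiguous frame means),
rescaled to [−1, 1] by x̃ᵢ = ((xᵢ−max)+(xᵢ−min))/(max−min), mapped to polar
angles φᵢ = arccos x̃ᵢ, and imaged as G[i,j] = sin(φᵢ−φⱼ), computed in the
closed matrix form √(1−x̃²)·x̃ᵀ − x̃·√(1−x̃²)ᵀ. G has a zero diagonal, is
antisymmetric, and lies in [−1, 1]. The polar radius rᵢ = tᵢ/N is computed
and exposed but does not enter G (which depends only on the angles).
Open choices resolved: the spectrum fed to the GAF is the plain magnitude
(not power or log-magnitude); the default image side is 224 with a 32-pixel
desk-scale variant; images are passed to the network as single-channel
scalar fields — colormapped renderings exist only as an optional PNG writer
for visual inspection.

**S-transform image.** The discrete Stockwell transform is computed in the
spectral domain: for DFT bin n > 0 the time row is the inverse DFT over m
of X[n+m]·exp(−2π²m²/n²) — a Gaussian voice whose width scales inversely
with frequency, giving wavelet-like multiresolution with STFT-like phase.
With this normalization the time-marginal identity Σ_τ S(τ, f) = X(f) holds
exactly for every f > 0, and the transform is linear; both are asserted in
the tests against brute-force DFT oracles. The f = 0 row, where the
Gaussian window degenerates, is defined as the signal mean. For imaging the
band (0, f_max] with f_max = 45 Hz (the ECG diagnostic band) is analyzed,
the magnitude is resized by area interpolation to the image side, and
values are scaled to [0, 1] by the global maximum (an all-zero beat maps to
an all-zero image).

## Network

Three branches, each ending in global average pooling:

* **1D SE-ResNet18** over the 12 × 651 beat: kernel-15 first convolution
  (stride 2, 64 filters), max-pool 3/2, four stages of two residual blocks
  with kernel-7 convolutions at widths 64/128/256/512, a
  squeeze-and-excitation unit in every block (two-layer perceptron
  bottlenecks 4/8/16/32, i.e. reduction 16, with a sigmoid gate), and
  dropout 0.2 between each block's two convolutions. The pooled feature
  passes one more dropout (0.2) before fusion, mirroring the standalone 1D
  network's pool–dropout–fc tail.
* **Two 2D ResNet18s** (7×7 stem, 3×3 blocks, same stage widths) over the
  single-channel GAF and ST images. They do not share weights and carry no
  SE blocks — the SE/dropout augmentations are read as belonging to the 1D
  variant; whether the 2D trunks should also carry SE was left open by the
  architecture description and resolved in favor of the plain trunks.

The branch features (512 each at full width) are concatenated and mapped to
class logits by a single fully connected layer; softmax is applied in the
loss and prediction paths. Fusion is end-to-end feature concatenation under
a single cross-entropy head, not per-branch training with decision-level
voting. `width_multiplier` scales all stage widths (and SE bottlenecks) for
desk-scale work; ablation subsets of the branches shrink the head
accordingly.

The entire stack — convolutions, batch normalization, pooling, SE, dropout,
the SGD-with-momentum optimizer and every backward pass — is implemented in
numpy; all analytic gradients are verified against central-difference
numerical gradients in the test suite.

**Batch-norm recalibration.** After the last epoch the batch-norm running
statistics are recomputed in one clean pass over the training partition
(cumulative averaging, dropout disabled, no weight updates). The
exponential running estimates otherwise lag the final weights on short
schedules, which can make inference-mode predictions collapse even when
training-mode accuracy is perfect.

## Training and evaluation protocol

Cross-entropy loss, SGD with learning rate 0.001 and momentum 0.9, batch 64,
60 epochs by default; no learning-rate schedule, early stopping, class
re-weighting or augmentation. Two split paradigms: intra-patient (beat-level
stratified 7:2:1 train/validation/test) and inter-patient (patient-level 7:3
train/test, no validation set, no patient shared across partitions — the
stricter generalization protocol; a class with a single patient stays
wholly in training, with a warning). k-fold cross-validation (default 10)
assigns folds at beat level intra and patient level inter, and is an
independent protocol from the fixed-ratio splits.

Metrics, all in percent: Acc = (TP+TN)/total, Sen = TP/(TP+FN),
Pre = TP/(TP+FP), Spe = TN/(TN+FP), F1 = 2·Sen·Pre/(Sen+Pre), and overall
AccT = Σ_y TP_y / Σ_y (TP_y+FN_y) (the trace over the total). Multi-class
values are macro-averages of per-class one-vs-rest tallies (the averaging
scheme was unstated and macro chosen); 0/0 is defined as 0. Detection
treats MI as the positive class.

## Synthetic data generator

Records are quasi-periodic trains of Gaussian bumps — one per wave
(P, Q, R, S, T), with per-wave centers/widths/amplitudes in ms and mV —
projected onto the 12 leads through fixed lead-amplitude templates (lead II
carries the largest R). RR intervals carry configurable fractional jitter.
MI-like classes perturb the template the way infarcts present: a smooth
ST-segment offset of ±0.2 mV on the leads facing the affected wall, T-wave
inversion on three of them, and (for the septal class) 4× deepened Q waves.
Noise adds a 0.1 mV / 0.3 Hz baseline-wander sinusoid, 0.05 mV mains
interference at 50 Hz and 0.05 mV broadband Gaussian noise — amplitudes a
scientist would call moderately noisy for resting ECG. Ground-truth R-peak
indices ride along in the record metadata, so detector accuracy is
measurable (matching tolerance ±50 ms).

What the generator does **not** emulate: beat-to-beat morphology variation
within a patient, arrhythmia, electrode artefacts, inter-patient amplitude
diversity, or realistic class priors. Passing synthetic tests therefore
demonstrates that the pipeline's machinery is correct and that the model
can learn cleanly separable multi-domain structure — not clinical
performance on real ECG databases, which additionally requires GPU-scale
training on tens of thousands of beats.

## Desk-scale study conditions

The reference detection study (used by the test suite and
`scripts/acceptance.py`) fixes: healthy vs anterior-MI-like classes, 8
patients per class × one 10 s record at 70 bpm (5% RR jitter), default
noise, 32 × 32 images, width multiplier 1/8 (~0.5 M parameters), SGD with
lr 0.005, batch 32, 12 epochs. The reduced learning-rate/epoch schedule is
the package's choice for the reduced width and sample size — the full-scale
defaults destabilize the small-batch numpy optimizer on this problem — and
the inter-patient split holds out ~44 beats from unseen patients.

## Known limitations

* The numpy network trains on CPU at desk scale only; full-width 224-pixel
  training at database scale is out of scope.
* Pan–Tompkins runs on lead II only; no multi-lead consensus detection.
* WFDB support covers the header + format-16 subset the pipeline needs.
* The S-transform is computed densely per frequency bin (O(L log L) per
  bin); fine for 651-sample beats, not tuned for long records.
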