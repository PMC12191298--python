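# ecgmff — multi-domain feature fusion for ECG myocardial-infarction analysis

`ecgmff` implements an end-to-end pipeline for detecting and localizing
myocardial infarction (MI) from 12-lead ECG by fusing three views of each
heartbeat:

1. **Time domain** — the raw 12-lead beat (12 × 651 samples at 1000 Hz:
   250 samples before the R peak, 400 after).
2. **Frequency domain** — a Gramian Angular Field (GAF) image of the beat's
   lead-II DFT magnitude spectrum. The spectrum is PAA-smoothed to the image
   side length, rescaled to [−1, 1], mapped to polar angles
   φᵢ = arccos(x̃ᵢ), and imaged as the antisymmetric difference field
   G[i, j] = sin(φᵢ − φⱼ).
3. **Time–frequency domain** — the magnitude of the discrete Stockwell
   (S-) transform of the lead-II beat,
   S(τ, f) = ∫ x(t) (|f|/√2π) e^{−(τ−t)²f²/2} e^{−i2πft} dt,
   restricted to the 0–45 Hz diagnostic band.

A three-branch convolutional network (MFF-CNN) consumes the triple: a 1D
SE-ResNet18 (kernel-15 stem, kernel-7 residual blocks, squeeze-and-excitation
channel attention, dropout 0.2) over the beat, and two 2D ResNet18 trunks
over the GAF and ST images. The 512-wide branch features are concatenated
and classified through a softmax head. Training uses cross-entropy with SGD
(lr 0.001, momentum 0.9, batch 64, 60 epochs by default), and evaluation
follows both the *intra-patient* (beat-level 7:2:1) and *inter-patient*
(patient-level 7:3, no patient shared between partitions) paradigms with
Acc/Sen/Pre/Spe/F1 per class and overall accuracy AccT.

The package is aimed at researchers in physiological signal processing who
want a fully inspectable, CPU-runnable reference implementation: every stage
— median-filter baseline removal, improved-threshold db6 wavelet denoising
(level thresholds TE_b = σ_b √(2 ln‖d_b‖ / ln(b+1)), σ_b = median(|d_b|)/0.6745),
Pan–Tompkins R-peak detection, beat segmentation, GAF/ST imaging, the network
(including backpropagation) and the metric suite — is plain numpy/scipy code
with property-based tests. A synthetic 12-lead ECG generator with
ground-truth R peaks and MI-like morphology (ST-segment shift, T-wave
inversion, pathological Q) makes the whole pipeline testable without any
data download.

## Worked example

Fit the reduced-width fused model on a synthetic healthy-vs-anterior-MI
cohort (8 patients per class, one 10 s record each) under the inter-patient
paradigm:

```python
from ecgmff import (SynthConfig, generate_dataset, MffClassifier,
                    SplitSpec, TrainConfig)
from ecgmff.imaging import ImagingConfig
from ecgmff.train_eval import BeatDataset

records = generate_dataset(
    8, ["HC", "AMI"],
    SynthConfig(duration=10, heart_rate=70, rr_jitter=0.05), seed=0)
dataset = BeatDataset.from_records(records, ImagingConfig(image_size=32))
model = MffClassifier(dataset, width_multiplier=0.125,
                      task="detection", seed=0)
results = model.fit(
    SplitSpec(paradigm="inter_patient", seed=0),
    TrainConfig(learning_rate=0.005, batch_size=32, epochs=12, seed=0))
print(results.summary())
```

Output:

```
Multi-domain feature-fusion ECG classifier
==============================================
task:              detection
classes:           AMI, HC
branches:          beat, gaf, st
width multiplier:  0.125
parameters:        492,706
train / test:      133 / 44 beats
epochs:            12 (final loss 0.0354)
Confusion matrix (rows = truth, columns = prediction):
     AMI  HC
AMI   22   0
HC     0  22

Per-class metrics (%):
       Acc    Sen    Pre    Spe     F1
AMI  100.0  100.0  100.0  100.0  100.0
HC   100.0  100.0  100.0  100.0  100.0

Macro averages (%): Acc=100.00  Sen=100.00  Pre=100.00  Spe=100.00  F1=100.00
Overall accuracy AccT = 100.00%
```

The confusion matrix covers the 44 beats of the held-out patients (none of
whom contributed training beats); with the strongly separated synthetic
morphologies the fused model classifies all of them correctly.

A command-line interface mirrors the library:

```bash
ecgmff synth --out data/raw --classes HC,AMI --n-per-class 4 --seed 0
ecgmff preprocess --in data/raw --out data/beats
ecgmff imaging --beats data/beats --out data/images --size 224 --fmax 45
ecgmff run --config pipeline.yaml      # full pipeline from a YAML config
ecgmff ablate --config pipeline.yaml   # branch-combination study
ecgmff crossval --config pipeline.yaml --folds 10
```

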