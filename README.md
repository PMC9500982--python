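# eegcube

Spatiotemporal 3D representations of multichannel EEG and a
channel-bottleneck 3D convolutional network (CNN-BN) for binary
valence/arousal classification, with exact parameter and FLOP accounting.

## The problem

Emotion recognition from EEG is commonly framed on DEAP-style recordings:
32-channel scalp EEG sampled at 128 Hz while a subject watches one-minute
stimuli, each trial rated 1-9 for valence (pleasantness) and arousal
(intensity).  Deep 3D CNNs classify these well but are expensive.  This
package implements two things:

1. **A 3D spatiotemporal representation.**  Each 1-s non-overlapping window
   of a trial is rendered sample by sample as a topographic map: the 32
   channel amplitudes are placed on a 9×9 grid following the 10–20 electrode
   layout, the 49 empty cells are filled by thin-plate-spline RBF
   interpolation, and the map is upsampled to 64×64 with Keys bicubic
   interpolation.  Stacking the 128 per-sample maps gives a 128×64×64 tensor
   per window.

2. **The CNN-BN architecture and its baselines.**  CNN-BN is a 3D CNN whose
   expensive 7×3×3 convolutions sit inside *channel bottleneck blocks*: a
   1×1×1 convolution first reduces the channel width C to C/4, the 7×3×3
   convolution runs at the reduced width, and a second 1×1×1 convolution
   restores the output width.  The full network is one convolution block,
   five bottleneck blocks and a two-layer dense head (16 conv / 16 batch-norm
   / 17 ReLU / 6 max-pool / 2 dense layers).  A plain six-block 3D CNN
   ("modified C3D", all 7×3×3) and a three-layer LSTM are provided as
   baselines.

The cost accounting uses the standard conventions: parameters are
`C_out·C_in·d·k·k (+bias)` per convolution, FLOPs are 2 per
multiply-accumulate with selectable element-wise add-ons for batch norm,
ReLU and pooling.  On a 1×128×64×64 input the bottleneck design cuts
parameters from 16.02 M to 1.11 M and FLOPs from 448.97 G to 22.36 G —
a ~93% / ~95% reduction.

Everything runs on a numpy backend (models instantiate, train with SGD and
evaluate without a deep-learning framework), and a synthetic DEAP-structured
EEG generator with a controllable class-effect dial makes the whole pipeline
testable without the gated DEAP download.  An optional reader for the real
DEAP "preprocessed Python" per-subject files is included.

## Worked example

```python
import eegcube as ec

# profile the proposed model against the plain baseline
report = ec.complexity_report([ec.build_c3d(), ec.build_cnn_bn(dense_hidden=64)])
print(report.to_json())
```

prints

```json
{
  "schema_version": 1,
  "models": {
    "c3d": {
      "parameter_count": 16024578,
      "parameters_millions": 16.02,
      "flops": 448968180224,
      "flops_giga": 448.97
    },
    "cnn-bn": {
      "parameter_count": 1108834,
      "parameters_millions": 1.11,
      "flops": 22362855744,
      "flops_giga": 22.36
    }
  },
  "baseline": "c3d",
  "proposed": "cnn-bn",
  "parameter_reduction_percent": 93.07,
  "flops_reduction_percent": 95.02
}
```

i.e. the bottleneck network needs 1.11 M trainable parameters and 22.36
GFLOPs per forward pass where the plain 3D CNN needs 16.02 M and 448.97 G —
reductions of 93.07% and 95.02%.

The representation and training pipeline, end to end on synthetic data:

```python
import numpy as np
import eegcube as ec

cfg = ec.SynthConfig(n_trials_per_subject=4, trial_seconds=5.0,
                     effect_size=2.0, seed=0)
trials = ec.generate_dataset(cfg).trials()
dataset = ec.build_dataset(trials, ec.MontageGrid.deap(),
                           window_seconds=1.0, target_side=32)
print(dataset.tensors.shape)        # (8, 128, 32, 32): 4 trials x 2 windows
```

A command-line interface mirrors the library:
`eegcube synth`, `eegcube represent`, `eegcube archspec`,
`eegcube complexity-report`, `eegcube train` (see `--help` on each).

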