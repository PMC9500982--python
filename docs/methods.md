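# Methods

## 3D spatiotemporal representation

A trial is a channel-major array of EEG amplitudes (µV) at a fixed sampling
rate (128 Hz for DEAP-style data) with per-trial 1–9 valence/arousal
ratings.  The pipeline is:

1. **Trim.**  The leading pre-stimulus segment (default 3 s) is dropped;
   for a 63-s trial this keeps the 60 s of stimulus-locked signal.
2. **Window.**  Non-overlapping windows of `window_seconds` (default 1 s);
   trailing samples that do not fill a window are discarded (floor rule).
3. **Project.**  Each time sample's 32 channel values are placed on a 9×9
   grid.  The electrode-to-cell table ships as a versioned JSON resource
   (`resources/deap_montage_9x9.json`): rows run anterior→posterior, columns
   left→right, midline channels in column 4, 0-based indices.  The table is
   a documented convention for the 10–20 layout, overridable by passing any
   other `MontageGrid`.
4. **Fill.**  The 49 electrode-free cells are interpolated with a
   thin-plate-spline RBF (scipy's `RBFInterpolator`) augmented with a
   degree-1 polynomial tail, nodes at occupied cell centres.  The polynomial
   tail makes constant and planar fields reproduce exactly, which the suite
   uses as an invariant; electrode-backed cells are never altered
   (interpolation, not smoothing).  All 81 cells of the square grid are
   filled — no scalp-shaped mask.
5. **Upsample.**  Keys bicubic convolution (a = −0.5), align-corners
   coordinate mapping (source corners map onto target corners), indices
   reflected at the borders, to `target_side`×`target_side` (default 64).
   This dialect is hand-implemented because library resamplers use B-spline
   or other kernels; a direct per-point kernel evaluation serves as the test
   oracle.  Downsampling below the source side is rejected.
6. **Stack.**  The per-sample maps are stacked in temporal order: depth
   index 0 is the earliest sample, giving 128×64×64 per 1-s window.

No amplitude normalization is applied by default (an optional per-channel
z-scoring flag exists on `build_dataset`).  Every stage is linear in the
channel amplitudes, so for a fixed montage the whole channels→map transform
is precomputed once as a matrix (`GridRenderer`); the staged functions
remain the reference path and the suite asserts their agreement.  Scaling
all amplitudes by *s* therefore scales every tensor entry by *s*, and
rendering is bit-deterministic.

## Architectures

Models are declarative layer lists (`ModelSpec`); shape tables, layer
censuses, parameter counts, FLOP counts and the numpy instantiation all
derive from the same spec.

**CNN-BN.**  Convolution block: 7×3×3 conv (stride 1, padding 3×1×1,
1→64 channels), batch norm, ReLU, 2×1×1 max pool (stride 2×1×1).  Five
bottleneck blocks with (C_bn, C_out) = (16,128), (32,256), (64,256),
(64,256), (64,256): 1×1×1 reduce → 7×3×3 at the reduced width → 1×1×1
expand, each conv followed by batch norm and ReLU, then a 2×2×2 max pool.
Each block's reduce conv takes the channel width to a quarter of the block
input.  Head: flatten (2048 features on the default input) → dense(C_mid) →
ReLU → dropout 0.5 → dense(2).  The 7×3×3 padding of 3×1×1 is forced by the
requirement that convolutions preserve D, H, W at stride 1.  C_mid is 128
in the training profile; the complexity-report profile uses 64, which is
the width consistent with the published 1.11 M total (both supported).

**Modified C3D.**  Six blocks of [7×3×3 conv, BN, ReLU, pool] with output
channels 64, 128, 256, 256, 256, 256; pool 2×1×1 after block 1 and 2×2×2
after blocks 2–6; dense 512 → 2.  The interior widths are not printed in
the source material; this schedule was selected by matching the published
parameter/FLOP totals (within 0.2% and 0.15%) and is fully overridable.

**LSTM baseline.**  Raw 1-s segments as 128 time steps × 32 features; three
stacked LSTM layers (hidden 128, a conventional choice), each followed by
tanh; last time step → dense(128) → ReLU → dropout 0.5 → dense(2).

Conv biases are included by default (a `conv_bias=False` switch exists,
since batch norm makes them redundant).  Initialization: Kaiming fan-in
normals for conv/dense weights, orthogonal recurrent matrices, forget-gate
bias 1, all driven by one seeded generator, so two builds with the same
seed have identical parameter checksums.

## Complexity accounting

Parameters: conv `C_out·C_in·d·k·k + C_out(bias)`; batch norm `2C`; dense
`out·in + out`; LSTM `4(h(in+h) + 2h)` per layer.  FLOPs (one forward
pass): 2 per MAC for conv/dense/LSTM-gate products; element-wise add-ons
(on by default, selectable): 2 ops/element for batch norm, 1 for
ReLU/tanh, kernel-volume−1 comparisons per output element for max pooling.
Bias additions are not counted separately.  Millions/giga figures are
rounded half-up to two decimals and reduction percentages are computed from
the rounded figures, as such tables are conventionally printed; if a
baseline rounds to zero the raw totals are used instead.

Under these conventions, on 1×128×64×64: CNN-BN (C_mid=64) has exactly
1,108,834 parameters (1.11 M) and 22.36 GFLOPs; C3D has 16,024,578 (16.02 M)
and 448.97 G.  The counters reproduce the published C3D figures to within
0.2% but the published 22.74 G for CNN-BN only to within ~1.7%: FLOP totals
depend on the counting tool's treatment of batch norm, activations, pooling
and biases, which is not documented for the published number.  The
per-layer breakdown reports conv/dense and element-wise totals separately
so any convention in that family can be reconstructed.

`measure_inference_time` reports median wall-clock per forward pass on the
numpy backend.  It is hardware- and backend-dependent and is deliberately
excluded from any validated claim.

## Training and evaluation

Ratings binarize at 5 with the boundary assigned to *low* (the split rule
must put 5 somewhere; assigning the boundary to low is the declared
convention).  Splits are uniform window-level 80/20 partitions,
seed-reproducible; window-level splitting mirrors the protocol being
modelled but leaks trial identity between train and test, so a caller can
split at trial granularity by filtering on the provenance table.  The loss
is mean binary cross-entropy (natural log, probabilities clipped at 1e-7);
the optimizer is plain SGD (momentum and weight decay default 0,
configurable), mini-batches of 32, initial learning rate 0.01 multiplied by
0.9 every 10 epochs, fixed 90-epoch budget with no early stopping (an
optional `target_accuracy` exit exists for smoke runs).  Metrics are
recall, precision, F1 and accuracy from the confusion counts with "high"
as positive; zero-denominator cases return 0 and are flagged.  Repeated
evaluation re-splits with seed `base+r`, retrains, and reports per-repeat
confusion matrices plus mean and population SD (n = repeats) per metric.

The numpy backend implements forward and backward passes for conv3d
(stride 1, via chunked im2col and flat GEMMs under a fixed memory budget),
batch norm, max pooling (kernel = stride), dense, ReLU, dropout (inverted,
seeded) and flatten; gradients are verified against finite differences.
The LSTM layer is forward-only: the recurrent baseline instantiates,
profiles and predicts but is not trainable on this backend.  Training runs
in single precision by default.

## Synthetic data generator

Each channel is 1/f-shaped Gaussian noise (spectral exponent 1, scaled to
5 µV SD) plus one sinusoid per band — theta 4–8 Hz (4 µV), alpha 8–13 Hz
(8 µV), beta 14–30 Hz (3 µV) — with per-trial random frequency and phase.
Class effects, controlled by a single dial δ (default 1):

* high valence: alpha amplitude ×(1+δ) on left-frontal channels
  (Fp1, AF3, F3, F7) and ×max(0, 1−δ/2) on right-frontal channels — a
  frontal-alpha-asymmetry convention;
* high arousal: beta amplitude ×(1+δ) on frontal-central channels
  (FC5, FC1, FC2, FC6, Fz, Cz).

Ratings are drawn uniformly from (5, 9] for high and [1, 5] for low
classes, consistent with the threshold rule.  Archives mirror the DEAP
per-subject layout (data `trials×channels×samples`, labels `trials×4` with
dominance/liking filled uniformly) with a balanced 2×2 class grid.  The
generator emulates band-power structure and topography only: no artifacts
(EOG/EMG), no volume conduction, no nonstationarity, and the class effect
is deterministic per trial.  Passing tests therefore demonstrate that the
pipeline and models behave correctly on signals with known structure, not
that any accuracy level transfers to real recordings.

`band_power_probe` validates the dial: Welch band powers (1-s Hann
segments, 50% overlap) over the effect-carrying channel groups, a
standardized logistic regression, stratified 5-fold cross-validated AUC.
At δ=0 the AUC sits in the chance band; it is monotone in δ and saturates
quickly because the per-trial amplitude change is deterministic.

## Desk-scale study conditions

The published headline accuracies require the gated DEAP accession and
GPU-scale training and are out of scope; learning behaviour is instead
checked at sizes a workstation handles in minutes, chosen once:

* **Smoke fit:** 64 windows from two 19-s trials (one per class, δ=5),
  0.5-s windows at side 32 — the smallest input the unmodified pooling
  cascade admits — and a 1/16-width CNN-BN (conv 4; bottlenecks (1,8)×1,
  (2,8)×4; dense 16), SGD with momentum 0.9, target train accuracy 0.95
  within 200 epochs (reached in ~15).
* **Chance band:** 320 zero-effect windows (40 four-second trials, 0.125-s
  windows at side 16) and a one-block 3D CNN, 5 repeats × 5 epochs; the
  mean held-out accuracy must lie in [0.40, 0.60].  The window count keeps
  per-repeat test sets large enough (64) that label-imbalance noise does
  not dominate the band.
* **Probe monotonicity:** 200 eight-second trials per δ ∈ {0, 0.5, 1, 2, 5}.

## Known limitations

* FLOP totals are convention-dependent; only the convention above is
  implemented natively (the breakdown allows others to be derived).
* The recurrent baseline does not train on the numpy backend.
* The 9×9 electrode table is a documented convention, not a measured
  digitization; alternative layouts can be supplied as JSON.
* Window-level splits leak trial identity; trial-level evaluation must be
  constructed from the provenance table by the caller.
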