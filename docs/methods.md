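# Methods

## Acquisition model

The package models a continuously running 2D radial bSSFP acquisition whose
spoke angle advances by the tiny golden angle ψ₇ = 180°/(φ + 6) ≈ 23.6281°
(φ the golden ratio). Spokes are full-diameter (each readout crosses the
k-space origin) and angles accumulate modulo 360° across the whole series,
matching an interactive acquisition that never stops; a flag restarts the
angle per frame for ablation. k-space is parameterized in cycles/pixel on
[−0.5, 0.5): sample m of an N-sample readout sits at signed radius
(m − N/2)/N, so the DC sample coincides with an FFT grid frequency.

Grouping S consecutive spokes into a frame yields temporal resolution
S·TR (TR default 3.2 ms) and acceleration R = (π/2 · N)/S relative to the
radial Nyquist count ⌈π/2 · N⌉. With the default 192-sample readout the
spoke ladder {13, 17, 21, 25, 29, 33} maps to R = {23.2, 17.7, 14.4, 12.1,
10.4, 9.1}.

## Operators

`forward`/`adjoint` are an exact type-2/type-1 non-uniform DFT pair,
evaluated with factorized per-axis phase matrices (one complex matmul per
frame instead of a quadruple loop). Exactness makes the operators
bit-stable and directly testable: the suite checks them against a literal
direct-summation oracle on 16×16 grids and verifies the inner-product
(adjoint) identity to 1e−10. A fast approximate gridding backend (e.g.
Kaiser–Bessel) could be substituted behind the same two functions; nothing
downstream depends on how the transform is computed.

Density compensation is the analytic ramp: each sample is weighted by its
annular area element |k|·Δk·(π/n_spokes) with Δk = 1/N; the DC sample uses
the conventional Δk/8 radius proxy, keeping the weight profile symmetric
about the spoke center. With these weights the adjoint of a
Nyquist-complete acquisition approximates the inverse transform (NRMSE
< 5% on a smooth phantom).

`degrade_series` builds training pairs retrospectively: frame t of a
ground-truth magnitude cine is projected onto spokes [t·S, (t+1)·S) of the
continuous trajectory, brought back by the density-compensated adjoint,
magnitude taken, and the aliased series min–max normalized to [0, 1]. The
aliased series is normalized by its own range (ground truth and input are
normalized independently); a shared-factor and a per-frame mode exist, the
latter being what a streaming reconstructor — which cannot know the series
range — actually uses. Ground-truth phase is assumed zero: the corpus is
magnitude cines re-used as real-valued images.

Degradation happens at the full matrix and the center crop is taken
afterwards, for both members of the pair. This mirrors the intended
training-pair pipeline and matters numerically: the ramp-quadrature error
of the adjoint concentrates at the image periphery and corners, which the
crop discards.

Readout oversampling matters for fidelity: the residual error of
adjoint(forward(·)) at Nyquist spoke counts scales with the DC quadrature
deficit ∝ 1/N² and the radial step Δk. The package's scaled test geometry
therefore uses 2× readout oversampling (N = 128 samples for a 64-matrix
phantom, cropped to 48), the standard scanner configuration, under which a
fully sampled degrade–reconstruct round trip scores SSIM > 0.95.

## Synthetic cine phantoms

`phantom.generate_cine` emulates the statistics of a breath-hold bSSFP cine
corpus, not anatomy: bright blood pools (intensity ≈ 0.9), a mid-intensity
myocardial shell (≈ 0.55), a darker body ellipse (≈ 0.35), seeded static
background structures, and a frozen smooth noise texture, all composed by
maximum. Seven view-class presets (SAX, 4CH, LVLA, RVLA, LVOT, RVOT, PA)
arrange chamber counts and orientations so the classes are geometrically
distinguishable (pairwise SSIM < 0.9). Contraction scales structure radii
by 1 − pulse·cf·(1 − cos 2πφ)/2 with cf the contraction fraction (default
0.25) and φ the cardiac phase; a series with `cycles=1` is exactly
periodic. Per-subject variation (shift, rotation, scale, intensity gain,
extra background ellipses, texture) is drawn from the config seed, making
every series a pure function of (config, seed).

What the phantoms deliberately lack: bSSFP contrast physics and banding,
through-plane motion, breathing drift, receive-coil shading, raw multi-coil
noise. Passing the learning tests therefore shows that the pipeline
(operators → pairing → recurrent training → streaming inference) works and
that the network can learn radial de-aliasing of moving scenes — not that
the learned weights transfer to clinical images.

Interventional devices are multiplicative, moving, "vanishing" Gaussians: a
balloon is one blob whose center attenuates the signal by at most 80%
(frame ← frame · (1 − a_t·0.8·G_t)), a guidewire is five blobs spaced along
a moving wire axis. Defaults: balloon sd 4 px, wire blob sd 1.5 px spaced
6 px — chosen so the devices span realistic balloon (~1 cm) and wire scales
at 1.67 mm/px; visibility ramps are raised-cosine in/out, emulating a
device crossing the slice. These device parameters are package choices, not
literature values.

## Network

Five ConvLSTM blocks — two encoder scales, a bottleneck, two decoder scales
— with 2×2 max-pooling between encoder scales and 2×2 nearest-neighbour
upsampling followed by a 3×3 channel-halving convolution in the decoder;
skip connections concatenate the encoder hidden state with the upsampled
decoder stream; a linear 1×1 head maps back to one channel and the input
frame is added (residual). Gates use σ (i, f, o) and tanh (candidate, cell
output); there are no peephole terms. Each block's 4 input and 4 hidden
convolutions are fused into one convolution over [X_t, H_{t−1}] with
4·C_h output channels — parameter-for-parameter identical to the 8 separate
convolutions.

Two architecture details are pinned by parameter-count consistency: with
peepholes omitted and upsample+3×3-conv decoders, the default 32/64/128
configuration instantiates exactly 1,790,465 trainable parameters (≈1.79 M),
the count the closed forms in the test suite reproduce layer by layer.
Transposed-convolution decoders or peephole gates would land elsewhere.
The output activation is linear; outputs are clipped to [0, 1] at inference
only, so training gradients are unaffected.

Initialization: Glorot-uniform weights from a seeded generator, zero
biases except the forget-gate bias (default 1.0, the standard LSTM
trainability device). All state is explicit: `ModelState` holds the five
(H, C) pairs; reset is exact zeros; `warmup` pushes n = 2 seeded
standard-normal frames through the recurrence and discards the outputs,
emulating the served network's startup. Streaming (frame-at-a-time) and
batched inference are the same code path and produce identical outputs.

The network and its training run on a minimal reverse-mode autodiff engine
written on numpy (same-padded conv via im2col + matmul, argmax-routed
max-pool, nearest upsampling, channel concat/slice, gate nonlinearities,
MAE/MSE losses, Adam). No deep-learning framework is required anywhere in
the package; every operator's gradient is checked against central finite
differences in the suite.

## Training protocol

Loss is mean absolute error (MSE available by config), optimized with Adam
at lr 0.001, batch size 4, 100 epochs. Series are split into 8-frame chunks
for memory; the recurrent state is carried across the chunks of a series
and reset only at its end. The carry is gradient-detached — truncated
backpropagation through time with an 8-frame window — so values cross chunk
boundaries but gradients do not (asserted by the suite). Sample order is
shuffled per epoch from the config seed; with a validation split present,
the best epoch by validation MAE is restored at the end (configurable).
MAE was chosen as the loss because it is also the protocol's lead reported
metric; no augmentation is used beyond acceleration randomization.

### Experiments

* Acceleration: "specific" networks trained at single spoke counts versus
  one "generic" network whose series are corrupted at randomly assigned
  rates from the ladder; every test series is evaluated at each rate
  under both nets plus the gridded input, with paired Wilcoxon statistics.
  The generic rate assignment is a *balanced* random draw, stratified by
  split: within the training set (and separately the validation set) every
  rate is represented as evenly as the group size allows, in seeded random
  order. At full scale this is indistinguishable from an i.i.d. draw
  (~equal counts per rate either way); at desk scale it prevents the
  degenerate corpora an i.i.d. draw can produce — e.g. a rate with zero
  training series, which would void the experiment's premise.
* Leave-one-orientation-out: one network per view class trained with that
  class excluded (tested on it) against a reference network trained on all
  classes, both with generic random-rate corruption.

### Scaled study conditions

Full-scale conditions (128×128 crop of ≥160 matrices, 98/2/10 subjects per
view, 100 epochs, 32/64/128 hidden) are available but far too heavy for a
routine run on one core. The package's declared desk-scale conditions —
used by the test suite and the CLI experiment presets — are: 64-matrix
phantoms cropped to 48×48, 128-sample readouts (2× oversampling), 12-frame
series, 4 subjects per view split 2/1/1 (train/val/test), hidden widths
(8, 16, 32), 100 epochs with best-epoch selection by validation MAE.
Under these conditions the 17-spoke specific network lifts held-out SSIM
from ≈0.63 (gridded) to ≈0.89; the specific-vs-generic comparison is
evaluated at 17 spokes/frame, the rate used for prospective imaging —
evaluating the gap at all six rates would require training all six
specific networks. The LOO harness is exercised structurally at micro
scale in the suite; its full scaled run is available through
`radrecon experiment loo`.

## Evaluation

Metrics are computed over a 1-based inclusive frame range (default 5–25,
skipping the frames where the recurrent reconstruction is still
stabilizing): pixelwise MAE/MSE, PSNR at unit dynamic range (+∞ sentinel
when MSE = 0), and frame-averaged 2D SSIM (Gaussian 11×11 window, σ = 1.5,
K1 = 0.01, K2 = 0.03, data range 1) — per-frame averaging rather than a 3D
window. SSIM is delegated to scikit-image and cross-checked in the suite
against an independently hand-rolled implementation; Shapiro–Wilk and the
paired Wilcoxon signed-rank test are delegated to scipy (exact null for
n ≤ 25 after dropping zero differences, normal approximation beyond), with
the exact p verified against brute-force sign-flip enumeration.

The sliding-window baseline grids frame k from a `width`-spoke window
(default 99) centered on the center spoke of gridded frame k (step 17).
Windows are clipped at the start of the stream and a frame is emitted only
once its trailing half-window is available, so the first frame needs
(99 − 17)/2 = 41 spokes beyond its own 17 — the latency cost of the
baseline. `width == step` reproduces per-frame gridding exactly, an
operator-level regression test.

Catheter visibility is scored per frame as the ratio of device contrast in
the reconstruction to device contrast in the ground truth, where contrast
is (surround − center)/surround with the surround sampled on a ring of
radius 3·sd around the device center; the device counts as visible at
ratio ≥ 0.5.

## Numerical choices and degenerate inputs

* Min–max normalization of a constant series returns zeros (documented
  degenerate rule); NaNs are rejected.
* Bicubic resampling rounds the output grid to the nearest even size
  (272 px at 1.45 mm → 236 px at 1.67 mm).
* `paired_wilcoxon` raises on all-zero differences instead of returning an
  arbitrary p-value; `normality_check` raises on constant input.
* Max-pool gradient routes to the argmax (first occurrence on exact ties).
* float32 throughout the network; float64 in the Fourier operators.
* Warm-up exists for startup latency, not quality. Because every training
  series starts from a zero state, the cold start *is* the condition the
  network was trained for: at desk scale, priming with standard-normal
  frames (whose range is far outside the [0, 1] training data) perturbs
  the state and costs SSIM on the first frames, a transient that washes
  out as real frames are carried; pushing zero frames instead is nearly
  neutral. The suite asserts the decay of the transient and warm-up
  determinism rather than any ordering between warm-up variants.

## Known limitations

Single-coil magnitude simulation only (no sensitivity maps, no complex
noise); stylized phantoms (see above); the exact NUDFT is O(H·W·S) per
frame — fine at desk scale, a gridding backend would be needed for 256+
matrices at Nyquist spoke counts; full-scale (1.79 M parameter, 128×128,
770-series) training is supported by the code but takes GPU-scale compute
budgets, and the packaged studies therefore run at the declared scaled
conditions.
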