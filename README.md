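# radrecon

Low-latency **deep artifact suppression** for highly undersampled tiny
golden-angle radial real-time cardiac MRI — as a self-contained, desk-scale
Python package.

Real-time (free-breathing, interactive) cardiac imaging acquires radial
k-space spokes continuously, incrementing the spoke angle by the tiny golden
angle ψ₇ = 180°/(φ + 6) ≈ 23.63°. Grouping S consecutive spokes into one
frame gives a temporal resolution of S·TR (e.g. 17 spokes × 3.2 ms ≈ 54
ms/frame) at an acceleration factor R = (π/2 · N<sub>samples</sub>) / S
relative to the radial Nyquist criterion — R ≈ 17.7 at 17 spokes with
192-sample readouts, far beyond what naive gridding can handle without
severe streaking. A recurrent residual U-Net, with a convolutional LSTM at
every scale of the encoder and decoder, removes those aliasing artifacts
frame by frame: each ConvLSTM block carries its hidden state H<sub>t</sub>
and memory cell C<sub>t</sub> across frames, so the current frame is
de-aliased using both spatial context and the preceding temporal history,
with no future frames needed — the property that makes streaming,
low-latency reconstruction possible. The reference architecture (3 scales,
32/64/128 hidden channels, 3×3 kernels, concatenated skips, linear 1×1 head,
residual input addition) has exactly **1,790,465** trainable parameters.

The package provides every stage of the framework:

| module | what it does |
| --- | --- |
| `radrecon.geometry` | tiny golden-angle trajectories, ramp density compensation, acceleration/timing bookkeeping |
| `radrecon.gridding` | exact type-2/type-1 non-uniform DFT pair; retrospective undersampling (`degrade_series`), normalization, cropping, bicubic resampling |
| `radrecon.phantom` | synthetic beating-heart cine generator (7 view-geometry classes), balloon/guidewire simulation, dataset pairing and LOO splits |
| `radrecon.autodiff` | minimal reverse-mode autodiff (conv/pool/upsample/gates) the network runs on |
| `radrecon.network` | the recurrent U-Net, stateful inference, warm-up, parameter accounting |
| `radrecon.training` | MAE/Adam protocol with 8-frame truncated-BPTT chunks; acceleration and leave-one-orientation-out experiment harnesses |
| `radrecon.evaluation` | MAE/MSE/PSNR/SSIM over a frame range, Shapiro–Wilk + paired Wilcoxon, sliding-window baseline, catheter-visibility scoring |
| `radrecon.streaming` | spoke-by-spoke streaming reconstruction loop with per-stage timing events |
| `radrecon.cli` | `radrecon simulate | pair | train | reconstruct | evaluate | experiment …` |

## Worked example

Train a small network at 17 spokes/frame on synthetic phantoms and measure
the de-aliasing gain on held-out subjects (scaled-down geometry: 64-matrix
phantoms cropped to 48×48, 128-sample readouts):

```python
import numpy as np
from radrecon import (SequenceParams, PhantomConfig, UNetSpec, TrainConfig,
                      make_corpus_configs, build_dataset, build_model,
                      train, reconstruct_series, ssim_series)

params = SequenceParams(n_samples=128)
base = PhantomConfig(matrix=64, n_frames=12)
configs = make_corpus_configs(per_view=3, split_counts=(2, 0, 1),
                              base=base, seed=0)
dataset = build_dataset(configs, params, ("specific", 17), seed=1, crop=48)

model = build_model(UNetSpec(hidden=(8, 16, 32)), seed=0)
model, history = train(model, dataset,
                       TrainConfig(epochs=100, seed=0, select_best=False))

test = [s for s in dataset if s.split == "test"]
gridded = np.mean([ssim_series(s.input, s.target) for s in test])
recon = np.mean([ssim_series(reconstruct_series(model, s.input)[0], s.target)
                 for s in test])
print(f"gridded SSIM {gridded:.3f} -> reconstructed SSIM {recon:.3f}")
```

Output (about 4 minutes on one CPU core):

```
gridded SSIM 0.642 -> reconstructed SSIM 0.890
```

That is, the naive density-compensated gridding of 17-spoke frames scores
SSIM 0.642 against the ground truth on unseen phantoms, and the trained
network lifts this to 0.890 — the streak artifacts are suppressed while the
moving anatomy is preserved. The same `train`/`reconstruct_series` calls
scale to the full-size configuration (`UNetSpec()` at 128×128, 100 epochs)
unchanged.

The command-line interface wraps the same functions, e.g.

```bash
radrecon simulate --views 7 --per-view 4 --seed 1 --out data/sim
radrecon experiment accel --per-view 3 --epochs 10 --out results/accel
```

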