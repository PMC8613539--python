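"""Residual U-Net with convolutional LSTM blocks for streaming de-aliasing.

The network reconstructs a cine frame-by-frame: each of the five ConvLSTM
blocks (two encoder scales, a bottleneck, two decoder scales) carries its own
hidden state H_t and memory cell C_t across frames, so the current frame is
de-aliased using spatial context plus everything the recurrent states have
retained about preceding frames.  The default specification — 3 scales with
32/64/128 hidden channels, 3x3 kernels, 2x2 max-pool and 2x2 nearest
upsampling followed by a 3x3 channel-halving convolution, concatenated skip
connections, a linear 1x1 head, and a residual connection adding the input
frame — instantiates 1,790,465 trainable parameters (~1.79 M).

Gate equations (no peephole terms):

    i, f, o = sigmoid(W * [X_t, H_{t-1}] + b)     (three gate slices)
    g       = tanh  (W * [X_t, H_{t-1}] + b)
    C_t     = f . C_{t-1} + i . g
    H_t     = o . tanh(C_t)

The four input and four hidden convolutions of each gate stack are fused into
a single convolution over the channel concatenation [X_t, H_{t-1}] with
4*hidden output channels — parameter-for-parameter identical to the 8
separate convolutions (4 on X_t, 4 on H_{t-1}).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gridding import CineSeries

__all__ = [
    "ConvLSTMSpec",
    "UNetSpec",
    "ModelState",
    "ConvLSTMCell",
    "RecurrentUNet",
    "convlstm_step",
    "build_model",
    "parameter_count",
    "convlstm_param_count",
    "reset_state",
    "warmup",
    "reconstruct_series",
]


@dataclass(frozen=True)
class ConvLSTMSpec:
    """One ConvLSTM block: 8 internal convolutions (4 on X_t, 4 on H_{t-1})."""

    in_channels: int
    hidden_channels: int
    kernel: int = 3

    @property
    def n_parameters(self) -> int:
        k, ci, ch = self.kernel, self.in_channels, self.hidden_channels
        return 4 * k * k * (ci + ch) * ch + 4 * ch


def convlstm_param_count(in_channels: int, hidden_channels: int, kernel: int = 3) -> int:
    """Closed-form trainable-parameter count of one ConvLSTM block."""
    return ConvLSTMSpec(in_channels, hidden_channels, kernel).n_parameters


@dataclass(frozen=True)
class UNetSpec:
    """Architecture specification of the recurrent U-Net."""

    hidden: Tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    in_channels: int = 1
    forget_bias: float = 1.0

    @property
    def scales(self) -> int:
        return len(self.hidden)

    def to_json(self) -> str:
        return json.dumps(
            {"hidden": list(self.hidden), "kernel": self.kernel,
             "in_channels": self.in_channels, "forget_bias": self.forget_bias}
        )

    @classmethod
    def from_json(cls, s: str) -> "UNetSpec":
        d = json.loads(s)
        return cls(hidden=tuple(d["hidden"]), kernel=d["kernel"],
                   in_channels=d["in_channels"],
                   forget_bias=d.get("forget_bias", 1.0))


class ModelState:
    """Per-ConvLSTM-layer (H_t, C_t) pairs carried across frames."""

    def __init__(self, pairs: List[Tuple[Tensor, Tensor]]):
        self.pairs = pairs

    def detach(self) -> "ModelState":
        """Cut the gradient tape while keeping values (chunk carry)."""
        return ModelState([(h.detach(), c.detach()) for h, c in self.pairs])

    def arrays(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return [(h.data.copy(), c.data.copy()) for h, c in self.pairs]

    def allclose(self, other: "ModelState", atol: float = 0.0) -> bool:
        return all(
            np.allclose(h1.data, h2.data, atol=atol)
            and np.allclose(c1.data, c2.data, atol=atol)
            for (h1, c1), (h2, c2) in zip(self.pairs, other.pairs)
        )


class ConvLSTMCell:
    """Fused-gate ConvLSTM; gate order along channels is (i, f, o, g)."""

    def __init__(self, spec: ConvLSTMSpec, rng: np.random.Generator):
        self.spec = spec
        k, ci, ch = spec.kernel, spec.in_channels, spec.hidden_channels
        fan_in = (ci + ch) * k * k
        fan_out = 4 * ch * k * k
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = Tensor(
            rng.uniform(-lim, lim, size=(4 * ch, ci + ch, k, k)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(4 * ch), requires_grad=True)

    def set_forget_bias(self, value: float) -> None:
        ch = self.spec.hidden_channels
        self.b.data[ch : 2 * ch] = value

    @property
    def parameters(self) -> List[Tensor]:
        return [self.w, self.b]

    def init_state(self, batch: int, h: int, w: int) -> Tuple[Tensor, Tensor]:
        ch = self.spec.hidden_channels
        z = np.zeros((batch, ch, h, w), dtype=np.float32)
        return Tensor(z.copy()), Tensor(z.copy())

    def step(
        self, x: Tensor, state: Tuple[Tensor, Tensor]
    ) -> Tuple[Tensor, Tuple[Tensor, Tensor]]:
        h_prev, c_prev = state
        ch = self.spec.hidden_channels
        z = ad.conv2d(ad.concat(x, h_prev), self.w, self.b)
        i = ad.sigmoid(ad.channel_slice(z, 0, ch))
        f = ad.sigmoid(ad.channel_slice(z, ch, 2 * ch))
        o = ad.sigmoid(ad.channel_slice(z, 2 * ch, 3 * ch))
        g = ad.tanh(ad.channel_slice(z, 3 * ch, 4 * ch))
        c = ad.add(ad.mul(f, c_prev), ad.mul(i, g))
        h = ad.mul(o, ad.tanh(c))
        return h, (h, c)


def convlstm_step(x, state, w, b):
    """Functional single ConvLSTM step on plain arrays (testing surface).

    ``w`` is the fused (4*Ch, Cin+Ch, k, k) gate weight, ``b`` the (4*Ch,)
    bias; ``state`` is an (H, C) array pair.  Returns (H_t, (H_t, C_t)).
    """
    ch = w.shape[0] // 4
    spec = ConvLSTMSpec(w.shape[1] - ch, ch, w.shape[2])
    cell = ConvLSTMCell.__new__(ConvLSTMCell)
    cell.spec = spec
    cell.w = Tensor(w)
    cell.b = Tensor(b)
    h, (hn, cn) = cell.step(
        Tensor(x), (Tensor(state[0]), Tensor(state[1]))
    )
    return h.data, (hn.data, cn.data)


class _Conv:
    """Plain convolution layer (decoder up-convolutions and the 1x1 head)."""

    def __init__(self, cin, cout, k, rng: np.random.Generator):
        fan_in, fan_out = cin * k * k, cout * k * k
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        self.w = Tensor(
            rng.uniform(-lim, lim, size=(cout, cin, k, k)), requires_grad=True
        )
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    @property
    def parameters(self):
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)


class RecurrentUNet:
    """Three-scale residual U-Net with one ConvLSTM block per scale/branch.

    Encoder: E1(1->h1) -> pool -> E2(h1->h2) -> pool -> bottleneck(h2->h3)
    Decoder: up(h3->h2) -> [skip h2] -> D2(2*h2->h2) -> up(h2->h1)
             -> [skip h1] -> D1(2*h1->h1) -> 1x1 head(h1->1) -> + input
    """

    def __init__(self, spec: UNetSpec = UNetSpec(), seed: int = 0):
        if spec.scales != 3:
            raise ValueError("this architecture is pinned to 3 scales")
        self.spec = spec
        rng = np.random.default_rng(seed)
        h1, h2, h3 = spec.hidden
        k = spec.kernel
        self.enc1 = ConvLSTMCell(ConvLSTMSpec(spec.in_channels, h1, k), rng)
        self.enc2 = ConvLSTMCell(ConvLSTMSpec(h1, h2, k), rng)
        self.bott = ConvLSTMCell(ConvLSTMSpec(h2, h3, k), rng)
        self.up1 = _Conv(h3, h2, k, rng)
        self.dec2 = ConvLSTMCell(ConvLSTMSpec(2 * h2, h2, k), rng)
        self.up2 = _Conv(h2, h1, k, rng)
        self.dec1 = ConvLSTMCell(ConvLSTMSpec(2 * h1, h1, k), rng)
        self.head = _Conv(h1, 1, 1, rng)
        for cell in self.cells:
            cell.set_forget_bias(spec.forget_bias)

    @property
    def cells(self) -> List[ConvLSTMCell]:
        return [self.enc1, self.enc2, self.bott, self.dec2, self.dec1]

    @property
    def parameters(self) -> List[Tensor]:
        ps: List[Tensor] = []
        for layer in (self.enc1, self.enc2, self.bott, self.up1,
                      self.dec2, self.up2, self.dec1, self.head):
            ps.extend(layer.parameters)
        return ps

    def zero_weights(self) -> None:
        for p in self.parameters:
            p.data[...] = 0.0

    # -- state management ---------------------------------------------------

    def init_state(self, batch: int, h: int, w: int) -> ModelState:
        if h % 4 or w % 4:
            raise ValueError("input size must be divisible by 4 (3 scales)")
        return ModelState(
            [
                self.enc1.init_state(batch, h, w),
                self.enc2.init_state(batch, h // 2, w // 2),
                self.bott.init_state(batch, h // 4, w // 4),
                self.dec2.init_state(batch, h // 2, w // 2),
                self.dec1.init_state(batch, h, w),
            ]
        )

    # -- forward ------------------------------------------------------------

    def step(self, x: Tensor, state: ModelState) -> Tuple[Tensor, ModelState]:
        """One frame through the network; returns (output, new state)."""
        s = state.pairs
        h1, s1 = self.enc1.step(x, s[0])
        h2, s2 = self.enc2.step(ad.maxpool2(h1), s[1])
        h3, s3 = self.bott.step(ad.maxpool2(h2), s[2])
        u1 = self.up1(ad.upsample2(h3))
        d2, s4 = self.dec2.step(ad.concat(h2, u1), s[3])
        u2 = self.up2(ad.upsample2(d2))
        d1, s5 = self.dec1.step(ad.concat(h1, u2), s[4])
        y = ad.add(self.head(d1), x)
        return y, ModelState([s1, s2, s3, s4, s5])

    def infer_frame(
        self, frame: np.ndarray, state: ModelState
    ) -> Tuple[np.ndarray, ModelState]:
        """Inference step on a raw [H, W] frame (no gradient bookkeeping)."""
        x = Tensor(frame[None, None])
        y, new_state = self.step(x, state)
        return y.data[0, 0], new_state.detach()

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters)}
        np.savez(path, spec=self.spec.to_json(), **arrays)

    @classmethod
    def load(cls, path) -> "RecurrentUNet":
        with np.load(path, allow_pickle=False) as z:
            spec = UNetSpec.from_json(str(z["spec"]))
            model = cls(spec)
            for i, p in enumerate(model.parameters):
                p.data[...] = z[f"p{i}"]
        return model


def build_model(spec: UNetSpec = UNetSpec(), seed: int = 0) -> RecurrentUNet:
    return RecurrentUNet(spec, seed=seed)


def parameter_count(model: RecurrentUNet) -> int:
    """Total number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters))


def reset_state(model: RecurrentUNet, batch: int, h: int, w: int) -> ModelState:
    """All-zero hidden/memory tensors (cold start)."""
    return model.init_state(batch, h, w)


def warmup(
    model: RecurrentUNet, h: int, w: int, n: int = 2, seed: int = 0
) -> ModelState:
    """Prime the recurrent states with ``n`` i.i.d. standard-normal frames.

    Emulates the served network's startup: dummy Gaussian-noise frames are
    pushed through the recurrence (outputs discarded) so the first real frame
    meets a non-degenerate state without extra latency.
    """
    rng = np.random.default_rng(seed)
    state = model.init_state(1, h, w)
    for _ in range(n):
        frame = rng.standard_normal((h, w)).astype(np.float32)
        _, state = model.infer_frame(frame, state)
    return state


def reconstruct_series(
    model: RecurrentUNet,
    aliased: CineSeries,
    state: Optional[ModelState] = None,
    clip: bool = True,
) -> Tuple[CineSeries, ModelState]:
    """Frame-by-frame stateful reconstruction of an aliased series.

    Streaming (one frame at a time with the returned state) and batched
    (whole series in one call) application produce identical outputs.
    Outputs are clipped to [0, 1] unless ``clip=False``.
    """
    t, h, w = aliased.frames.shape
    if state is None:
        state = model.init_state(1, h, w)
    out = np.empty((t, h, w), dtype=np.float64)
    for i in range(t):
        y, state = model.infer_frame(
            aliased.frames[i].astype(np.float32), state
        )
        out[i] = y
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return aliased.copy_with(out), state
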