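"""Synthetic beating-heart cine phantoms and interventional-device simulation.

The generator emulates the statistical shape of a breath-hold bSSFP magnitude
cine corpus: a bright blood pool (or pools), a mid-intensity myocardial ring,
a darker body, static background structures, and smooth periodic contraction.
Seven view-geometry presets stand in for the standard cardiac imaging planes
(short axis, four chamber, LV/RV long axis, LV/RV outflow tract, pulmonary
artery); they are geometrically distinguishable but deliberately stylized —
ellipse algebra with smooth temporal warps, not an anatomical simulator.

Interventional devices are modelled as moving, "vanishing" multiplicative
2D Gaussians: a balloon is a single blob with a maximal signal decrease of
80% in the blood pool, a guidewire is five blobs along a moving polyline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import AccelerationSpec, SequenceParams
from .gridding import CineSeries, center_crop, degrade_series

__all__ = [
    "VIEW_CLASSES",
    "PhantomConfig",
    "DevicePath",
    "PairedSample",
    "generate_cine",
    "render_frame",
    "apply_balloon",
    "apply_guidewire",
    "balloon_path",
    "guidewire_path",
    "make_corpus_configs",
    "draw_generic_rates",
    "assign_generic_rates",
    "build_dataset",
    "loo_split",
]

VIEW_CLASSES = ("SAX", "4CH", "LVLA", "RVLA", "LVOT", "RVOT", "PA")


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic cine subject.

    ``contraction_fraction`` is the peak fractional radius reduction of the
    blood pool over the cardiac cycle; ``cycles`` is the number of cardiac
    cycles the series spans (1.0 makes the series exactly periodic).
    """

    view_class: str = "SAX"
    n_frames: int = 30
    heart_rate_bpm: float = 70.0
    matrix: int = 160
    contraction_fraction: float = 0.25
    noise_sd: float = 0.015
    seed: int = 0
    cycles: float = 1.0
    pixel_mm: float = 1.67
    tr_ms: float = 3.2

    def __post_init__(self) -> None:
        if self.view_class not in VIEW_CLASSES:
            raise ValueError(f"unknown view_class {self.view_class!r}")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if not (0.0 < self.contraction_fraction < 0.5):
            raise ValueError("contraction_fraction must be in (0, 0.5)")
        if self.matrix < 32 or self.matrix % 2:
            raise ValueError("matrix must be even and >= 32")


# Per-view structure tables: (cx, cy, rx, ry, rot_deg, intensity, edge, pulse)
# in normalized [-1, 1] coordinates.  ``pulse`` scales the systolic radius
# reduction (1 = full blood-pool contraction, 0 = static).
_BODY = (0.0, 0.0, 0.88, 0.80, 0.0, 0.35, 0.40, 0.04)

_VIEW_STRUCTURES = {
    "SAX": [
        (-0.42, -0.10, 0.21, 0.31, -20.0, 0.85, 0.30, 0.8),   # RV pool
        (-0.10, -0.05, 0.37, 0.35, 0.0, 0.55, 0.30, 0.35),    # LV myocardium
        (-0.10, -0.05, 0.22, 0.20, 0.0, 0.92, 0.30, 1.0),     # LV pool
    ],
    "4CH": [
        (-0.28, 0.02, 0.30, 0.50, 8.0, 0.55, 0.30, 0.35),     # LV myo shell
        (-0.28, 0.00, 0.17, 0.40, 8.0, 0.92, 0.30, 1.0),      # LV pool
        (0.12, 0.05, 0.16, 0.37, -5.0, 0.82, 0.30, 0.9),      # RV pool
        (-0.26, 0.55, 0.16, 0.19, 0.0, 0.78, 0.30, 0.4),      # LA
        (0.14, 0.52, 0.15, 0.17, 0.0, 0.74, 0.30, 0.4),       # RA
    ],
    "LVLA": [
        (-0.10, 0.02, 0.32, 0.58, 25.0, 0.55, 0.30, 0.35),    # myo shell
        (-0.10, 0.00, 0.19, 0.48, 25.0, 0.92, 0.30, 1.0),     # LV pool
        (0.30, 0.48, 0.18, 0.16, 0.0, 0.78, 0.30, 0.4),       # atrium
    ],
    "RVLA": [
        (0.05, 0.02, 0.23, 0.48, -30.0, 0.82, 0.30, 0.9),     # RV pool
        (-0.32, 0.42, 0.17, 0.15, 0.0, 0.74, 0.30, 0.4),      # RA
        (0.42, -0.35, 0.12, 0.11, 0.0, 0.70, 0.30, 0.3),      # PA root
    ],
    "LVOT": [
        (-0.15, 0.12, 0.33, 0.42, 10.0, 0.55, 0.30, 0.35),    # myo shell
        (-0.15, 0.10, 0.22, 0.32, 10.0, 0.92, 0.30, 1.0),     # LV pool
        (0.12, -0.28, 0.10, 0.30, 35.0, 0.85, 0.30, 0.5),     # outflow
        (0.32, -0.52, 0.13, 0.12, 0.0, 0.80, 0.30, 0.3),      # aortic root
    ],
    "RVOT": [
        (0.02, 0.16, 0.26, 0.30, -15.0, 0.82, 0.30, 0.9),     # RV pool
        (-0.10, -0.30, 0.09, 0.28, -40.0, 0.85, 0.30, 0.5),   # outflow
        (-0.30, -0.55, 0.13, 0.11, 0.0, 0.80, 0.30, 0.3),     # PA
    ],
    "PA": [
        (0.00, -0.05, 0.16, 0.40, 0.0, 0.85, 0.30, 0.4),      # PA trunk
        (-0.32, -0.46, 0.21, 0.10, 30.0, 0.80, 0.30, 0.3),    # left branch
        (0.32, -0.46, 0.21, 0.10, -30.0, 0.80, 0.30, 0.3),    # right branch
        (0.02, 0.45, 0.31, 0.23, 0.0, 0.60, 0.30, 0.5),       # heart below
    ],
}


def _subject_variation(config: PhantomConfig):
    """Seeded per-subject jitter: shift, rotation, scale, extra background."""
    rng = np.random.default_rng(config.seed)
    shift = rng.uniform(-0.05, 0.05, size=2)
    rot = rng.uniform(-8.0, 8.0)
    scale = rng.uniform(0.94, 1.06)
    gain = rng.uniform(-0.04, 0.04)
    n_bg = 2
    bg = []
    for _ in range(n_bg):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0.55, 0.72)
        bg.append(
            (
                r * np.cos(ang),
                r * np.sin(ang),
                rng.uniform(0.08, 0.16),
                rng.uniform(0.08, 0.16),
                rng.uniform(-45, 45),
                rng.uniform(0.42, 0.52),
                0.3,
                0.0,
            )
        )
    # static smooth texture field, one per subject (temporally frozen so the
    # series stays exactly periodic over a full cardiac cycle)
    tex = rng.normal(0.0, 1.0, size=(config.matrix, config.matrix))
    tex = gaussian_filter(tex, sigma=2.0)
    tex /= max(np.abs(tex).max(), 1e-12)
    return shift, rot, scale, gain, bg, tex


def _render_ellipse(X, Y, cx, cy, rx, ry, rot_deg, val, edge):
    """Soft-edged ellipse; ``edge`` is the quadratic-distance rolloff width."""
    th = math.radians(rot_deg)
    dx, dy = X - cx, Y - cy
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    d = (u / rx) ** 2 + (v / ry) ** 2
    return np.clip((1.0 - d) / edge, 0.0, 1.0) * val


def render_frame(config: PhantomConfig, phase: float) -> np.ndarray:
    """Render one frame at cardiac phase ``phase`` (periodic with period 1)."""
    n = config.matrix
    ax = np.linspace(-1.0, 1.0, n, endpoint=False) + 1.0 / n
    X, Y = np.meshgrid(ax, ax)
    shift, rot, scale, gain, bg, tex = _subject_variation(config)
    systole = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # 0 at phase 0, 1 mid
    img = np.zeros((n, n))
    structures = [_BODY] + _VIEW_STRUCTURES[config.view_class] + bg
    th = math.radians(rot)
    for (cx, cy, rx, ry, srot, val, edge, pulse) in structures:
        s = scale * (1.0 - pulse * config.contraction_fraction * systole)
        cxr = scale * (np.cos(th) * cx - np.sin(th) * cy) + shift[0]
        cyr = scale * (np.sin(th) * cx + np.cos(th) * cy) + shift[1]
        layer = _render_ellipse(
            X, Y, cxr, cyr, rx * s, ry * s, srot + rot, val + gain, edge
        )
        img = np.maximum(img, layer)
    if config.noise_sd > 0:
        img = img + config.noise_sd * tex
    return np.clip(img, 0.0, 1.0)


def generate_cine(config: PhantomConfig) -> CineSeries:
    """Generate a periodic beating-heart phantom cine.

    Deterministic in (config, seed); frame t is rendered at cardiac phase
    ``cycles * t / n_frames`` so a series with ``cycles=1`` spans exactly one
    cycle and ``render_frame(config, 1.0)`` reproduces frame 0.
    """
    frames = np.stack(
        [
            render_frame(config, config.cycles * t / config.n_frames)
            for t in range(config.n_frames)
        ]
    )
    return CineSeries(
        frames=frames,
        pixel_mm=config.pixel_mm,
        tr_ms=config.tr_ms,
        view=config.view_class,
        subject=f"{config.view_class.lower()}-{config.seed:05d}",
    )


# ---------------------------------------------------------------------------
# Interventional devices


@dataclass
class DevicePath:
    """Trajectory of a moving, vanishing multiplicative Gaussian device.

    ``centers`` has shape (T, n_blobs, 2) in pixel (x, y) coordinates;
    ``amplitude`` in [0, 1] is the per-frame visibility (0 = out of plane);
    ``max_attenuation`` is the peak fractional signal decrease (0.8 = 80%).
    """

    centers: np.ndarray
    amplitude: np.ndarray
    sd_px: float
    n_blobs: int
    max_attenuation: float = 0.8

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.centers.ndim != 3 or self.centers.shape[1] != self.n_blobs:
            raise ValueError("centers must be (T, n_blobs, 2)")
        if self.amplitude.min() < 0 or self.amplitude.max() > 1:
            raise ValueError("amplitude must lie in [0, 1]")
        if self.n_blobs not in (1, 5):
            raise ValueError("n_blobs must be 1 (balloon) or 5 (guidewire)")

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]


def _raised_cosine_amplitude(n_frames, appear, disappear, ramp):
    """Visibility ramping smoothly in over ``ramp`` frames after ``appear``
    and out before ``disappear`` (device moving through the slice)."""
    t = np.arange(n_frames, dtype=np.float64)
    up = np.clip((t - appear) / max(ramp, 1e-9), 0.0, 1.0)
    down = np.clip((disappear - t) / max(ramp, 1e-9), 0.0, 1.0)
    a = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))
    a[(t < appear) | (t > disappear)] = 0.0
    return np.clip(a, 0.0, 1.0)


def balloon_path(
    n_frames: int,
    start_xy: Sequence[float],
    end_xy: Sequence[float],
    sd_px: float = 4.0,
    appear: int = 2,
    disappear: Optional[int] = None,
    ramp: int = 4,
    max_attenuation: float = 0.8,
) -> DevicePath:
    """Balloon tip drifting from ``start_xy`` to ``end_xy`` while fading in/out."""
    if disappear is None:
        disappear = n_frames - 3
    t = np.linspace(0.0, 1.0, n_frames)[:, None]
    centers = (1 - t) * np.asarray(start_xy)[None] + t * np.asarray(end_xy)[None]
    return DevicePath(
        centers=centers[:, None, :],
        amplitude=_raised_cosine_amplitude(n_frames, appear, disappear, ramp),
        sd_px=sd_px,
        n_blobs=1,
        max_attenuation=max_attenuation,
    )


def guidewire_path(
    n_frames: int,
    start_xy: Sequence[float],
    end_xy: Sequence[float],
    direction: Sequence[float] = (1.0, 0.3),
    spacing_px: float = 6.0,
    sd_px: float = 1.5,
    appear: int = 2,
    disappear: Optional[int] = None,
    ramp: int = 4,
    max_attenuation: float = 0.8,
) -> DevicePath:
    """Five blobs spaced ``spacing_px`` along a moving wire axis."""
    if disappear is None:
        disappear = n_frames - 3
    t = np.linspace(0.0, 1.0, n_frames)[:, None]
    tip = (1 - t) * np.asarray(start_xy)[None] + t * np.asarray(end_xy)[None]
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    offsets = np.arange(5)[:, None] * spacing_px * d[None, :]  # (5, 2)
    centers = tip[:, None, :] + offsets[None, :, :]
    return DevicePath(
        centers=centers,
        amplitude=_raised_cosine_amplitude(n_frames, appear, disappear, ramp),
        sd_px=sd_px,
        n_blobs=5,
        max_attenuation=max_attenuation,
    )


def _apply_device(series: CineSeries, path: DevicePath) -> CineSeries:
    if path.n_frames != series.n_frames:
        raise ValueError("device path length must match series length")
    h, w = series.frames.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    out = series.frames.copy()
    for t in range(series.n_frames):
        a = path.amplitude[t]
        if a == 0.0:
            continue
        for (cx, cy) in path.centers[t]:
            g = np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * path.sd_px**2)
            )
            out[t] = out[t] * (1.0 - a * path.max_attenuation * g)
    return series.copy_with(out)


def apply_balloon(series: CineSeries, path: DevicePath) -> CineSeries:
    """Multiplicative single-Gaussian balloon: at full visibility the signal
    at the blob center drops by ``max_attenuation`` (default 80%)."""
    if path.n_blobs != 1:
        raise ValueError("balloon path must have exactly 1 blob")
    return _apply_device(series, path)


def apply_guidewire(series: CineSeries, path: DevicePath) -> CineSeries:
    """Same attenuation law applied by each of the 5 wire blobs in turn."""
    if path.n_blobs != 5:
        raise ValueError("guidewire path must have exactly 5 blobs")
    return _apply_device(series, path)


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class PairedSample:
    """(aliased input, ground-truth target) training unit with its rate."""

    input: CineSeries
    target: CineSeries
    accel: AccelerationSpec
    split: str = "train"
    view: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError("input/target shapes must match")


def make_corpus_configs(
    views: Iterable[str] = VIEW_CLASSES,
    per_view: int = 28,
    split_counts: tuple = (24, 1, 3),
    base: Optional[PhantomConfig] = None,
    seed: int = 0,
) -> list:
    """Per-view subject configs with train/val/test split tags.

    The full-scale corpus mirrors a 98/2/10 split per orientation; the
    desk-scale default is 24/1/3 of 28 subjects per view.
    """
    if sum(split_counts) != per_view:
        raise ValueError("split_counts must sum to per_view")
    base = base or PhantomConfig()
    tags = (
        ["train"] * split_counts[0]
        + ["val"] * split_counts[1]
        + ["test"] * split_counts[2]
    )
    out = []
    for vi, view in enumerate(views):
        for j in range(per_view):
            cfg = replace(base, view_class=view, seed=seed + 1000 * vi + j)
            out.append((cfg, tags[j]))
    return out


def draw_generic_rates(n: int, rates: Sequence[int], rng) -> np.ndarray:
    """Balanced random rate assignment for generic (variable-rate) training.

    Each rate is assigned ``n // len(rates)`` times, the remainder spread over
    distinct randomly chosen rates, and the whole assignment shuffled — so for
    any corpus size every rate is represented as evenly as possible
    (approximately n/len(rates) series each), while the per-series order is
    random.
    """
    rates = list(rates)
    base = np.repeat(rates, n // len(rates))
    extra = rng.choice(rates, size=n % len(rates), replace=False)
    out = np.concatenate([base, extra]).astype(int)
    rng.shuffle(out)
    return out


def assign_generic_rates(splits, rates, rng) -> np.ndarray:
    """Per-split balanced rate assignment: each split group (train/val/test)
    sees every rate as evenly as its size allows."""
    splits = list(splits)
    out = np.empty(len(splits), dtype=int)
    for tag in dict.fromkeys(splits):
        idx = [i for i, s in enumerate(splits) if s == tag]
        out[idx] = draw_generic_rates(len(idx), rates, rng)
    return out


def build_dataset(
    configs: Sequence,
    params: SequenceParams,
    spokes_mode,
    seed: int = 0,
    crop: Optional[int] = None,
) -> list:
    """Degrade phantom cines into paired training samples.

    ``spokes_mode`` is either ``("specific", S)`` — every series degraded at S
    spokes/frame — or ``("generic", (S1, S2, ...))`` — one rate per series,
    assigned by the balanced random draw of :func:`draw_generic_rates` with
    the stated seed.  Ground truth and aliased series are both center-cropped
    (after degradation) when ``crop`` is given, mirroring the train-pair
    pipeline.
    """
    if not configs:
        raise ValueError("empty config list")
    mode, arg = spokes_mode
    rng = np.random.default_rng(seed)
    splits = [
        (entry[1] if isinstance(entry, tuple) else "train") for entry in configs
    ]
    if mode == "generic":
        rates = [int(r) for r in assign_generic_rates(splits, arg, rng)]
    elif mode == "specific":
        rates = [int(arg)] * len(configs)
    else:
        raise ValueError(f"unknown spokes_mode {mode!r}")
    samples = []
    for (entry, spf) in zip(configs, rates):
        cfg, split = entry if isinstance(entry, tuple) else (entry, "train")
        gt = generate_cine(cfg)
        aliased = degrade_series(gt, params, spokes_per_frame=spf)
        if crop is not None:
            gt = center_crop(gt, crop)
            aliased = center_crop(aliased, crop)
        samples.append(
            PairedSample(
                input=aliased,
                target=gt,
                accel=AccelerationSpec.from_params(spf, params),
                split=split,
                view=cfg.view_class,
                subject=gt.subject,
            )
        )
    return samples


def loo_split(dataset: Sequence[PairedSample], left_out_view: str):
    """Leave-one-orientation-out split.

    Returns (train, val, test): train/val keep their tags but exclude the
    left-out view entirely; test is every series of the left-out view.
    """
    views = {s.view for s in dataset}
    if left_out_view not in views:
        raise ValueError(f"unknown view label {left_out_view!r}")
    test = [s for s in dataset if s.view == left_out_view]
    train = [s for s in dataset if s.view != left_out_view and s.split != "val"]
    val = [s for s in dataset if s.view != left_out_view and s.split == "val"]
    return train, val, test
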