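"""Image-quality metrics, paired statistics, and baseline reconstructions.

Reconstruction quality is scored with MAE, MSE, PSNR and SSIM over an
inclusive 1-based frame range (default frames 5-25, skipping the initial
frames where the recurrent reconstruction is still stabilizing).  SSIM uses
the standard Gaussian 11x11 window (sigma 1.5, K1=0.01, K2=0.03) at unit
dynamic range, averaged over frames.  Distribution comparisons follow the
usual non-parametric protocol: Shapiro-Wilk for normality, then a two-sided
paired Wilcoxon signed-rank test (exact null for n <= 25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .geometry import SequenceParams, make_trajectory
from .gridding import CineSeries, KSpaceData, adjoint, normalize_series

__all__ = [
    "MetricReport",
    "metrics",
    "ssim_series",
    "paired_wilcoxon",
    "normality_check",
    "sliding_window_lead_in",
    "sliding_window_recon",
    "catheter_visibility",
]


@dataclass
class MetricReport:
    """Per-series quality metrics over an inclusive 1-based frame range."""

    mae: float
    mse: float
    psnr: float
    ssim: float
    frame_range: Tuple[int, int]
    series_id: str = ""
    rate: Optional[float] = None
    network: str = ""

    def as_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "rate": self.rate,
            "network": self.network,
            "mae": self.mae,
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
        }


def _frames(series) -> np.ndarray:
    return series.frames if isinstance(series, CineSeries) else np.asarray(series)


def _ssim_frame(a: np.ndarray, b: np.ndarray) -> float:
    return float(
        structural_similarity(
            a,
            b,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def ssim_series(pred, gt) -> float:
    """Frame-averaged SSIM over a whole series."""
    p, g = _frames(pred), _frames(gt)
    return float(np.mean([_ssim_frame(p[t], g[t]) for t in range(p.shape[0])]))


def metrics(
    pred,
    gt,
    frame_range: Tuple[int, int] = (5, 25),
    series_id: str = "",
    rate: Optional[float] = None,
    network: str = "",
) -> MetricReport:
    """MAE/MSE/PSNR/SSIM between a reconstruction and its ground truth.

    ``frame_range`` is 1-based inclusive; PSNR uses unit dynamic range and
    reports +inf when MSE is exactly zero.
    """
    p, g = _frames(pred), _frames(gt)
    if p.shape != g.shape:
        raise ValueError("pred/gt shapes must match")
    lo, hi = frame_range
    if lo < 1 or hi > p.shape[0] or lo > hi:
        raise ValueError(
            f"frame_range {frame_range} outside series of {p.shape[0]} frames"
        )
    p = p[lo - 1 : hi]
    g = g[lo - 1 : hi]
    diff = p - g
    mae = float(np.abs(diff).mean())
    mse = float((diff**2).mean())
    psnr = math.inf if mse == 0.0 else float(10.0 * np.log10(1.0 / mse))
    ssim = float(np.mean([_ssim_frame(p[t], g[t]) for t in range(p.shape[0])]))
    return MetricReport(
        mae=mae, mse=mse, psnr=psnr, ssim=ssim,
        frame_range=frame_range, series_id=series_id, rate=rate,
        network=network,
    )


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 remaining pairs, the normal approximation beyond.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nz = np.count_nonzero(d)
    if nz == 0:
        raise ValueError("all paired differences are zero (degenerate input)")
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def normality_check(x: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value)."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input (degenerate)")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def sliding_window_lead_in(width: int = 99, step: int = 17) -> int:
    """Extra spokes needed before the first sliding-window frame, beyond the
    ``step`` spokes the per-frame gridded reconstruction needs: (width-step)/2."""
    if width < step:
        raise ValueError("width must be >= step")
    return (width - step) // 2


def sliding_window_recon(
    spokes: np.ndarray,
    params: SequenceParams,
    size: int,
    width: int = 99,
    step: int = 17,
    start_index: int = 0,
    norm_mode: str = "series",
) -> CineSeries:
    """Sliding-window baseline: frame k is gridded from a ``width``-spoke
    window centered on the center spoke of gridded frame k.

    ``spokes`` is the continuous stream of per-spoke sample vectors,
    shape (n_spokes, n_samples).  Windows are clipped at the start of the
    stream; a frame is emitted only once the trailing half-window is
    available, so the first frame needs ``(width - step) // 2`` spokes beyond
    its own ``step``.  ``width == step`` reproduces the per-frame gridded
    reconstruction exactly.
    """
    if width < step:
        raise ValueError("width must be >= step")
    n_spokes = spokes.shape[0]
    if n_spokes < step + sliding_window_lead_in(width, step):
        raise ValueError("spoke stream shorter than one window")
    half_lo = (width - 1) // 2
    half_hi = width // 2
    frames = []
    k = 0
    while True:
        center = k * step + (step - 1) // 2
        lo = max(0, center - half_lo)
        hi = center + half_hi  # inclusive
        if hi >= n_spokes:
            break
        traj = make_trajectory(params, hi - lo + 1, start_index=start_index + lo)
        ks = KSpaceData(samples=spokes[lo : hi + 1], traj=traj)
        frames.append(np.abs(adjoint(ks, size, dcf=traj.dcf)))
        k += 1
    if not frames:
        raise ValueError("no complete window in stream")
    out = np.stack(frames)
    if norm_mode == "series":
        out = normalize_series(out)
    elif norm_mode == "frame":
        out = np.stack([normalize_series(f) for f in out])
    return CineSeries(frames=out, tr_ms=params.tr_ms)


def _bilinear(frame: np.ndarray, x: float, y: float) -> float:
    h, w = frame.shape
    x = min(max(x, 0.0), w - 1.001)
    y = min(max(y, 0.0), h - 1.001)
    x0, y0 = int(x), int(y)
    fx, fy = x - x0, y - y0
    return float(
        frame[y0, x0] * (1 - fx) * (1 - fy)
        + frame[y0, x0 + 1] * fx * (1 - fy)
        + frame[y0 + 1, x0] * (1 - fx) * fy
        + frame[y0 + 1, x0 + 1] * fx * fy
    )


def catheter_visibility(pred, gt, device_path) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame device-contrast ratio of a reconstruction vs ground truth.

    For each frame the device contrast is measured as (surround - center) /
    surround, with the center sampled at the (first-blob) device position and
    the surround averaged on a ring of radius 3 * sd around it.  Returns
    (ratio array, boolean mask of full-visibility frames); the device counts
    as visible in a frame when the ratio is >= 0.5.
    """
    p, g = _frames(pred), _frames(gt)
    if p.shape != g.shape:
        raise ValueError("pred/gt shapes must match")
    h, w = p.shape[1:]
    ratios = np.zeros(p.shape[0])
    full = device_path.amplitude >= 0.99
    n_ring = 16
    ring_r = 3.0 * device_path.sd_px
    for t in range(p.shape[0]):
        cx, cy = device_path.centers[t, 0]
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("device path outside image")
        angles = 2 * np.pi * np.arange(n_ring) / n_ring
        def contrast(frame):
            center = _bilinear(frame, cx, cy)
            ring = np.mean(
                [
                    _bilinear(frame, cx + ring_r * np.cos(a), cy + ring_r * np.sin(a))
                    for a in angles
                ]
            )
            if ring <= 1e-9:
                return 0.0
            return (ring - center) / ring
        cg = contrast(g[t])
        cp = contrast(p[t])
        ratios[t] = 0.0 if cg <= 1e-9 else cp / cg
    return ratios, full
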