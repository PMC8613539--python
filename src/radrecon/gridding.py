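"""Non-uniform Fourier operators and the retrospective degradation pipeline.

The forward operator is an exact type-2 non-uniform DFT evaluated with
factorized phase matrices (the 2D phase separates into per-axis complex
exponentials, so each frame costs one H x W x S complex matmul rather than a
naive quadruple loop); the adjoint is the matching type-1 transform.  Exact
transforms keep the operator pair bit-stable and testable against a direct
summation oracle — a fast approximate gridding backend could be swapped in
behind the same two functions.

``degrade_series`` implements retrospective undersampling used to build
training pairs: each ground-truth frame is projected onto the tiny
golden-angle spokes of that frame interval, brought back with the
density-compensated adjoint, and the magnitude is renormalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

from .geometry import RadialTrajectory, SequenceParams, make_trajectory

__all__ = [
    "CineSeries",
    "KSpaceData",
    "forward",
    "adjoint",
    "degrade_series",
    "normalize_series",
    "center_crop",
    "resample_bicubic",
]


@dataclass
class CineSeries:
    """Real-valued magnitude cine: frames [T, H, W] normalized to [0, 1]."""

    frames: np.ndarray
    pixel_mm: float = 1.67
    tr_ms: float = 3.2
    view: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be [T, H, W]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def copy_with(self, frames: np.ndarray) -> "CineSeries":
        return CineSeries(
            frames=frames,
            pixel_mm=self.pixel_mm,
            tr_ms=self.tr_ms,
            view=self.view,
            subject=self.subject,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("frames", data=self.frames.astype(np.float32))
            d.attrs["pixel_mm"] = self.pixel_mm
            d.attrs["tr_ms"] = self.tr_ms
            d.attrs["view"] = self.view
            d.attrs["subject"] = self.subject

    @classmethod
    def from_hdf5(cls, path) -> "CineSeries":
        with h5py.File(path, "r") as f:
            d = f["frames"]
            return cls(
                frames=np.asarray(d, dtype=np.float64),
                pixel_mm=float(d.attrs.get("pixel_mm", 1.67)),
                tr_ms=float(d.attrs.get("tr_ms", 3.2)),
                view=str(d.attrs.get("view", "")),
                subject=str(d.attrs.get("subject", "")),
            )


@dataclass
class KSpaceData:
    """Complex samples of one frame, grouped by spoke, with their trajectory."""

    samples: np.ndarray  # (n_spokes, n_samples) complex
    traj: RadialTrajectory

    def __post_init__(self) -> None:
        expect = (self.traj.n_spokes, self.traj.n_samples)
        if self.samples.shape != expect:
            raise ValueError(f"samples shape {self.samples.shape} != {expect}")


def _phase_matrices(coords: np.ndarray, h: int, w: int, sign: float):
    """Per-axis complex exponentials for pixel grids centered at the midpoint."""
    x = np.arange(w, dtype=np.float64) - w / 2
    y = np.arange(h, dtype=np.float64) - h / 2
    ex = np.exp(sign * 2j * np.pi * np.outer(coords[:, 0], x))  # (S, W)
    ey = np.exp(sign * 2j * np.pi * np.outer(coords[:, 1], y))  # (S, H)
    return ex, ey


def forward(image: np.ndarray, traj: RadialTrajectory) -> KSpaceData:
    """Type-2 NUDFT: sample(k) = sum_p image(p) exp(-2*pi*i k.p)."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square [H, W]")
    if image.shape[0] % 2:
        raise ValueError("image side must be even")
    h, w = image.shape
    ex, ey = _phase_matrices(traj.coords, h, w, sign=-1.0)
    inner = image.astype(np.complex128) @ ex.T  # (H, S)
    samples = np.einsum("sh,hs->s", ey, inner)
    return KSpaceData(
        samples=samples.reshape(traj.n_spokes, traj.n_samples), traj=traj
    )


def adjoint(
    kspace: KSpaceData, size: int, dcf: Optional[np.ndarray] = None
) -> np.ndarray:
    """Type-1 NUDFT onto a ``size x size`` grid:
    image(p) = sum_s dcf_s sample_s exp(+2*pi*i k_s.p).

    With ``dcf`` equal to one this is the exact adjoint of :func:`forward`
    (inner-product identity); with ramp weights it is the naive density-
    compensated (gridded) reconstruction.
    """
    traj = kspace.traj
    s = kspace.samples.reshape(-1).astype(np.complex128)
    if s.size != traj.coords.shape[0]:
        raise ValueError("samples inconsistent with trajectory")
    if dcf is not None:
        s = s * np.asarray(dcf, dtype=np.float64)
    ex, ey = _phase_matrices(traj.coords, size, size, sign=+1.0)
    # image[y, x] = sum_s w_s conj-phase: (H,S) @ (S,W)
    return (ey.T * s[None, :]) @ ex


def degrade_series(
    gt: CineSeries,
    params: SequenceParams,
    spokes_per_frame: Optional[int] = None,
    start_spoke: int = 0,
    continuous: bool = True,
    norm_mode: str = "series",
) -> CineSeries:
    """Retrospectively undersample a ground-truth cine onto radial spokes.

    Frame ``t`` is projected onto spokes ``[t*S, (t+1)*S)`` of the continuous
    tiny golden-angle acquisition (or onto spokes restarting at ``start_spoke``
    every frame when ``continuous=False``), reconstructed with the density-
    compensated adjoint, and the magnitude is taken.

    norm_mode: 'series' rescales the aliased series by its own min/max,
    'frame' rescales each frame independently (streaming-compatible),
    'none' leaves raw magnitudes.
    """
    if gt.n_frames == 0:
        raise ValueError("empty series")
    spf = params.spokes_per_frame if spokes_per_frame is None else spokes_per_frame
    if spf < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    size = gt.frames.shape[1]
    out = np.empty_like(gt.frames)
    for t in range(gt.n_frames):
        s0 = start_spoke + (t * spf if continuous else 0)
        traj = make_trajectory(params, spf, start_index=s0)
        k = forward(gt.frames[t], traj)
        img = adjoint(k, size, dcf=traj.dcf)
        out[t] = np.abs(img)
        if norm_mode == "frame":
            out[t] = _minmax(out[t])
    if norm_mode == "series":
        out = _minmax(out)
    elif norm_mode not in ("frame", "none"):
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    return gt.copy_with(out)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def normalize_series(series):
    """Min-max normalize a whole series (or array) to [0, 1].

    A constant series maps to all zeros (documented degenerate rule).
    """
    arr = series.frames if isinstance(series, CineSeries) else np.asarray(series)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    out = _minmax(arr.astype(np.float64))
    if isinstance(series, CineSeries):
        return series.copy_with(out)
    return out


def center_crop(series, size: int = 128):
    """Spatially centered ``size x size`` crop of every frame."""
    arr = series.frames if isinstance(series, CineSeries) else np.asarray(series)
    h, w = arr.shape[-2:]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds input {h}x{w}")
    top = (h - size) // 2
    left = (w - size) // 2
    out = arr[..., top : top + size, left : left + size].copy()
    if isinstance(series, CineSeries):
        return series.copy_with(out)
    return out


def resample_bicubic(series, src_pixel_mm: float, dst_pixel_mm: float):
    """Resample frames to a new pixel size with bicubic interpolation.

    The output grid is ``round_to_even(N * src/dst)`` per side; equal pixel
    sizes return an unchanged copy.
    """
    if src_pixel_mm <= 0 or dst_pixel_mm <= 0:
        raise ValueError("pixel sizes must be positive")
    arr = series.frames if isinstance(series, CineSeries) else np.asarray(series)
    h, w = arr.shape[-2:]
    if src_pixel_mm == dst_pixel_mm:
        out = arr.copy()
    else:
        scale = src_pixel_mm / dst_pixel_mm
        nh = max(2, int(round(h * scale / 2)) * 2)
        nw = max(2, int(round(w * scale / 2)) * 2)
        frames = arr if arr.ndim == 3 else arr[None]
        out = np.stack(
            [
                _sk_resize(
                    f, (nh, nw), order=3, mode="reflect",
                    anti_aliasing=False, preserve_range=True,
                )
                for f in frames
            ]
        )
        if arr.ndim == 2:
            out = out[0]
    if isinstance(series, CineSeries):
        res = series.copy_with(out)
        res.pixel_mm = dst_pixel_mm
        return res
    return out
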