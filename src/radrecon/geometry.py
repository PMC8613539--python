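"""Tiny golden-angle radial trajectory geometry.

Continuous radial acquisitions increment the spoke angle by a *tiny golden
angle* psi_N = 180 / (phi + N - 1) degrees, with phi the golden ratio.  For
order N = 7 this gives psi_7 ~ 23.63 deg, which yields near-uniform angular
coverage for any window of consecutive spokes — the property that makes
sliding reconstruction windows and interactive (real-time) imaging possible.

k-space coordinates are expressed in cycles/pixel on the [-0.5, 0.5) torus;
sample ``m`` of a spoke sits at signed radius ``(m - n_samples/2) / n_samples``
so the DC sample coincides with an FFT grid point.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOLDEN_RATIO",
    "TINY_GOLDEN_ORDER",
    "SequenceParams",
    "RadialTrajectory",
    "AccelerationSpec",
    "tiny_golden_angle",
    "spoke_angles",
    "make_trajectory",
    "density_compensation",
    "acceleration_factor",
    "nyquist_spokes",
    "frame_duration_ms",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

#: default tiny golden-angle order; psi_7 = 180/(phi+6) ~ 23.628 deg
TINY_GOLDEN_ORDER = 7


def tiny_golden_angle(order: int = TINY_GOLDEN_ORDER) -> float:
    """Angular increment (degrees) of the tiny golden-angle family.

    ``order=1`` recovers the classic golden angle 180/phi ~ 111.246 deg;
    ``order=7`` gives the ~23.63 deg increment used for real-time imaging.
    """
    if int(order) != order or order < 1:
        raise ValueError(f"order must be a positive integer, got {order!r}")
    return 180.0 / (GOLDEN_RATIO + order - 1)


def spoke_angles(
    n_spokes: int, start_index: int = 0, order: int = TINY_GOLDEN_ORDER
) -> np.ndarray:
    """Angles (deg, mod 360) of spokes ``start_index .. start_index+n_spokes-1``
    of a continuous tiny golden-angle acquisition."""
    if n_spokes < 0:
        raise ValueError("n_spokes must be >= 0")
    psi = tiny_golden_angle(order)
    idx = start_index + np.arange(n_spokes, dtype=np.float64)
    return np.mod(idx * psi, 360.0)


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition bookkeeping for a radial bSSFP sequence.

    Defaults mirror a 1.5 T interactive real-time protocol: TR 3.2 ms,
    192 samples per readout (2x readout oversampling of a ~128 crop),
    17 spokes per frame.
    """

    tr_ms: float = 3.2
    n_samples: int = 192
    spokes_per_frame: int = 17
    fov_mm: float = 320.0
    pixel_mm: float = 1.67

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.n_samples < 2 or self.n_samples % 2:
            raise ValueError("n_samples must be even and >= 2")
        if self.spokes_per_frame < 1:
            raise ValueError("spokes_per_frame must be >= 1")


@dataclass
class RadialTrajectory:
    """Spoke angles plus per-sample 2D k-space coordinates and density weights.

    ``coords`` has shape (n_spokes * n_samples, 2); component 0 pairs with the
    image x (width) axis, component 1 with y (height).  ``dcf`` are the ramp
    density-compensation weights of :func:`density_compensation`.
    """

    angles_deg: np.ndarray
    coords: np.ndarray
    start_index: int
    n_samples: int
    dcf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dcf is None:
            self.dcf = density_compensation(self)

    @property
    def n_spokes(self) -> int:
        return len(self.angles_deg)

    def angles_to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["spoke_index", "angle_deg"])
            for i, a in enumerate(self.angles_deg):
                w.writerow([self.start_index + i, f"{a:.6f}"])


def make_trajectory(
    params: SequenceParams,
    n_spokes: int,
    start_index: int = 0,
    order: int = TINY_GOLDEN_ORDER,
) -> RadialTrajectory:
    """Full-diameter radial spokes through the k-space origin.

    Each spoke carries ``params.n_samples`` samples at signed radii
    ``(m - n/2)/n`` for m = 0..n-1, rigidly rotated to the spoke angle.
    """
    if params.n_samples % 2:
        raise ValueError("n_samples must be even (center-sample convention)")
    angles = spoke_angles(n_spokes, start_index, order)
    n = params.n_samples
    radii = (np.arange(n, dtype=np.float64) - n / 2) / n
    theta = np.deg2rad(angles)
    # (n_spokes, n_samples, 2): kx along cos, ky along sin
    coords = np.empty((n_spokes, n, 2))
    coords[..., 0] = np.cos(theta)[:, None] * radii[None, :]
    coords[..., 1] = np.sin(theta)[:, None] * radii[None, :]
    return RadialTrajectory(
        angles_deg=angles,
        coords=coords.reshape(-1, 2),
        start_index=start_index,
        n_samples=n,
    )


def density_compensation(traj: RadialTrajectory) -> np.ndarray:
    """Analytic ramp density-compensation weights.

    Each sample is weighted by its annular area element |k| * dk * dtheta with
    dk = 1/n_samples and dtheta = pi/n_spokes (full-diameter spokes cover 360
    deg with 2*n_spokes half-spokes).  The center (DC) sample, hit by every
    spoke, gets the conventional dk/8 radius proxy so the weight profile stays
    symmetric about the spoke center.  With this normalization the adjoint of
    a Nyquist-complete acquisition approximates the inverse transform.
    """
    if traj.n_spokes == 0:
        raise ValueError("trajectory is empty")
    n = traj.n_samples
    dk = 1.0 / n
    r = np.abs(np.hypot(traj.coords[:, 0], traj.coords[:, 1]))
    r = np.where(r < dk / 2, dk / 8.0, r)
    return r * dk * (np.pi / traj.n_spokes)


def nyquist_spokes(n_samples: int) -> int:
    """Spokes needed for azimuthal Nyquist sampling: ceil(pi/2 * n_samples)."""
    return int(math.ceil(math.pi / 2.0 * n_samples))


def acceleration_factor(spokes_per_frame: int, n_samples: int = 192) -> float:
    """Radial acceleration R = (pi/2 * n_samples) / spokes_per_frame, to 1 dp."""
    if spokes_per_frame <= 0 or n_samples <= 0:
        raise ValueError("spokes_per_frame and n_samples must be positive")
    return round((math.pi / 2.0 * n_samples) / spokes_per_frame, 1)


def frame_duration_ms(spokes_per_frame: int, tr_ms: float = 3.2) -> int:
    """Temporal resolution of one frame in ms (nearest integer)."""
    if spokes_per_frame <= 0 or tr_ms <= 0:
        raise ValueError("inputs must be positive")
    return int(round(spokes_per_frame * tr_ms))


@dataclass(frozen=True)
class AccelerationSpec:
    """Acceleration descriptor attached to every synthetically degraded series."""

    spokes_per_frame: int
    r_factor: float
    frame_ms: int

    @classmethod
    def from_params(
        cls, spokes_per_frame: int, params: SequenceParams
    ) -> "AccelerationSpec":
        return cls(
            spokes_per_frame=spokes_per_frame,
            r_factor=acceleration_factor(spokes_per_frame, params.n_samples),
            frame_ms=frame_duration_ms(spokes_per_frame, params.tr_ms),
        )
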