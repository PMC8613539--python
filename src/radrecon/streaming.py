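"""Streaming frame-by-frame reconstruction loop with per-stage timing.

Emulates the low-latency acquisition-reconstruction pipeline: spokes arrive
one at a time; as soon as a frame's worth (``spokes_per_frame``) is
available it is gridded (density-compensated adjoint), pushed through the
recurrent network with carried state, and delivered.  Timing of each stage
is recorded per frame but never asserted against wall-clock targets —
absolute latencies are hardware properties, not algorithmic ones.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .geometry import SequenceParams, make_trajectory
from .gridding import CineSeries, KSpaceData, adjoint, forward, normalize_series
from .network import ModelState, RecurrentUNet, warmup as warmup_state

__all__ = ["StreamEvent", "spoke_stream_from_series", "stream_reconstruct"]


@dataclass
class StreamEvent:
    """Per-frame bookkeeping of the streaming loop (timestamps monotonic)."""

    frame_index: int
    t_spokes_complete: float
    t_gridded: float
    t_dealiased: float
    t_delivered: float
    state_policy: str

    def __post_init__(self) -> None:
        ts = (
            self.t_spokes_complete,
            self.t_gridded,
            self.t_dealiased,
            self.t_delivered,
        )
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("stage timestamps must be monotonic")


def spoke_stream_from_series(
    gt: CineSeries,
    params: SequenceParams,
    spokes_per_frame: int,
    start_spoke: int = 0,
) -> Iterator[np.ndarray]:
    """Simulate the continuous spoke stream a scanner would emit for ``gt``.

    Frame t of the ground truth supplies spokes [t*S, (t+1)*S) of the
    continuous tiny golden-angle acquisition, one readout at a time.
    """
    for t in range(gt.n_frames):
        traj = make_trajectory(
            params, spokes_per_frame, start_index=start_spoke + t * spokes_per_frame
        )
        k = forward(gt.frames[t], traj)
        for i in range(spokes_per_frame):
            yield k.samples[i]


def stream_reconstruct(
    spoke_source: Iterable[np.ndarray],
    model: RecurrentUNet,
    params: SequenceParams,
    spokes_per_frame: int,
    size: int,
    start_spoke: int = 0,
    warmup: bool = True,
    warmup_seed: int = 0,
    clip: bool = True,
) -> Tuple[CineSeries, List[StreamEvent]]:
    """Consume spokes incrementally and emit de-aliased frames.

    Each gridded frame is min/max-normalized independently (a streaming
    reconstructor cannot know the series-wide range), so the offline
    equivalent is ``degrade_series(..., norm_mode='frame')`` followed by
    ``reconstruct_series``; the two paths produce identical outputs.
    Incomplete trailing frames are dropped.
    """
    state: Optional[ModelState] = None
    policy = "reset"
    if warmup:
        state = warmup_state(model, size, size, n=2, seed=warmup_seed)
        policy = "warmup"
    frames: List[np.ndarray] = []
    events: List[StreamEvent] = []
    buffer: List[np.ndarray] = []
    spoke_idx = start_spoke
    frame_idx = 0
    for spoke in spoke_source:
        buffer.append(np.asarray(spoke))
        if len(buffer) < spokes_per_frame:
            continue
        t0 = time.perf_counter()
        traj = make_trajectory(
            params, spokes_per_frame, start_index=spoke_idx
        )
        k = KSpaceData(samples=np.stack(buffer), traj=traj)
        gridded = normalize_series(np.abs(adjoint(k, size, dcf=traj.dcf)))
        t1 = time.perf_counter()
        if state is None:
            state = model.init_state(1, size, size)
        y, state = model.infer_frame(gridded.astype(np.float32), state)
        t2 = time.perf_counter()
        if clip:
            y = np.clip(y, 0.0, 1.0)
        frames.append(y)
        t3 = time.perf_counter()
        events.append(
            StreamEvent(
                frame_index=frame_idx,
                t_spokes_complete=t0,
                t_gridded=t1,
                t_dealiased=t2,
                t_delivered=t3,
                state_policy=policy,
            )
        )
        policy = "carry"
        spoke_idx += spokes_per_frame
        frame_idx += 1
        buffer = []
    if not frames:
        raise ValueError("spoke stream shorter than one frame")
    return CineSeries(frames=np.stack(frames), tr_ms=params.tr_ms), events
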