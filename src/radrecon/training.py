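"""Training protocol and generalizability experiment harnesses.

Training minimizes the mean absolute error between the reconstructed and
ground-truth frames with Adam (learning rate 0.001, batch size 4, 100 epochs
at full scale).  Each series is split into chunks of 8 frames purely for
memory reasons: the recurrent states are carried (gradient-detached —
truncated backpropagation through time) across the chunks of one series and
reset only at the end of the complete time series.

Two experiment harnesses mirror the generalizability studies:

* acceleration — "specific" networks trained at single undersampling rates
  versus one "generic" network trained with rates drawn at random per series
  from the same set;
* leave-one-orientation-out — seven networks each trained with one view
  class excluded (tested on it), against one reference network trained on
  all orientations, all with generic random-rate corruption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .evaluation import metrics, paired_wilcoxon
from .geometry import AccelerationSpec, SequenceParams
from .gridding import CineSeries, center_crop, degrade_series
from .network import RecurrentUNet, UNetSpec, build_model
from .phantom import (PairedSample, PhantomConfig, assign_generic_rates,
                      generate_cine, loo_split)

__all__ = [
    "TrainConfig",
    "chunk_series",
    "train",
    "run_acceleration_experiment",
    "run_loo_experiment",
    "AccelReport",
    "LooReport",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults follow the full-scale recipe."""

    epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 4
    chunk_len: int = 8
    loss: str = "mae"
    seed: int = 0
    shuffle: bool = True
    select_best: bool = True

    def __post_init__(self) -> None:
        if self.chunk_len < 2:
            raise ValueError("chunk_len must be >= 2")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")


def chunk_series(n_frames: int, chunk_len: int = 8) -> List[Tuple[int, int, bool]]:
    """Split a series of ``n_frames`` into consecutive chunks.

    Returns (start, stop, carry_after) triples: the recurrent state is
    carried across chunk boundaries (carry_after=True) and reset only after
    the final chunk of the series (carry_after=False).  The last chunk may
    be short.
    """
    if n_frames < 1:
        raise ValueError("series must have at least one frame")
    bounds = list(range(0, n_frames, chunk_len)) + [n_frames]
    out = []
    for i in range(len(bounds) - 1):
        out.append((bounds[i], bounds[i + 1], i < len(bounds) - 2))
    return out


def _loss_fn(name: str):
    return ad.mae_loss if name == "mae" else ad.mse_loss


def _batched(items: Sequence, size: int):
    for i in range(0, len(items), size):
        yield items[i : i + size]


def _val_mae(model: RecurrentUNet, samples: Sequence[PairedSample]) -> float:
    from .network import reconstruct_series

    errs = []
    for s in samples:
        rec, _ = reconstruct_series(model, s.input, clip=True)
        errs.append(float(np.abs(rec.frames - s.target.frames).mean()))
    return float(np.mean(errs)) if errs else float("nan")


def train(
    model: RecurrentUNet,
    dataset: Sequence[PairedSample],
    config: TrainConfig = TrainConfig(),
) -> Tuple[RecurrentUNet, Dict[str, list]]:
    """Train in place; returns (model, history).

    ``dataset`` entries tagged split='train' are optimized over; split='val'
    entries drive best-epoch selection by validation MAE.  Deterministic for
    a fixed config seed and initial model.
    """
    train_set = [s for s in dataset if s.split == "train"]
    val_set = [s for s in dataset if s.split == "val"]
    if not train_set:
        raise ValueError("dataset contains no training samples")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters, lr=config.lr)
    lossf = _loss_fn(config.loss)
    history: Dict[str, list] = {"train_loss": [], "val_loss": []}
    best = (float("inf"), None)
    for epoch in range(config.epochs):
        order = np.arange(len(train_set))
        if config.shuffle:
            rng.shuffle(order)
        epoch_losses = []
        for batch_idx in _batched(order, config.batch_size):
            batch = [train_set[i] for i in batch_idx]
            t_len = min(s.input.n_frames for s in batch)
            h, w = batch[0].input.frames.shape[1:]
            x_all = np.stack(
                [s.input.frames[:t_len] for s in batch]
            ).astype(np.float32)
            y_all = np.stack(
                [s.target.frames[:t_len] for s in batch]
            ).astype(np.float32)
            state = model.init_state(len(batch), h, w)
            for (lo, hi, carry) in chunk_series(t_len, config.chunk_len):
                opt.zero_grad()
                loss = None
                for t in range(lo, hi):
                    x = Tensor(x_all[:, t][:, None])
                    y, state = model.step(x, state)
                    fl = lossf(y, y_all[:, t][:, None])
                    loss = fl if loss is None else ad.add(loss, fl)
                loss = ad.scale(loss, 1.0 / (hi - lo))
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {loss.data!r}"
                    )
                loss.backward()
                opt.step()
                epoch_losses.append(float(loss.data))
                # TBPTT: values cross the chunk boundary, gradients do not
                state = state.detach() if carry else None
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_set:
            vm = _val_mae(model, val_set)
            history["val_loss"].append(vm)
            if config.select_best and vm < best[0]:
                best = (vm, [p.data.copy() for p in model.parameters])
    if config.select_best and best[1] is not None:
        for p, data in zip(model.parameters, best[1]):
            p.data[...] = data
    return model, history


# ---------------------------------------------------------------------------
# experiment harnesses


def _degrade_pairs(
    gts: Sequence[Tuple[CineSeries, str]],
    params: SequenceParams,
    rates: Sequence[int],
    crop: Optional[int] = None,
) -> List[PairedSample]:
    out = []
    for (gt, split), spf in zip(gts, rates):
        aliased = degrade_series(gt, params, spokes_per_frame=int(spf))
        g = gt
        if crop is not None:
            g = center_crop(gt, crop)
            aliased = center_crop(aliased, crop)
        out.append(
            PairedSample(
                input=aliased,
                target=g,
                accel=AccelerationSpec.from_params(int(spf), params),
                split=split,
                view=gt.view,
                subject=gt.subject,
            )
        )
    return out


def _metric_rows(
    samples: Sequence[PairedSample],
    recon_frames: Sequence[np.ndarray],
    network: str,
    frame_range: Tuple[int, int],
) -> List[dict]:
    rows = []
    for s, rec in zip(samples, recon_frames):
        rep = metrics(
            rec, s.target, frame_range=frame_range,
            series_id=s.subject, rate=s.accel.r_factor, network=network,
        )
        row = rep.as_dict()
        row["view"] = s.view
        row["spokes"] = s.accel.spokes_per_frame
        rows.append(row)
    return rows


@dataclass
class AccelReport:
    """Long-format metric table plus specific-vs-generic paired statistics."""

    table: pd.DataFrame
    stats: pd.DataFrame
    models: Dict[str, RecurrentUNet]


def run_acceleration_experiment(
    configs: Sequence[Tuple[PhantomConfig, str]],
    params: SequenceParams,
    unet_spec: UNetSpec,
    train_cfg: TrainConfig,
    rates: Sequence[int] = (13, 17, 21, 25, 29, 33),
    specific_rates: Optional[Sequence[int]] = None,
    crop: Optional[int] = None,
    frame_range: Tuple[int, int] = (5, 25),
    seed: int = 0,
) -> AccelReport:
    """Specific-vs-generic acceleration study on a phantom corpus.

    Trains one "specific" network per rate in ``specific_rates`` (default:
    all of ``rates``) plus one "generic" network whose training series are
    corrupted at rates drawn uniformly from ``rates``; every test series is
    then evaluated at each specific rate under both networks, alongside the
    gridded input.
    """
    from .network import reconstruct_series

    if specific_rates is None:
        specific_rates = tuple(rates)
    missing = set(specific_rates) - set(rates)
    if missing:
        raise ValueError(f"specific rates {sorted(missing)} not in rate set")
    gts = [(generate_cine(cfg), split) for cfg, split in configs]
    rng = np.random.default_rng(seed)
    models: Dict[str, RecurrentUNet] = {}
    for s in specific_rates:
        ds = _degrade_pairs(gts, params, [s] * len(gts), crop)
        model = build_model(unet_spec, seed=seed)
        train(model, ds, train_cfg)
        models[f"specific-{s}"] = model
    generic_rates = assign_generic_rates([sp for _, sp in gts], rates, rng)
    ds_gen = _degrade_pairs(gts, params, generic_rates, crop)
    generic = build_model(unet_spec, seed=seed)
    train(generic, ds_gen, train_cfg)
    models["generic"] = generic

    rows: List[dict] = []
    for s in specific_rates:
        test = [
            p
            for p in _degrade_pairs(
                [(g, sp) for g, sp in gts if sp == "test"], params,
                [s] * sum(1 for _, sp in gts if sp == "test"), crop,
            )
        ]
        rows += _metric_rows(
            test, [p.input.frames for p in test], "gridded", frame_range
        )
        for name in (f"specific-{s}", "generic"):
            recs = [
                reconstruct_series(models[name], p.input)[0].frames
                for p in test
            ]
            label = "specific" if name.startswith("specific") else "generic"
            rows += _metric_rows(test, recs, label, frame_range)
    table = pd.DataFrame(rows)
    stats_rows = []
    for s in specific_rates:
        sub = table[table.spokes == s]
        for metric_name in ("mae", "ssim"):
            a = sub[sub.network == "specific"].sort_values("series_id")[metric_name]
            b = sub[sub.network == "generic"].sort_values("series_id")[metric_name]
            try:
                stat, p = paired_wilcoxon(a.values, b.values)
            except ValueError:
                stat, p = float("nan"), float("nan")
            stats_rows.append(
                {"spokes": s, "metric": metric_name,
                 "mean_specific": float(a.mean()),
                 "mean_generic": float(b.mean()),
                 "wilcoxon_stat": stat, "p_value": p}
            )
    return AccelReport(table=table, stats=pd.DataFrame(stats_rows), models=models)


@dataclass
class LooReport:
    """Per-orientation metrics for LOO networks vs the all-views reference."""

    table: pd.DataFrame
    stats: pd.DataFrame
    models: Dict[str, RecurrentUNet]


def run_loo_experiment(
    configs: Sequence[Tuple[PhantomConfig, str]],
    params: SequenceParams,
    unet_spec: UNetSpec,
    train_cfg: TrainConfig,
    rates: Sequence[int] = (13, 17, 21, 25, 29, 33),
    eval_rate: int = 17,
    crop: Optional[int] = None,
    frame_range: Tuple[int, int] = (5, 25),
    seed: int = 0,
) -> LooReport:
    """Leave-one-orientation-out study.

    Trains one network per view class with that class excluded, plus one
    reference network on all classes; all nets use generic random-rate
    corruption.  Each left-out view's test series (degraded at
    ``eval_rate``) is scored under its LOO network, the reference network,
    and the gridded input.
    """
    from .network import reconstruct_series

    gts = [(generate_cine(cfg), split) for cfg, split in configs]
    views = sorted({g.view for g, _ in gts})
    rng = np.random.default_rng(seed)
    generic_rates = assign_generic_rates([sp for _, sp in gts], rates, rng)
    full_ds = _degrade_pairs(gts, params, generic_rates, crop)
    models: Dict[str, RecurrentUNet] = {}
    for view in views:
        tr, val, _ = loo_split(full_ds, view)
        model = build_model(unet_spec, seed=seed)
        train(model, tr + val, train_cfg)
        models[f"loo-{view}"] = model
    reference = build_model(unet_spec, seed=seed)
    train(reference, full_ds, train_cfg)
    models["all"] = reference

    rows: List[dict] = []
    for view in views:
        test_gts = [(g, sp) for g, sp in gts if sp == "test" and g.view == view]
        test = _degrade_pairs(test_gts, params, [eval_rate] * len(test_gts), crop)
        rows += _metric_rows(
            test, [p.input.frames for p in test], "gridded", frame_range
        )
        for name, label in ((f"loo-{view}", "loo"), ("all", "all")):
            recs = [
                reconstruct_series(models[name], p.input)[0].frames for p in test
            ]
            rows += _metric_rows(test, recs, label, frame_range)
    table = pd.DataFrame(rows)
    stats_rows = []
    for metric_name in ("mae", "ssim"):
        a = table[table.network == "loo"].sort_values("series_id")[metric_name]
        b = table[table.network == "all"].sort_values("series_id")[metric_name]
        try:
            stat, p = paired_wilcoxon(a.values, b.values)
        except ValueError:
            stat, p = float("nan"), float("nan")
        stats_rows.append(
            {"metric": metric_name, "mean_loo": float(a.mean()),
             "mean_all": float(b.mean()), "wilcoxon_stat": stat, "p_value": p}
        )
    return LooReport(table=table, stats=pd.DataFrame(stats_rows), models=models)
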